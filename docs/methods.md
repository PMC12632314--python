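# Methods

This note documents the models behind `onoff`, the parameters that matter,
the design choices made where several readings were defensible, and what
the synthetic-data tests do and do not demonstrate about real recordings.

## Conventions

Time is seconds from session start, floating point; every interval is
half-open `[start, end)`, so a spike at exactly `end` belongs to the next
interval and boundary ambiguities cannot arise. Continuous signals are
stored channel-major with a JSON sidecar (`channel_ids, sample_rate,
dtype, t0, kind`); tables are TSV with a one-line header. Sample rates are
configuration, not constants: defaults 24414.0625 Hz wideband (the TDT
nominal rate behind the rounded "24.414 kHz"), 400 Hz LFP, 1017 Hz
EEG/EMG. Unsure and Artifact bouts are excluded from every condition-level
computation unless explicitly included.

## MUA spike detection

Wideband traces are band-passed 300–12000 Hz with a zero-phase FIR filter
(Kaiser design, ≥ 60 dB stop-band per pass; the kernel is convolved with
its own reverse, so the applied response is the squared magnitude with
zero phase — spike timing is not skewed). The per-sample median across
channels is then subtracted (common median reference). Noise is estimated
per channel as `sigma = median(|x − median(x)|)/0.6745`; local extrema
beyond `k·sigma` (default k = 4, negative-going — the extracellular
convention; the crossing polarity is configurable because it cannot be
inferred from the detection rule alone) are spike times, with a 1-ms
refractory suppressing multiple crossings of one waveform. Firing rates
are counts over 2-s windows tiling the recording; the last partial window
is dropped rather than rescaled, so windowed rates have homogeneous
variance and total count is conserved over the tiled span.

Two practical notes. With very few channels the common-median residual is
noticeably heavier-tailed than its MAD suggests and the effective
threshold drops; at 16 channels the residual is near-Gaussian and the
false-event rate on pure noise is ~2–4/s/channel at k = 4 — which is why
MUA-scale true rates (tens of Hz) are needed for a clean detection. The
LFP path low-passes at 160 Hz (kaiser FIR, zero phase) and decimates by
`round(fs/400)`; for TDT-rate input the resulting rate is 400.23 Hz and is
stored exactly.

## ON/OFF segmentation

Single channel: ON periods are maximal spike runs whose internal
inter-spike intervals are all `< 50 ms` (the bound is exclusive — an ISI
of exactly 50 ms ends the run); runs are timestamped first-to-last spike,
zero-width for single spikes. Candidate OFF periods are inter-run gaps
`≥ 50 ms`. A candidate is accepted when **at least one** adjacent run
lasts ≥ 30 ms; this one-sided reading implements the prohibition on an OFF
flanked by two single-spike "runs" while keeping an OFF between one solid
ON and one isolated spike — the stricter both-sides reading is available
(`OffParams.both_flanks`). Stretches touching the recording edges are
never single-channel OFFs (no flanking ON exists).

Global: the step function `n(t)` counts channels currently inside a
single-channel OFF. Maximal stretches with `n ≥ quorum` (12 of 16) lasting
50–400 ms are global OFF periods; maximal sub-quorum stretches of
50–2000 ms are global ON periods. Stretches violating their duration bound
are labelled `unclassified`, not truncated — truncation would fabricate
boundaries the data do not contain. A consequence worth noting: total
*classified* OFF time is not monotone in the quorum (raising the quorum
can shorten an over-long stretch into the classifiable range); the
monotone quantity is quorum-occupancy time (classified plus over-long),
and that is what the invariant tests assert. Channel counts other than 16
require an explicit quorum; there is no silent 12/16 rescaling.

Fallback mode (for recordings with channels too quiet for the flanking
rule): every gap ≥ 50 ms in the merged all-channel train is an OFF period,
edges included; an empty recording is one OFF. The mode is explicit
configuration, never switched automatically.

Detected OFF boundaries are systematically wider than the underlying
population silence: a channel's OFF starts at its last spike before the
silence, on average `1/rate` early. At the default 80 Hz nominal ON rate
the quorum crossing adds ≈ 4–5 ms per edge, a +7% bias on the mean
duration of ~125-ms events — visible in the recovery numbers and inherent
to spike-defined silence, not a detector artifact.

## Spectral estimation

Multitaper short-time PSD: 4-s DPSS windows, time–half-bandwidth NW = 4,
2·NW − 1 = 7 tapers weighted by their eigenvalues, 50% overlap (2-s hop).
Each window is detrended (constant removal) before tapering so DC cannot
leak into delta. PSD is one-sided power per Hz, so a band integral equals
that band's variance contribution: a unit 2-Hz sinusoid yields delta power
0.5. Band power is the trapezoidal integral over the band
(delta 0.5–4, theta 4–8, alpha 8–13, sigma 11–16, beta 13–30 Hz); bands
sharing edges on the 0.25-Hz grid sum exactly to the integral of their
union. Normalization divides each channel by its mean over windows whose
centers fall in reference windows (baseline NREM), or per window by a
channel-matched partner series (contralateral probe). Channels are
normalized first and averaged after.

## OFF-locked waveform metrics

LFP snippets (default 1 s each side — covering the longest global OFF plus
flanks) are aligned to OFF start, end or midpoint; events whose snippet
crosses a recording edge are dropped; an optional event cap supports
first-N-event subsetting. On the across-event mean waveform:

- **initiation slope** — Savitzky–Golay smooth (window 11 samples,
  polyorder 3 at 400 Hz: ≈ 27 ms, wide enough to suppress noise, narrow
  enough not to flatten a 30-ms rise), first difference × sample rate,
  maximum over ±10 samples of the OFF start;
- **termination slope** — identical, aligned to the OFF end;
- **peak amplitude** — extremum of the mean waveform within ±20 samples of
  the OFF midpoint; signed maximum for positive-going slow waves, signed
  minimum under the negative-polarity option.

The smoother is exact on polynomials up to its order, so ramp slopes are
recovered exactly; on the generator's smooth slow-wave kernel the measured
maximum is within 0.5% of the closed-form derivative maximum when the
maximizing point lies in the window interior. Slopes are invariant to DC
offsets and scale linearly with the signal. Metrics are computed on the
event-locked average only; single-trial slopes are far too noisy at
realistic LFP noise levels.

## STTC

For trains A, B restricted to a window: `T_A` is the proportion of A
spikes with at least one B spike within ±5 ms; `P_A` is the measure of the
union of ±5 ms tiles around A's spikes, clipped to the window, over the
window duration. The default formula pairs each train's coincidence
proportion with its **own** tiling fraction,

    STTC = ½ [ (T_A − P_A)/(1 − T_A·P_A) + (T_B − P_B)/(1 − T_B·P_B) ],

`formula="cutts_eglen"` gives the original cross-paired variant
(`T_A` with `P_B`). The two coincide for identical trains and whenever
`P_A = P_B`, and differ measurably for rate-asymmetric pairs; both are
bounded in [−1, 1] and exposed so users can compare. Empty trains and
degenerate denominators yield missing values (NaN), never zero — absence
of evidence is not zero synchrony. Per condition, the coefficient is
computed per continuous bout (epoch) and averaged across epochs in
coefficient space for display; Fisher-Z (`atanh`, clipped to
±(1 − 10⁻⁶), so r = 1 maps to 7.2543) is applied for condition means,
differences and tests. Bouts shorter than 2·dt are skipped (tiling
ill-defined).

## Conditions and statistics

Recovery sleep is the first 3600 s of *cumulative* NREM after the end of
sleep deprivation, truncating the final bout mid-bout — the only reading
that yields exactly one hour; the circadian-matched window runs the same
accumulation starting exactly 24 h before the recovery start, so shifting
a hypnogram by +24 h maps one onto the other identically. A quota that
cannot be met returns a short window with an explicit flag rather than an
error.

The statistics harness delegates to scipy/statsmodels/pingouin and adds
only the gating and bookkeeping: Shapiro–Wilk (α = 0.05) on paired
differences (or each group) selects paired/unpaired t versus Wilcoxon
signed-rank/Mann–Whitney U; families are adjusted with Benjamini–Hochberg;
three or more groups gate on Levene's test between classic and Welch ANOVA
with Tukey HSD contrasts. Effect sizes: Hedge's g with
J = 1 − 3/(4·df − 1) (paired designs standardize by the SD of
differences), matched-pairs rank-biserial for Wilcoxon, rank-biserial from
U for Mann–Whitney, partial eta-squared for ANOVA. Under a paired normal
null (n = 10) the gated test's measured type-I rate is 0.051 at 20 000
replicates.

## Video actigraphy

Movement is `(ΔX² + ΔY²)` per node per frame transition (1 frame/s),
averaged across nodes; the series is robust Z-scored
(`z = (m − median)/(1.4826·MAD)`), and frames with `z` below
`τ = −mean/std` are sleep. The mean and std defining τ are taken from the
**raw** movement series by default. The alternative reading — mean/std of
the z-series itself — is implemented (`threshold_stats="zscored"`) but not
default: because movement is non-negative and right-skewed, the z-series
mean is positive whenever quiescence holds the median, which pushes τ into
the body of the *active* movement distribution and mislabels several
percent of frames; the raw-series statistics place τ in the silent gap
between the quiescent and active clusters. Both readings assume the
recording is not dominated by sleep (the median must not sit so deep in
the quiescent cluster that the scale collapses); the method targets
recordings such as sleep-deprivation days where wake holds the majority of
frames. Degenerate series fall back from MAD to standard-deviation
scaling, and to all-wake labels when no variation exists at all.
Total-sleep-fraction error compares the predicted sleep fraction with the
hypnogram's NREM + REM + IS fraction over a common window. The novelty
ratio is the fraction of test-phase frames (first 300 s) with the nose
node on the novel-texture side of the arena split.

## Synthetic session generator

The generator produces the statistical structure the analyses assume,
with exported ground truth, from a single seeded RNG (identical configs
give bit-identical sessions).

- **Hypnogram**: wake episodes alternate with sleep episodes holding a
  geometric number (mean 5) of NREM bouts, each followed by REM with
  probability 0.25; log-normal bout durations (medians 1400/180/90 s,
  shapes 0.6/0.5/0.4). Over 24 h this yields sleep fractions of
  0.40 ± 0.04 — the regime of the actigraphy validation recordings.
- **Population OFF events**: a renewal process inside NREM bouts — onset
  gap = 100 ms minimum ON gap + exponential, duration log-normal
  (median 120 ms, shape 0.25, safely inside the 50–400 ms detection
  bounds), rate 0.5 events/s; configs whose rate × (mean duration + gap)
  reach 1 are rejected as an overlapping regime. Events never cross bout
  edges.
- **Per-channel membership**: each channel joins an event with
  probability 0.95 and jitters entry/exit by Normal(0, 2 ms), truncated at
  ±3 SD so every membership stays inside the dilated population event.
  Jitter is the synchrony dial: raising it lowers across-channel overlap,
  STTC, OFF-locked slope and peak monotonically.
- **Spikes**: Poisson at 80 Hz nominal per channel outside the channel's
  OFF memberships (0 Hz inside by default), thinned by a 2.5-ms dead time
  (realized rate ≈ 66 Hz). The dead time mirrors the fact that
  threshold-detected MUA cannot contain sub-millisecond doublets; setting
  `refractory_ms = 0` restores a plain Poisson process. MUA-scale rates
  are deliberate: OFF boundaries are defined by last/first spikes, and the
  boundary bias scales as 1/rate.
- **LFP** (400 Hz): per channel, a smooth asymmetric-Gaussian slow-wave
  bump (rise SD 30 ms, decay SD 120 ms, peak amplitude 0.5 mV, polarity
  configurable for positive-going versus negative-going slow-wave
  phenotypes) centred on each of the channel's own jittered OFF midpoints,
  over 1/f background noise (exponent 1.0, RMS 0.1 mV). The bump is C¹
  with an analytic derivative, giving the slope metrics a closed-form
  oracle; its second derivative jumps at the peak, so slope-accuracy tests
  use event durations that keep the smoothing window off the peak.
- **EMG** (1017 Hz): white noise with state-dependent RMS
  (wake 0.10, NREM 0.03, REM 0.01 mV).
- **Pose** (1 frame/s, 8 nodes): a common body random walk — log-normal
  step magnitude (shape 0.5) normalized so the mean squared per-frame
  displacement is `2·step_sd²` (wake 8 px, sleep 0.05 px), uniform
  heading — plus independent per-node Gaussian jitter (0.5/0.1 px)
  modelling pose-estimation noise. Nodes ride on one body because a
  mouse's tracked points move together; independent per-node walks would
  average into an unrealistically concentrated movement statistic.
- **Wideband** (24414.0625 Hz): unit Gaussian noise plus a stereotyped
  biphasic template (sharp 0.06-ms trough, slower 0.15-ms rebound at 35%
  amplitude) at each ground-truth spike time, snapped to the sample grid;
  trough amplitude in units of the noise SD sets the SNR.
- **Protocols**: staged pulse trains (default 1 Hz/180 ms × 10 min,
  2 Hz/140 ms × 10 min, 3 Hz/100 ms × 5 min with 45-s breaks, then
  3 Hz/80 ms bouts with 30-s breaks repeating until sleep onset, truncated
  there so no light is emitted at or after onset).

### What the generator does not emulate

No biophysics: firing is gated Poisson, not conductance dynamics; slow
waves are stereotyped kernels, not emergent network events; there is no
spindle/theta structure, no travelling-wave topography across the probe,
no electrode drift, movement artifact or line noise; pose has no grooming
or rearing micro-movements. Passing recovery tests therefore demonstrates
that the implementations are correct and well-calibrated under the stated
statistical model — not that real recordings meet that model.

## Problem sizes in the test and acceptance runs

Suites are sized to finish comfortably on one CPU: oracle equivalence runs
1000 random 16-channel 10-s instances; STTC calibration uses 200
independent 5-Hz/300-s pairs, 10⁴ random pairs for symmetry/bounds and 500
instances against the quadratic oracle; monotonicity experiments use
1200-s pure-NREM sessions with paired seeds (10 per condition), which
makes the jitter contrasts deterministic-grade by sharing the event
skeleton across jitter levels; spike recovery uses 20-s, 16-channel
wideband; actigraphy validation uses twenty 24-h sessions; the type-I
calibration uses 2000 replicates. `scripts/acceptance.py` re-measures the
same quantities from scratch at the seed given on the command line.

## Known limitations

The boundary bias of spike-defined OFF periods (above) is not corrected;
analyses that compare conditions are unaffected because the bias is common
to both sides. `sttc_condition` loops over channel pairs per epoch in
Python — fine for 16 channels and hour-long conditions, not tuned for
hundreds of channels. The actigraphy threshold is undefined-by-design on
sleep-dominated recordings (documented above). The statistics harness
covers the designs used in practice (paired/unpaired two-sample, one-way
multi-group); it does not implement mixed-effects or two-way designs.
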