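# onoff

Analysis pipeline for cortical **ON/OFF-period** dynamics in multichannel
sleep electrophysiology, with a ground-truth synthetic session generator.

During NREM sleep, cortical populations alternate between periods of
sustained firing (ON) and near-complete silence (OFF); the density and
synchrony of OFF periods track sleep pressure and drive the slow waves
visible in the field potential. This package implements the full analysis
chain needed to quantify that biology from a chronically implanted
16-channel probe plus EEG/EMG and overhead video:

- **MUA spike detection** — zero-phase 300–12000 Hz band-pass, per-sample
  common median reference, MAD noise estimate (σ = MAD/0.6745), peaks
  beyond 4σ, firing rates in 2-s windows.
- **OFF-period detection** — single-channel rule (ON = spike run with all
  inter-spike intervals < 50 ms; OFF = silence ≥ 50 ms with a flanking ON
  ≥ 30 ms) and a population rule: a **global OFF** is a maximal stretch
  where ≥ 12 of 16 channels are simultaneously OFF for 50–400 ms, a
  **global ON** a sub-quorum stretch of 50–2000 ms. A fallback definition
  (all-channel silence ≥ 50 ms) covers low-MUA recordings.
- **Slow-wave activity (SWA)** — multitaper (DPSS, 4-s windows, NW = 4,
  7 tapers, 50% overlap) power spectra; SWA = ∫ PSD over 0.5–4 Hz,
  normalized to a baseline NREM mean or a contralateral probe.
- **Spike-time tiling coefficient (STTC)** — rate-robust pairwise spike
  synchrony with a ±5 ms coincidence window,
  `STTC = ½[(T_A − P_A)/(1 − T_A·P_A) + (T_B − P_B)/(1 − T_B·P_B)]`,
  computed per epoch and averaged per condition, with Fisher-Z
  (`z = atanh(r)`, clipped at 1 − 10⁻⁶) for statistics.
- **OFF-locked waveform metrics** — event-locked LFP averages; maximal
  Savitzky–Golay-smoothed derivative within ±10 samples of OFF start/end
  (initiation/termination slope) and the peak within ±20 samples of the
  OFF midpoint.
- **Conditions & statistics** — baseline / recovery ("first hour of
  cumulative NREM after sleep deprivation", truncated to exactly 3600 s) /
  circadian-matched windows; Shapiro–Wilk-gated paired tests, BH-FDR,
  Levene-gated (Welch) ANOVA with Tukey HSD; Hedge's g and rank-biserial
  effect sizes.
- **Video actigraphy** — node-averaged squared pose displacement
  (ΔX² + ΔY²), robust Z-scoring, a single `-mean/std` threshold for
  sleep/wake, total-sleep-fraction error against a scored hypnogram, and
  the floor-texture-task novelty ratio.
- **Synthetic sessions** (`onoff.synth`) — vigilance-state bout structure,
  a renewal process of population OFF events with log-normal durations,
  per-channel participation and entry/exit jitter (the synchrony dial),
  dead-time Poisson firing, OFF-locked slow waves of either polarity over
  1/f noise, EMG tone, laser pulse protocols, pose tracks, and wideband
  traces with injected spike templates — all with exported ground truth.

## Worked example

Simulate ten minutes of NREM with the default bistability (0.5 OFF
events/s, log-normal durations with 120 ms median, 2 ms channel jitter)
and run the core analyses:

```python
from onoff import (GeneratorConfig, simulate_session, detect_off_periods,
                   off_statistics, match_events, sttc_condition,
                   spectrogram, bandpower, IntervalSet, Hypnogram)

cfg = GeneratorConfig(seed=7, session_length=600.0,
                      state_schedule=Hypnogram(["NREM"], [0.0], [600.0]))
spikes, lfp, emg, truth = simulate_session(cfg)

det = detect_off_periods(spikes)
win = IntervalSet.from_arrays([0.0], [600.0], "nrem")
freq, dur = off_statistics(det["global_off"], win)
hit = match_events(det["global_off"], truth.population_off)
swa = bandpower(spectrogram(lfp), "delta").values.mean()
sttc = sttc_condition(spikes, win).offdiag_mean()
```

Output:

```
global OFF periods:   298
OFF frequency:        29.8 events/min
mean OFF duration:    126.2 ms
ground-truth hit rate: 99.7%
NREM SWA (0.5-4 Hz):  0.0119 mV^2
mean pairwise STTC:   0.0383
```

The detector recovers 99.7% of the generator's population silence events;
the frequency matches the configured 30/min, and the mean detected
duration exceeds the true event duration by a few milliseconds because a
channel's OFF period is bounded by its last/first spikes. SWA here is raw
delta-band power (mV²); condition analyses express it relative to a
baseline NREM mean. The mean STTC of ~0.04 reflects synchrony carried
purely by the shared silence events — independent Poisson trains give
0.00.

A command-line mirror exists for every stage
(`onoff simulate | detect-spikes | lfp | detect-off | psd | bandpower |
off-metrics | sttc | actigraphy | ftr-ratio | conditions | stats | run`);
`onoff run --out-dir RUN` executes the whole synthetic pipeline and writes
a hash-based manifest that makes re-runs resumable.

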