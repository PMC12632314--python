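"""Synthetic session generator with known ground truth.

Emulates the statistical structure the analysis stages assume: a vigilance
hypnogram (Wake/NREM/REM bouts), bistable ON/OFF population activity inside
NREM (a renewal process of population silence events with log-normal
durations), per-channel participation and entry/exit jitter (the synchrony
dial), Poisson multi-unit firing gated by the OFF events, OFF-locked slow
waves of configurable polarity over 1/f background noise, state-dependent
EMG tone, laser pulse protocols and overhead-video pose trajectories.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so identical configs produce bit-identical sessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import (
    ContinuousTraces,
    Hypnogram,
    IntervalSet,
    PoseTrack,
    SpikeTrainSet,
    StimulationProtocol,
    StimulationStage,
    SLEEP_STATES,
)

log = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "sample_hypnogram",
    "simulate_session",
    "simulate_pose",
    "simulate_wideband",
    "generate_protocol",
    "default_induction_protocol",
    "slow_wave_kernel",
    "spike_template",
]


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic session.

    Durations of OFF events and jitter are in milliseconds (the scale on
    which they are usually quoted); everything else is seconds, Hz, mV or
    pixels as annotated.
    """

    seed: int = 0
    n_channels: int = 16
    session_length: float = 600.0                 # s
    state_schedule: Hypnogram | None = None       # explicit hypnogram wins

    # hypnogram bout sampling (log-normal medians/shapes, seconds)
    wake_bout_median: float = 1400.0
    wake_bout_shape: float = 0.6
    nrem_bout_median: float = 180.0
    nrem_bout_shape: float = 0.5
    rem_bout_median: float = 90.0
    rem_bout_shape: float = 0.4
    rem_prob: float = 0.25          # chance of a REM bout after a NREM bout
    nrem_bouts_per_episode: float = 4.0

    # population OFF process (NREM only)
    off_rate_nrem: float = 0.5                    # events / s of NREM
    off_duration_median_ms: float = 120.0
    off_duration_shape: float = 0.25
    min_on_gap_ms: float = 100.0                  # renewal refractoriness
    channel_jitter_sd_ms: float = 2.0             # entry/exit jitter SD
    participation_prob: float = 0.95

    # firing
    on_firing_rate: float = 80.0                  # Hz per channel
    off_firing_rate: float = 0.0                  # Hz inside OFF membership
    refractory_ms: float = 2.5                    # spike-train dead time

    # LFP
    lfp_rate: float = 400.0                       # Hz
    lfp_polarity: str = "positive"                # {"positive", "negative"}
    kernel_amplitude_mv: float = 0.5
    kernel_rise_ms: float = 30.0
    kernel_decay_ms: float = 120.0
    noise_exponent: float = 1.0                   # 1/f^a background
    noise_rms_mv: float = 0.1

    # EMG
    emg_rate: float = 1017.0
    emg_rms_by_state: dict = field(default_factory=lambda: {
        "Wake": 0.10, "NREM": 0.03, "REM": 0.01,
        "IS": 0.02, "Unsure": 0.05, "Artifact": 0.20,
    })

    # pose
    pose_frame_rate: float = 1.0                  # Hz (1 frame per second)
    n_pose_nodes: int = 8
    pose_step_sd_by_state: dict = field(default_factory=lambda: {
        "Wake": 8.0, "NREM": 0.05, "REM": 0.05,
        "IS": 0.05, "Unsure": 1.0, "Artifact": 1.0,
    })
    pose_node_jitter_by_state: dict = field(default_factory=lambda: {
        "Wake": 0.5, "NREM": 0.1, "REM": 0.1,
        "IS": 0.1, "Unsure": 0.2, "Artifact": 0.2,
    })
    pose_speed_shape: float = 0.5   # log-normal sigma of body step magnitude

    # which signals to synthesize
    make_lfp: bool = True
    make_emg: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.participation_prob <= 1):
            raise ValueError("participation_prob must be in [0, 1]")
        if self.channel_jitter_sd_ms < 0:
            raise ValueError("channel_jitter_sd must be >= 0")
        if self.lfp_polarity not in ("positive", "negative"):
            raise ValueError("lfp_polarity must be 'positive' or 'negative'")
        mean_dur = (self.off_duration_median_ms / 1000.0) * np.exp(
            self.off_duration_shape**2 / 2
        )
        if self.off_rate_nrem * (mean_dur + self.min_on_gap_ms / 1000.0) >= 1.0:
            raise ValueError(
                "off_rate_nrem x (mean OFF duration + minimum ON gap) >= 1: "
                "OFF events would overlap"
            )


@dataclass
class GroundTruth:
    """Generator-side truth against which detections are scored."""

    population_off: IntervalSet
    per_channel_off: list[IntervalSet]
    hypnogram: Hypnogram
    laser: IntervalSet
    true_sleep_fraction: float


# -------------------------------------------------------------- hypnogram --

def sample_hypnogram(config: GeneratorConfig, rng: np.random.Generator) -> Hypnogram:
    """Sample a Wake/NREM/REM bout sequence covering the session.

    Wake episodes alternate with sleep episodes; a sleep episode holds a
    geometric number of NREM bouts, each optionally followed by REM.  Bout
    durations are log-normal.  The final bout is truncated at session end.
    """
    T = config.session_length
    bouts: list[tuple[str, float, float]] = []
    t = 0.0

    def add(state: str, dur: float) -> float:
        nonlocal t
        end = min(t + dur, T)
        if end > t:
            bouts.append((state, t, end))
        t = end
        return t

    while t < T:
        add("Wake", rng.lognormal(np.log(config.wake_bout_median), config.wake_bout_shape))
        if t >= T:
            break
        n_nrem = 1 + rng.geometric(1.0 / config.nrem_bouts_per_episode)
        for _ in range(n_nrem):
            add("NREM", rng.lognormal(np.log(config.nrem_bout_median), config.nrem_bout_shape))
            if t >= T:
                break
            if rng.random() < config.rem_prob:
                add("REM", rng.lognormal(np.log(config.rem_bout_median), config.rem_bout_shape))
                if t >= T:
                    break

    states, starts, ends = zip(*bouts)
    return Hypnogram(list(states), np.array(starts), np.array(ends))


# ------------------------------------------------------------- OFF events --

def _population_off_events(config: GeneratorConfig, hyp: Hypnogram,
                           rng: np.random.Generator) -> IntervalSet:
    """Renewal process of population OFF events inside NREM bouts.

    Inter-onset gap = minimum ON gap + exponential; events that would cross
    the bout end are dropped, so every event lies fully inside one bout.
    """
    rate = config.off_rate_nrem
    if rate <= 0:
        return IntervalSet()
    mean_dur = (config.off_duration_median_ms / 1000.0) * np.exp(
        config.off_duration_shape**2 / 2
    )
    min_gap = config.min_on_gap_ms / 1000.0
    exp_mean = max(1.0 / rate - mean_dur - min_gap, 1e-3)
    mu = np.log(config.off_duration_median_ms / 1000.0)
    out = []
    for state, s, e in zip(hyp.states, hyp.starts, hyp.ends):
        if state != "NREM":
            continue
        t = s + min_gap + rng.exponential(exp_mean)
        while True:
            dur = rng.lognormal(mu, config.off_duration_shape)
            if t + dur >= e:
                break
            out.append((t, t + dur, "population_off"))
            t = t + dur + min_gap + rng.exponential(exp_mean)
    return IntervalSet.from_tuples(out)


def _per_channel_offs(config: GeneratorConfig, pop: IntervalSet,
                      rng: np.random.Generator) -> list[IntervalSet]:
    """Jittered, Bernoulli-thinned per-channel membership of each event.

    Entry/exit jitter is Normal(0, sd) truncated at +/-3 sd so that every
    per-channel OFF stays inside the population event dilated by 3 sd.
    """
    sd = config.channel_jitter_sd_ms / 1000.0
    n_ev = len(pop)
    out = []
    for _ in range(config.n_channels):
        participates = rng.random(n_ev) < config.participation_prob
        j_in = np.clip(rng.normal(0.0, sd, n_ev), -3 * sd, 3 * sd) if sd else np.zeros(n_ev)
        j_out = np.clip(rng.normal(0.0, sd, n_ev), -3 * sd, 3 * sd) if sd else np.zeros(n_ev)
        s = pop.starts + j_in
        e = pop.ends + j_out
        keep = participates & (e > s)
        out.append(IntervalSet.from_arrays(s[keep], e[keep], "channel_off"))
    return out


# ----------------------------------------------------------------- spikes --

def _enforce_dead_time(t: np.ndarray, refractory: float) -> np.ndarray:
    """Greedy thinning: drop any spike closer than ``refractory`` to the
    previously kept spike."""
    if refractory <= 0 or t.size < 2:
        return t
    keep = np.ones(t.size, dtype=bool)
    last = t[0]
    for i in range(1, t.size):
        if t[i] - last < refractory:
            keep[i] = False
        else:
            last = t[i]
    return t[keep]


def _delete_in_intervals(t: np.ndarray, iv: IntervalSet) -> np.ndarray:
    if not len(iv) or not t.size:
        return t
    lo = np.searchsorted(t, iv.starts, side="left")
    hi = np.searchsorted(t, iv.ends, side="left")
    drop = np.zeros(t.size, dtype=bool)
    for a, b in zip(lo, hi):
        drop[a:b] = True
    return t[~drop]


def _poisson_train(rate: float, T: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * T)
    return np.sort(rng.uniform(0.0, T, n))


def _channel_spikes(config: GeneratorConfig, off: IntervalSet,
                    rng: np.random.Generator) -> np.ndarray:
    T = config.session_length
    t = _poisson_train(config.on_firing_rate, T, rng)
    t = _delete_in_intervals(t, off)
    if config.off_firing_rate > 0 and len(off):
        extra = []
        for s, e, _ in off:
            extra.append(s + _poisson_train(config.off_firing_rate, e - s, rng))
        t = np.sort(np.concatenate([t] + extra))
    t = _enforce_dead_time(t, config.refractory_ms / 1000.0)
    # strict monotonicity for the container (dead time already guarantees it
    # unless refractory is 0, where exact ties are conceivable)
    if t.size > 1:
        t = t[np.insert(np.diff(t) > 0, 0, True)]
    return t


# -------------------------------------------------------------------- LFP --

def slow_wave_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak asymmetric-Gaussian slow-wave kernel.

    Rises with SD ``rise_s`` for t < 0 and decays with SD ``decay_s`` for
    t >= 0; the peak (value 1) sits at t = 0.  Smooth everywhere, so its
    derivative has a closed form usable as an oracle for slope metrics.
    """
    t = np.asarray(t, dtype=np.float64)
    out = np.where(
        t < 0,
        np.exp(-0.5 * (t / rise_s) ** 2),
        np.exp(-0.5 * (t / decay_s) ** 2),
    )
    return out


def slow_wave_kernel_derivative(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Closed-form time derivative of :func:`slow_wave_kernel` (1/s units)."""
    t = np.asarray(t, dtype=np.float64)
    return np.where(
        t < 0,
        -t / rise_s**2 * np.exp(-0.5 * (t / rise_s) ** 2),
        -t / decay_s**2 * np.exp(-0.5 * (t / decay_s) ** 2),
    )


def _one_over_f_noise(n: int, exponent: float, rms: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise with unit slope exponent and target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _render_lfp(config: GeneratorConfig, per_channel_off: list[IntervalSet],
                rng: np.random.Generator) -> ContinuousTraces:
    fs = config.lfp_rate
    n = int(round(config.session_length * fs))
    sign = 1.0 if config.lfp_polarity == "positive" else -1.0
    amp = sign * config.kernel_amplitude_mv
    rise = config.kernel_rise_ms / 1000.0
    decay = config.kernel_decay_ms / 1000.0
    half = int(np.ceil(4 * max(rise, decay) * fs))
    lag_t = np.arange(-half, half + 1) / fs
    kern_lags = np.arange(-half, half + 1)
    data = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        x = _one_over_f_noise(n, config.noise_exponent, config.noise_rms_mv, rng)
        off = per_channel_off[c]
        if len(off):
            mids = off.midpoints()
            centers = np.round(mids * fs).astype(np.int64)
            frac = mids * fs - centers  # sub-sample alignment
            for ctr, fr in zip(centers, frac):
                i0 = max(0, ctr - half)
                i1 = min(n, ctr + half + 1)
                if i1 <= i0:
                    continue
                seg = kern_lags[(i0 - ctr + half):(i1 - ctr + half)]
                x[i0:i1] += amp * slow_wave_kernel((seg - fr) / fs, rise, decay)
        data[c] = x
    ids = [f"ch{c:02d}" for c in range(config.n_channels)]
    return ContinuousTraces(data, fs, ids, t0=0.0, kind="lfp")


# -------------------------------------------------------------------- EMG --

def _render_emg(config: GeneratorConfig, hyp: Hypnogram,
                rng: np.random.Generator) -> ContinuousTraces:
    fs = config.emg_rate
    n = int(round(config.session_length * fs))
    x = rng.standard_normal(n)
    rms = np.full(n, config.emg_rms_by_state.get("Wake", 0.1))
    for state, s, e in zip(hyp.states, hyp.starts, hyp.ends):
        i0, i1 = int(s * fs), min(n, int(np.ceil(e * fs)))
        rms[i0:i1] = config.emg_rms_by_state.get(state, 0.05)
    return ContinuousTraces((x * rms)[None, :], fs, ["emg"], t0=0.0, kind="emg")


# ----------------------------------------------------------------- public --

def simulate_session(
    config: GeneratorConfig,
    protocol: StimulationProtocol | None = None,
    protocol_start: float = 0.0,
) -> tuple[SpikeTrainSet, ContinuousTraces | None, ContinuousTraces | None, GroundTruth]:
    """Generate one session: spikes, LFP, EMG and ground truth.

    Population OFF events arrive as a renewal process inside NREM bouts;
    each channel joins an event with ``participation_prob`` and jitters its
    entry/exit; firing is Poisson (with a short dead time) at
    ``on_firing_rate`` outside the channel's OFF memberships; the LFP is a
    sum of slow-wave kernels centred on the channel's OFF midpoints plus
    1/f noise.  Identical configs give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    hyp = config.state_schedule or sample_hypnogram(config, rng)
    pop = _population_off_events(config, hyp, rng)
    per_off = _per_channel_offs(config, pop, rng)

    trains = [_channel_spikes(config, per_off[c], rng) for c in range(config.n_channels)]
    ids = [f"ch{c:02d}" for c in range(config.n_channels)]
    spikes = SpikeTrainSet(trains, duration=config.session_length, channel_ids=ids)

    lfp = _render_lfp(config, per_off, rng) if config.make_lfp else None
    emg = _render_emg(config, hyp, rng) if config.make_emg else None

    laser = IntervalSet()
    if protocol is not None:
        laser = generate_protocol(protocol, start=protocol_start)

    span = hyp.ends[-1] - hyp.starts[0]
    sleep = sum(e - s for st, s, e in zip(hyp.states, hyp.starts, hyp.ends)
                if st in SLEEP_STATES)
    truth = GroundTruth(
        population_off=pop,
        per_channel_off=per_off,
        hypnogram=hyp,
        laser=laser,
        true_sleep_fraction=float(sleep / span),
    )
    return spikes, lfp, emg, truth


# ------------------------------------------------------------------- pose --

def simulate_pose(hyp: Hypnogram, config: GeneratorConfig,
                  rng: np.random.Generator | None = None) -> PoseTrack:
    """Overhead-video pose track at ``pose_frame_rate``.

    The body centroid performs a random walk whose per-frame step magnitude
    is log-normal (shape ``pose_speed_shape``), normalized so that the mean
    squared displacement per frame is ``2 * step_sd**2`` (the sum over both
    axes); the heading is uniform.  Nodes ride on the centroid at fixed
    offsets plus independent per-frame Gaussian jitter (pose-model noise).
    Sleep states get near-zero steps and jitter.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t0, t1 = hyp.span()
    n_frames = int(np.floor((t1 - t0) * config.pose_frame_rate)) + 1
    times = t0 + np.arange(n_frames) / config.pose_frame_rate

    # per-frame state lookup
    idx = np.searchsorted(hyp.starts, times, side="right") - 1
    idx = np.clip(idx, 0, len(hyp) - 1)
    states = [hyp.states[i] for i in idx]

    step_sd = np.array([config.pose_step_sd_by_state.get(s, 0.0) for s in states])
    jit_sd = np.array([config.pose_node_jitter_by_state.get(s, 0.0) for s in states])

    sigma = config.pose_speed_shape
    # body step magnitude, E[mag^2] = 2 * step_sd^2
    mag = step_sd[:-1] * np.sqrt(2.0) * np.exp(
        sigma * rng.standard_normal(n_frames - 1) - sigma**2
    )
    heading = rng.uniform(0, 2 * np.pi, n_frames - 1)
    steps = np.column_stack([mag * np.cos(heading), mag * np.sin(heading)])
    body = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) + 300.0

    n_nodes = config.n_pose_nodes
    angles = 2 * np.pi * np.arange(n_nodes) / n_nodes
    offsets = 12.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    jitter = rng.standard_normal((n_frames, n_nodes, 2)) * jit_sd[:, None, None]
    positions = body[:, None, :] + offsets[None, :, :] + jitter

    names = ["nose", "head", "ear_l", "ear_r", "center", "shoulder", "hip", "tail"]
    if n_nodes != 8:
        names = [f"node{i}" for i in range(n_nodes)]
    return PoseTrack(positions, frame_rate=config.pose_frame_rate, node_names=names)


# --------------------------------------------------------------- wideband --

def spike_template(sample_rate: float) -> np.ndarray:
    """Stereotyped biphasic extracellular spike, unit trough depth.

    A sharp negative deflection (SD 0.06 ms, sample-accurate localization
    even in noise) followed by a slower positive rebound (0.35 of the
    trough, SD 0.15 ms, centred +0.35 ms).
    """
    t = np.arange(-25, 41) / sample_rate  # about -1 ms .. +1.6 ms
    trough = -np.exp(-0.5 * (t / 6.0e-5) ** 2)
    rebound = 0.35 * np.exp(-0.5 * ((t - 3.5e-4) / 1.5e-4) ** 2)
    return trough + rebound


def simulate_wideband(
    spikes: SpikeTrainSet,
    sample_rate: float = 24414.0625,
    noise_sigma: float = 1.0,
    amplitude_sigma: float = 10.0,
    seed: int = 0,
) -> tuple[ContinuousTraces, SpikeTrainSet]:
    """Wideband traces with spike templates over white Gaussian noise.

    Each spike places the template so its trough falls on the sample nearest
    the spike time; the returned :class:`SpikeTrainSet` carries these
    grid-snapped times (the ground truth for sample-accurate recovery).
    """
    rng = np.random.default_rng(seed)
    n = int(round(spikes.duration * sample_rate))
    tmpl = spike_template(sample_rate) * amplitude_sigma * noise_sigma
    trough_at = 25  # index of the template trough
    data = rng.standard_normal((spikes.n_channels, n)) * noise_sigma
    snapped = []
    for c, train in enumerate(spikes.trains):
        centers = np.round(train * sample_rate).astype(np.int64)
        centers = centers[(centers - trough_at >= 0) & (centers - trough_at + tmpl.size <= n)]
        for ctr in centers:
            i0 = ctr - trough_at
            data[c, i0:i0 + tmpl.size] += tmpl
        centers = np.unique(centers)
        snapped.append(centers / sample_rate)
    traces = ContinuousTraces(data, sample_rate, list(spikes.channel_ids),
                              t0=0.0, kind="wideband")
    truth = SpikeTrainSet(snapped, duration=spikes.duration,
                          channel_ids=list(spikes.channel_ids))
    return traces, truth


# --------------------------------------------------------------- protocol --

def default_induction_protocol() -> StimulationProtocol:
    """Four-stage OFF-induction pulse pattern.

    Stage 1: 1 Hz, 180 ms on, 10 min, 45 s break.  Stage 2: 2 Hz, 140 ms,
    10 min, 45 s break.  Stage 3: 3 Hz, 100 ms, 5 min, 45 s break.
    Stage 4: 3 Hz, 80 ms, 5 min bouts with 30 s breaks, repeated until
    sleep onset.
    """
    return StimulationProtocol([
        StimulationStage(1.0, 180.0, 600.0, 45.0),
        StimulationStage(2.0, 140.0, 600.0, 45.0),
        StimulationStage(3.0, 100.0, 300.0, 45.0),
        StimulationStage(3.0, 80.0, 300.0, 30.0, repeat_until_sleep=True),
    ])


def generate_protocol(
    protocol: StimulationProtocol,
    start: float = 0.0,
    sleep_onset: float | None = None,
) -> IntervalSet:
    """Expand a staged pulse protocol into laser-on intervals.

    Within a stage, pulses repeat every ``1/pulse_rate`` s with ``on_time``
    ms of light each; a break follows each stage.  A ``repeat_until_sleep``
    stage loops (stage + break) until ``sleep_onset`` and is truncated
    there: no light is emitted at or after sleep onset.  Labels are
    ``stage1``, ``stage2``, ... in protocol order.
    """
    if sleep_onset is not None and sleep_onset <= start:
        raise ValueError("sleep_onset must come after start")
    out: list[tuple[float, float, str]] = []
    t = start

    def emit_bout(stage: StimulationStage, t0: float, label: str) -> None:
        n_pulses = int(round(stage.stage_duration * stage.pulse_rate))
        period = 1.0 / stage.pulse_rate
        on = stage.on_time / 1000.0
        for i in range(n_pulses):
            s = t0 + i * period
            e = s + on
            if sleep_onset is not None:
                if s >= sleep_onset:
                    return
                e = min(e, sleep_onset)
            if e > s:
                out.append((s, e, label))

    for k, stage in enumerate(protocol.stages):
        label = f"stage{k + 1}"
        if stage.repeat_until_sleep and sleep_onset is not None:
            while t < sleep_onset:
                emit_bout(stage, t, label)
                t += stage.stage_duration + stage.break_duration
            break
        emit_bout(stage, t, label)
        t += stage.stage_duration + stage.break_duration
    return IntervalSet.from_tuples(out)
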