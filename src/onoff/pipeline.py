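"""End-to-end orchestration: simulate-or-load -> detect -> quantify.

A pipeline run executes the analysis stages in dependency order on one
session (synthetic by default), writing every stage's outputs under an
output directory together with a run manifest: the config snapshot, the
seed, and SHA-256 hashes of every stage's inputs and outputs.  Re-running
on an unchanged directory verifies hashes and skips completed stages;
deleting a stage output triggers recomputation of just that stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .actigraphy import classify_sleep, movement_series, sleep_fraction_error
from .config import AnalysisConfig
from .offperiods import detect_off_periods, off_statistics
from .spectral import bandpower, normalize, spectrogram
from .sttc import sttc_condition
from .synth import GeneratorConfig, simulate_pose, simulate_session
from .types import IntervalSet
from .waveforms import (
    event_locked_average,
    initiation_slope,
    off_peak_amplitude,
    termination_slope,
)

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    seed: int
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, inputs: list[Path], outputs: list[Path]) -> None:
        self.stages[stage] = {
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }

    def stage_is_current(self, stage: str, inputs: list[Path]) -> bool:
        entry = self.stages.get(stage)
        if entry is None:
            return False
        for p, digest in entry["outputs"].items():
            if not Path(p).exists() or _sha256(Path(p)) != digest:
                return False
        recorded = entry["inputs"]
        current = {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()}
        return recorded == current

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "config": self.config,
             "stages": self.stages, "warnings": self.warnings}, indent=1))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        obj = json.loads(Path(path).read_text())
        return cls(seed=obj["seed"], config=obj["config"],
                   stages=obj["stages"], warnings=obj.get("warnings", []))


def run_pipeline(
    gen_config: GeneratorConfig,
    analysis: AnalysisConfig | None = None,
    out_dir: str | Path = "onoff_run",
    resume: bool = True,
) -> RunManifest:
    """Run the full synthetic pipeline and write all stage outputs.

    Stages: simulate -> off detection -> SWA -> STTC -> OFF-locked
    waveform metrics -> actigraphy -> summary.  Deterministic given the
    generator config (which carries the seed).
    """
    analysis = analysis or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if analysis.off.n_channels != gen_config.n_channels:
        raise ValueError(
            f"config mismatch: generator has {gen_config.n_channels} channels, "
            f"OFF detection expects {analysis.off.n_channels}"
        )

    manifest_path = out / "manifest.json"
    config_snapshot = json.loads(json.dumps({
        "generator": dataclasses.asdict(
            dataclasses.replace(gen_config, state_schedule=None)
        ),
        "analysis": analysis.to_dict(),
    }))  # JSON round-trip so tuples compare equal against a loaded manifest
    if resume and manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        if manifest.config != config_snapshot:
            log.info("config changed; restarting pipeline from scratch")
            manifest = RunManifest(seed=gen_config.seed, config=config_snapshot)
    else:
        manifest = RunManifest(seed=gen_config.seed, config=config_snapshot)

    spikes_p = out / "spikes.tsv"
    lfp_p = out / "lfp"
    hyp_p = out / "hypnogram.tsv"
    truth_p = out / "ground_truth.tsv"
    pose_p = out / "pose.tsv"

    # ---- stage: simulate -------------------------------------------------
    sim_outputs = [spikes_p, Path(str(lfp_p) + ".bin"), hyp_p, truth_p, pose_p]
    if not (resume and manifest.stage_is_current("simulate", [])):
        spikes, lfp, emg, truth = simulate_session(gen_config)
        pose = simulate_pose(truth.hypnogram, gen_config,
                             rng=np.random.default_rng(gen_config.seed + 1))
        oio.write_spikes(spikes, spikes_p)
        oio.write_traces(lfp, lfp_p)
        if emg is not None:
            oio.write_traces(emg, out / "emg")
        oio.write_hypnogram(truth.hypnogram, hyp_p)
        oio.write_intervals(truth.population_off, truth_p)
        oio.write_pose(pose, pose_p)
        manifest.record("simulate", [], sim_outputs)
        manifest.save(manifest_path)
    else:
        log.info("simulate: outputs current, skipping")
        spikes = oio.read_spikes(spikes_p)
        lfp = oio.read_traces(lfp_p)
        truth = None
        pose = oio.read_pose(pose_p)
    hyp = oio.read_hypnogram(hyp_p)
    nrem = hyp.bouts_of("NREM")

    # ---- stage: OFF detection -------------------------------------------
    off_p = out / "off_intervals.tsv"
    if not (resume and manifest.stage_is_current("off", [spikes_p])):
        detected = detect_off_periods(spikes, analysis.off)
        rows = []
        for key in ("global_off", "global_on", "unclassified"):
            for s, e, l in detected[key]:
                rows.append((s, e, l))
        for c, iv in enumerate(detected["single_off"]):
            for s, e, _ in iv:
                rows.append((s, e, f"single_off:{spikes.channel_ids[c]}"))
        oio.write_intervals(IntervalSet.from_tuples(
            [(s, e, l) for s, e, l in rows]), off_p)
        manifest.record("off", [spikes_p], [off_p])
        manifest.save(manifest_path)
    off_iv = oio.read_intervals(off_p)
    global_off = off_iv.select("global_off")

    # ---- stage: SWA ------------------------------------------------------
    swa_p = out / "swa.tsv"
    if not (resume and manifest.stage_is_current("swa", [Path(str(lfp_p) + ".bin")])):
        spec = spectrogram(lfp, analysis.spectral)
        swa = bandpower(spec, "delta")
        try:
            swa_norm = normalize(swa, nrem, mode="baseline_nrem_mean")
            values = swa_norm.values
            normalization = swa_norm.normalization
        except ValueError:
            values = swa.values
            normalization = "none"
            manifest.warnings.append("no NREM reference; SWA left unnormalized")
        df = pd.DataFrame(values.T, columns=lfp.channel_ids)
        df.insert(0, "time_s", swa.times)
        df.to_csv(swa_p, sep="\t", index=False)
        manifest.record("swa", [Path(str(lfp_p) + ".bin")], [swa_p])
        manifest.save(manifest_path)

    # ---- stage: STTC -----------------------------------------------------
    sttc_p = out / "sttc.tsv"
    if len(nrem) and not (resume and manifest.stage_is_current("sttc", [spikes_p])):
        mat = sttc_condition(spikes, nrem, analysis.sttc, condition="nrem")
        pd.DataFrame(mat.values, index=mat.channel_ids,
                     columns=mat.channel_ids).to_csv(sttc_p, sep="\t")
        manifest.record("sttc", [spikes_p], [sttc_p])
        manifest.save(manifest_path)

    # ---- stage: waveform metrics ----------------------------------------
    wf_p = out / "waveform_metrics.tsv"
    if len(global_off) and not (
        resume and manifest.stage_is_current("waveforms", [off_p])
    ):
        rows = {}
        for align, fn in (
            ("off_start", initiation_slope),
            ("off_end", termination_slope),
        ):
            avg = event_locked_average(lfp, global_off, alignment=align)
            rows["initiation_slope" if align == "off_start" else
                 "termination_slope"] = fn(avg, analysis.savgol)
        avg = event_locked_average(lfp, global_off, alignment="off_midpoint")
        polarity = "positive" if gen_config.lfp_polarity == "positive" else "negative"
        rows["peak_amplitude"] = off_peak_amplitude(avg, polarity=polarity)
        df = pd.DataFrame(rows, index=lfp.channel_ids)
        df.index.name = "channel"
        df.to_csv(wf_p, sep="\t")
        manifest.record("waveforms", [off_p], [wf_p])
        manifest.save(manifest_path)

    # ---- stage: actigraphy ----------------------------------------------
    act_p = out / "actigraphy.tsv"
    if not (resume and manifest.stage_is_current("actigraphy", [pose_p])):
        mov = movement_series(pose)
        res = classify_sleep(mov, analysis.actigraphy)
        pd.DataFrame({
            "frame": np.arange(res.labels.size),
            "movement": mov.movement,
            "z": res.zscores,
            "sleep": res.labels.astype(int),
        }).to_csv(act_p, sep="\t", index=False)
        manifest.record("actigraphy", [pose_p], [act_p])
        manifest.save(manifest_path)

    # ---- stage: summary --------------------------------------------------
    summary_p = out / "summary.json"
    summary: dict = {"seed": gen_config.seed}
    if len(nrem):
        freq, dur = off_statistics(global_off, nrem)
        summary["off_frequency_per_min"] = freq
        summary["off_mean_duration_ms"] = dur
    act = pd.read_csv(act_p, sep="\t")
    summary["actigraphy_sleep_fraction"] = float(act["sleep"].mean())
    mov = movement_series(pose)
    res = classify_sleep(mov, analysis.actigraphy)
    span = hyp.span()
    summary["sleep_fraction_error"] = sleep_fraction_error(
        res, mov, hyp, IntervalSet.from_arrays([span[0]], [span[1]], "session"))
    summary_p.write_text(json.dumps(summary, indent=1))
    manifest.record("summary", [act_p], [summary_p])
    manifest.save(manifest_path)
    return manifest
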