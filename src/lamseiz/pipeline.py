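"""End-to-end orchestration: simulate -> preprocess -> detect -> csd -> mua
-> layer stats -> engagement -> ICA, as one reproducible run.

A single global seed fans out to per-stage child seeds by stable hashing of
the stage name, so enabling or disabling one stage never perturbs another
stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import csd as csd_mod
from . import detect as detect_mod
from . import ica as ica_mod
from . import io as io_mod
from . import mua as mua_mod
from . import preprocess as pre_mod
from . import synthetic as syn_mod
from . import temporal as temp_mod
from .laminar import LayerPartition, alternation_index, peak_layer_counts

STAGES = ("simulate", "preprocess", "detect", "csd", "mua", "analyze", "ica")
_DEPS = {
    "detect": ("preprocess",),
    "csd": ("preprocess",),
    "mua": ("preprocess",),
    "analyze": ("csd", "detect"),
    "ica": ("csd", "detect"),
}


class DependencyError(RuntimeError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    zone: str = "onset"
    out_dir: str | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    simulate_overrides: dict = field(default_factory=dict)
    detector: detect_mod.DetectorParams = field(default_factory=detect_mod.DetectorParams)
    preprocess: pre_mod.PreprocessParams = field(default_factory=pre_mod.PreprocessParams)
    mua_params: mua_mod.MuaParams = field(default_factory=mua_mod.MuaParams)
    n_ica_components: int = 8

    def validate(self) -> None:
        for stage, deps in _DEPS.items():
            if self.stages.get(stage, False):
                missing = [d for d in deps if not self.stages.get(d, False)]
                if missing:
                    raise DependencyError(
                        f"stage {stage!r} requires upstream stage(s) {missing}"
                    )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(
            seed=int(d.get("seed", 0)),
            zone=d.get("zone", "onset"),
            out_dir=d.get("out_dir"),
        )
        cfg.stages.update(d.get("stages", {}))
        cfg.simulate_overrides = d.get("simulate", {})
        if "detector" in d:
            cfg.detector = detect_mod.DetectorParams(**d["detector"])
        if "preprocess" in d:
            cfg.preprocess = pre_mod.PreprocessParams(**d["preprocess"])
        if "mua" in d:
            cfg.mua_params = mua_mod.MuaParams(**d["mua"])
        cfg.n_ica_components = int(d.get("n_ica_components", 8))
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return the report bundle (a dict; also
    written to ``out_dir`` as JSON/CSV when configured)."""
    config.validate()
    report: dict = {"seed": config.seed, "zone": config.zone}

    sim_cfg = syn_mod.default_config(
        config.zone, seed=stage_seed(config.seed, "simulate"), **config.simulate_overrides
    )
    rec, truth = syn_mod.simulate_seizure(sim_cfg)
    report["n_truth_discharges"] = int(truth.discharge_times_s.size)

    if config.stages.get("preprocess", True):
        rec = pre_mod.filter_bands(rec, config.preprocess)

    partition = LayerPartition.default(sim_cfg.n_contacts)
    ictal = rec.annotations["seizure"]
    preictal = rec.annotations["preictal"]

    detections = None
    if config.stages.get("detect", True):
        detections = detect_mod.detect_discharges(rec, config.detector)
        scores = detect_mod.evaluate_detection(
            detections.times_s, truth.discharge_times_s, rec.duration_s
        )
        report["detection"] = scores

    csdm = None
    if config.stages.get("csd", True):
        csdm = csd_mod.compute_csd(rec)
        norm = csd_mod.rescale_sinks_sources(csdm, scope=ictal)
        report["csd_range"] = [float(norm.values.min()), float(norm.values.max())]

    if config.stages.get("mua", True) and rec.mua is not None:
        rate = mua_mod.estimate_mua_rate(rec, config.mua_params)
        report["mua_deepest20_fraction"] = mua_mod.depth_fraction(rate, ictal, 0.2)

    if config.stages.get("analyze", True) and csdm is not None and detections is not None:
        counts = peak_layer_counts(csdm, detections.times_s, partition)
        report["peak_layer_counts"] = counts
        ai = alternation_index(
            csdm, detections.times_s, baseline_interval=preictal
        )
        report["alternation_index_max"] = float(np.nanmax(ai))
        binned = temp_mod.normalize_seizure_time(csdm, ictal)
        base = temp_mod.baseline_from_interval(
            csdm, preictal, (ictal[1] - ictal[0]) / 100.0
        )
        eng = temp_mod.engagement_matrix(binned, base, partition=partition)
        onsets = {}
        for g in partition.groups:
            r = temp_mod.engagement_onset(temp_mod.group_engagement_series(eng, g))
            onsets[g] = None if r is None else {"onset_percent": r[0], "p": r[1]}
        report["engagement_onsets"] = onsets

    if config.stages.get("ica", True) and csdm is not None and detections is not None:
        windows, kept, dropped = ica_mod.build_event_windows(csdm, detections.times_s)
        res = ica_mod.decompose(
            windows, kept, config.n_ica_components, seed=stage_seed(config.seed, "ica")
        )
        patt = ica_mod.count_patterns(res)
        report["n_patterns"] = patt.n_patterns
        report["pattern_switch_times_s"] = patt.switch_times_s
        report["ica_windows_dropped"] = dropped

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_mod.write_recording(rec, out / "recording.h5")
        if detections is not None:
            io_mod.write_event_csv(detections.events, out / "discharges.csv")
        io_mod.write_event_csv(
            io_mod.make_event_table(truth.discharge_times_s, label="truth"),
            out / "truth_discharges.csv",
        )
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        io_mod.write_provenance(
            out / "provenance.json",
            {"zone": config.zone, "stages": config.stages}, config.seed,
        )
    return report
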