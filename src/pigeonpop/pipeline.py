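"""End-to-end orchestration: simulate -> equalize -> classify -> compare ->
time-course -> state-space, with per-stage status, seeds and artifact
hashes recorded in a JSON report.

Every stage is a pure function of its declared inputs plus the configured
seeds, so re-running with the same configuration reproduces every artifact
bit for bit (verified by the recorded SHA-256 hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import frames as fr
from . import statespace as ss
from . import timecourse as tc
from .selectivity import classify_population, compare_regions, region_summary
from .simulate import NON_SELECTIVE, generate_frame_pair, make_population, simulate_spike_counts
from .stimuli import build_stimulus_set, schedule_session

log = logging.getLogger(__name__)

DEFAULT_LABEL_MIX = {
    "non_selective": 0.40,
    "visually_selective": 0.15,
    "actor_selective:pigeon": 0.12,
    "actor_selective:greeble": 0.06,
    "behavior_selective": 0.09,
    "actor_and_behavior": 0.12,
    "other:multi_behavior": 0.03,
    "other:two_pigeon": 0.03,
}


@dataclass
class AnalysisConfig:
    """All knobs of a pipeline run (timing constants in ms)."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    n_neurons_per_region: int = 30
    label_mix: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MIX))
    effect_size: float = 1.0
    event_gain: float = 1.0
    sound_modulated_fraction: float = 0.1
    sound_effect: float = 0.5
    alpha: float = 0.05
    bin_ms: int = 200
    step_ms: int = 40
    kernel_ms: int = 200
    baseline_trim_ms: int = 600
    family: str = "negbin"
    n_m2_videos: int = 2
    statespace_region: str = "MVL"
    stages: tuple = ("simulate", "equalize", "classify", "compare",
                     "timecourse", "statespace")
    data_path: str | None = None    # reuse an existing counts.csv

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("bin_ms", "step_ms", "kernel_ms", "baseline_trim_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.data_path is not None and not Path(self.data_path).exists():
            raise FileNotFoundError(f"data_path {self.data_path!r} not found")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the configured stages in order; failures mark the stage and
    subsequent dependents but still produce a partial report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    state: dict = {}

    def run_stage(name, fn):
        if name not in config.stages:
            report["stages"][name] = {"status": "skipped"}
            return
        t0 = time.time()
        try:
            artifacts = fn() or {}
            report["stages"][name] = {
                "status": "ok", "seconds": round(time.time() - t0, 2),
                "artifacts": {k: _sha256(Path(v)) for k, v in artifacts.items()},
                "paths": {k: str(v) for k, v in artifacts.items()},
            }
        except Exception as exc:   # stage failure -> partial report
            log.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}

    def stage_simulate():
        stim = build_stimulus_set(seed=config.seed)
        sched = schedule_session(stim, seed=config.seed + 1)
        pop = make_population(
            config.n_neurons_per_region, config.label_mix,
            effect_size=config.effect_size, seed=config.seed + 2,
            sound_modulated_fraction=config.sound_modulated_fraction,
            sound_effect=config.sound_effect)
        # transient pigeon-only event modulation rides on the
        # pigeon-selective units, on top of their sustained effect
        for neuron in pop:
            if neuron.label == "actor_selective:pigeon":
                neuron.event_gain = config.event_gain
                neuron.event_actors = ("pigeon",)
        table = simulate_spike_counts(sched, stim, pop, seed=config.seed + 3)
        state.update(stim=stim, pop=pop, table=table)
        counts_path = out / "counts.csv"
        table.to_csv(counts_path, index=False)
        sched_path = out / "schedule.csv"
        pd.DataFrame([dataclasses.asdict(t) for t in sched.trials]).to_csv(
            sched_path, index=False)
        truth_path = out / "ground_truth.json"
        truth_path.write_text(json.dumps(
            [{**dataclasses.asdict(n),
              "effect_map": {f"{a}.{b}": v for (a, b), v in n.effect_map.items()}}
             for n in pop], indent=1))
        return {"counts": counts_path, "schedule": sched_path,
                "ground_truth": truth_path}

    def stage_equalize():
        a, b, mask = generate_frame_pair(64, 64, seed=config.seed + 4)
        stack_a = fr.FrameStack(frames=[a], fg_masks=[mask])
        stack_b = fr.FrameStack(frames=[b], fg_masks=[mask])
        fg, bg = fr.compute_target_luminance([stack_a])
        matched = fr.luminance_match(stack_b, fg, bg)
        eq_a, eq_b = fr.spatial_frequency_match([stack_a, matched])
        dis = fr.frame_dissimilarity(eq_a, eq_b)
        path = out / "frame_dissimilarity.csv"
        pd.DataFrame({"frame": np.arange(len(dis)),
                      "correlation": dis}).to_csv(path, index=False)
        return {"dissimilarity": path}

    def _table():
        if "table" in state:
            return state["table"]
        if config.data_path is None:
            raise RuntimeError("no simulated data and no data_path configured")
        state["table"] = pd.read_csv(config.data_path)
        return state["table"]

    def stage_classify():
        table = _table()
        labels = {}
        for region, sub in table.groupby("region", sort=True):
            labels[region] = classify_population(sub, alpha=config.alpha)
        state["labels"] = labels
        path = out / "labels.json"
        path.write_text(json.dumps(
            {r: {n: lab.to_dict() for n, lab in labs.items()}
             for r, labs in labels.items()}, indent=1))
        summary = region_summary(
            {r: list(labs.values()) for r, labs in labels.items()})
        spath = out / "region_summary.csv"
        summary.to_csv(spath)
        return {"labels": path, "summary": spath}

    def stage_compare():
        labels = state["labels"]
        comparisons = {}
        for what, pred in (
                ("actor_selective", lambda l: l.category.startswith("actor_selective")),
                ("sound_modulated", lambda l: l.sound_modulated)):
            counts = {r: (sum(pred(l) for l in labs.values()), len(labs))
                      for r, labs in labels.items()}
            comparisons[what] = [dataclasses.asdict(c)
                                 for c in compare_regions(counts, what)]
        path = out / "region_comparisons.json"
        path.write_text(json.dumps(comparisons, indent=1, default=str))
        return {"comparisons": path}

    def stage_timecourse():
        table = _table()
        labels = state["labels"][config.statespace_region]
        pigeon_units = [n for n, lab in labels.items()
                        if lab.category == "actor_selective:pigeon"]
        sub = table[table["neuron_id"].isin(pigeon_units)]
        results = {}
        if sub["neuron_id"].nunique() >= 2:
            pairs = sorted(sub.loc[sub["behavior"] != "twoPigeon", "pair"]
                           .unique())[:config.n_m2_videos]
            for pair in pairs:
                fit = tc.fit_m2(sub, pair)
                bins = tc.significant_bins(fit, config.alpha, video=pair)
                actor = tc.actor_contrast_in_bins(
                    fit, [b.bin_index for b in bins])
                results[pair] = {
                    "significant_bins": [b.bin_index for b in bins],
                    "actor_contrasts": [vars(c) for c in actor],
                }
        path = out / "timecourse.json"
        path.write_text(json.dumps(results, indent=1))
        return {"timecourse": path}

    def stage_statespace():
        table = _table()
        sub = table[table["region"] == config.statespace_region]
        matrix, index, neurons = ss.build_activity_matrix(
            sub, baseline_trim_ms=config.baseline_trim_ms,
            kernel_ms=config.kernel_ms, step_ms=config.step_ms)
        ts = ss.pca_trajectories(matrix, index, neurons)
        payload = {
            "variance_explained": ts.variance_explained.tolist(),
            "conditions": [list(c) for c in ts.conditions],
            "distances": {},
        }
        for pair in sorted({p for p, _a in ts.conditions}):
            try:
                t, d = ss.divergence_series(ts, pair)
            except KeyError:
                continue
            top = ss.top_divergences(d)
            payload["distances"][pair] = {
                "times": t.tolist(), "distance": d.tolist(),
                "top2_times": t[top].tolist(),
            }
        path = out / "trajectories.json"
        path.write_text(json.dumps(payload, indent=1))
        return {"trajectories": path}

    run_stage("simulate", stage_simulate)
    run_stage("equalize", stage_equalize)
    run_stage("classify", stage_classify)
    run_stage("compare", stage_compare)
    run_stage("timecourse", stage_timecourse)
    run_stage("statespace", stage_statespace)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1))
    return report
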