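"""Planted-ground-truth neuron populations and negative-binomial spike counts.

Each simulated neuron carries a known selectivity label and the generative
parameters that realize it.  Counts per 200 ms bin follow an NB2 law,

    count ~ NB2(mu, theta),   Var = mu + mu^2 / theta,

with

    log mu = baseline + u_trial
             + phase * ( effect_map[actor, behavior]
                         + event_gain * 1[bin in event window, actor in scope]
                         + sound_effect * 1[sound on, actor == pigeon] )

where ``phase`` is 1 during the video and 0 during the baseline (the middle
2 s of the 6 s inter-trial interval, 10 bins), and ``u_trial`` is a
per-trial Gaussian random intercept.  NB2 draws are realized as a
gamma-Poisson mixture, which is exact and numerically safe for large theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import BEHAVIORS, TWO_PIGEON, BIN_SECONDS, StimulusSet, TrialSchedule

REGIONS = ("MVL", "Wulst", "NCL")
N_BASELINE_BINS = 10   # middle 2 s of the 6 s ITI at 200 ms

# selectivity label vocabulary (ground truth and classifier output share it)
NON_SELECTIVE = "non_selective"
VISUAL = "visually_selective"
ACTOR_PIGEON = "actor_selective:pigeon"
ACTOR_GREEBLE = "actor_selective:greeble"
ACTOR_MIXED = "actor_selective:mixed_sign"
OTHER_MULTI = "other:multi_behavior"
OTHER_TWO_PIGEON = "other:two_pigeon"
EXCLUDED = "excluded"   # singular fit sentinel, never planted

SPIKE_COUNT_COLUMNS = [
    "neuron_id", "subject_id", "region", "trial_number", "phase", "bin_index",
    "actor", "behavior", "exemplar", "sound", "monitor", "pair", "video",
    "count",
]


@dataclass
class NeuronGroundTruth:
    """Generative parameters of one simulated unit."""

    neuron_id: str
    subject_id: str
    region: str
    label: str
    baseline_log_rate: float        # log(counts / 200 ms bin)
    theta: float                    # NB2 dispersion, > 0
    sigma_trial: float              # SD of the per-trial log-rate intercept
    effect_map: dict = field(default_factory=dict)  # (actor, behavior) -> log increment
    event_gain: float = 0.0         # extra log-rate inside event windows
    event_actors: tuple = ("pigeon", "greeble")
    sound_effect: float = 0.0       # log increment for pigeon sound-on bins
    contralateral_monitor: str = "left"

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.sigma_trial < 0:
            raise ValueError("sigma_trial must be >= 0")


def _effect_map_for_label(label: str, beta: float,
                          rng: np.random.Generator) -> tuple[str, dict]:
    """Resolve a (possibly unparameterized) label into a full effect map.

    Returns the fully qualified label and the (actor, behavior) -> log
    increment map consistent with it.
    """
    core = list(BEHAVIORS)
    if label == NON_SELECTIVE:
        return label, {}
    if label == VISUAL:
        m = {(a, b): beta for a in ("pigeon", "greeble") for b in core}
        m[("pigeon", TWO_PIGEON)] = beta
        return label, m
    if label.startswith("actor_selective"):
        which = label.split(":", 1)[1] if ":" in label else str(rng.choice(["pigeon", "greeble"]))
        if which == "mixed_sign":
            m = {("pigeon", b): beta for b in core}
            m.update({("greeble", b): -beta for b in core})
        else:
            m = {(which, b): beta for b in core}
        return f"actor_selective:{which}", m
    if label.startswith("behavior_selective"):
        b = label.split(":", 1)[1] if ":" in label else str(rng.choice(core))
        return f"behavior_selective:{b}", {("pigeon", b): beta, ("greeble", b): beta}
    if label.startswith("actor_and_behavior"):
        parts = label.split(":")
        actor = parts[1] if len(parts) > 1 else str(rng.choice(["pigeon", "greeble"]))
        b = parts[2] if len(parts) > 2 else str(rng.choice(core))
        return f"actor_and_behavior:{actor}:{b}", {(actor, b): beta}
    if label == OTHER_MULTI:
        b1, b2 = rng.choice(core, size=2, replace=False)
        return label, {(a, b): beta for a in ("pigeon", "greeble") for b in (b1, b2)}
    if label == OTHER_TWO_PIGEON:
        return label, {("pigeon", TWO_PIGEON): beta}
    raise ValueError(f"unknown label {label!r}")


def make_population(
    n_neurons_per_region: int,
    label_mix: dict[str, float],
    effect_size: float = 1.0,
    seed: int = 0,
    regions: tuple = REGIONS,
    n_subjects_per_region: int = 3,
    baseline_mean_log: float = math.log(2.0),
    baseline_sd: float = 0.7,
    theta: float = 2.0,
    sigma_trial: float = 0.3,
    event_gain: float = 0.0,
    event_actors: tuple = ("pigeon", "greeble"),
    sound_modulated_fraction: float = 0.0,
    sound_effect: float = 0.0,
) -> list[NeuronGroundTruth]:
    """Draw a population of ground-truth neurons.

    ``label_mix`` maps selectivity labels to proportions (must sum to 1);
    each neuron's label is an independent categorical draw.  Baseline
    log-rates are Normal(log 2, 0.7^2) per 200 ms bin by default, spanning
    near-zero to moderate rates.  Neuron IDs are nested within subjects,
    subjects within regions; each subject has a fixed implanted hemisphere,
    hence a fixed contralateral monitor.
    """
    probs = np.array(list(label_mix.values()), dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("label_mix proportions must be non-negative and sum to 1")
    labels = list(label_mix.keys())
    rng = np.random.default_rng(seed)
    population: list[NeuronGroundTruth] = []
    for region in regions:
        for i in range(n_neurons_per_region):
            subj_idx = i % n_subjects_per_region
            subject_id = f"{region}_s{subj_idx + 1}"
            raw_label = labels[int(rng.choice(len(labels), p=probs))]
            label, effect_map = _effect_map_for_label(raw_label, effect_size, rng)
            base = float(rng.normal(baseline_mean_log, baseline_sd)) if baseline_sd > 0 \
                else baseline_mean_log
            sound_on = bool(rng.random() < sound_modulated_fraction)
            population.append(NeuronGroundTruth(
                neuron_id=f"{subject_id}_n{i + 1}",
                subject_id=subject_id,
                region=region,
                label=label,
                baseline_log_rate=base,
                theta=theta,
                sigma_trial=sigma_trial,
                effect_map=effect_map,
                event_gain=event_gain,
                event_actors=tuple(event_actors),
                sound_effect=sound_effect if sound_on else 0.0,
                contralateral_monitor="left" if subj_idx % 2 == 0 else "right",
            ))
    return population


def _nb2_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def _event_flags(spec, n_bins: int) -> np.ndarray:
    """Bins overlapping an event window by at least half a bin."""
    flags = np.zeros(n_bins, dtype=bool)
    edges = np.arange(n_bins + 1) * BIN_SECONDS
    for start, end, _tag in spec.event_windows:
        overlap = np.minimum(edges[1:], end) - np.maximum(edges[:-1], start)
        flags |= overlap >= BIN_SECONDS / 2 - 1e-9
    return flags


def simulate_spike_counts(
    schedule: TrialSchedule,
    stimulus_set: StimulusSet,
    population: list[NeuronGroundTruth],
    seed: int = 0,
    contralateral_only: bool = True,
) -> pd.DataFrame:
    """Simulate the binned spike-count table for a whole session.

    One row per (neuron, trial, 200 ms bin): 10 baseline bins from the
    middle 2 s of the ITI, then the full video duration (last partial bin
    dropped).  By default only trials shown on each neuron's contralateral
    monitor are emitted (3 of 6 per video), mirroring the analysis
    restriction imposed by the near-complete optic-nerve decussation.
    """
    if len(schedule) == 0 or not population:
        raise ValueError("schedule and population must be non-empty")
    rng = np.random.default_rng(seed)
    specs = {v.video_id: v for v in stimulus_set.videos}

    base = np.array([n.baseline_log_rate for n in population])
    theta = np.array([n.theta for n in population])
    sig = np.array([n.sigma_trial for n in population])
    evgain = np.array([n.event_gain for n in population])
    snd = np.array([n.sound_effect for n in population])
    n_units = len(population)

    chunks: list[pd.DataFrame] = []
    for trial in schedule.trials:
        spec = specs[trial.video_id]
        keep = np.ones(n_units, dtype=bool)
        if contralateral_only:
            keep = np.array([n.contralateral_monitor == trial.monitor
                             for n in population])
        # per-(neuron, trial) random intercept is drawn for every trial so the
        # stream is identical whether or not ipsilateral trials are kept
        u = rng.normal(0.0, 1.0, size=n_units) * sig
        if not keep.any():
            continue
        idx = np.flatnonzero(keep)

        n_vid_bins = int(spec.duration / BIN_SECONDS + 1e-9)
        ev = _event_flags(spec, n_vid_bins)
        eff = np.array([pop_n.effect_map.get((spec.actor, spec.behavior), 0.0)
                        for pop_n in population])
        ev_on = np.array([spec.actor in pop_n.event_actors for pop_n in population])
        sound_on = spec.sound == "on" and spec.actor == "pigeon"

        # (unit, bin) log-rate for baseline then video phase
        log_mu_base = (base + u)[idx, None] * np.ones((1, N_BASELINE_BINS))
        log_mu_vid = (base + u + eff + (snd if sound_on else 0.0))[idx, None] \
            + np.where(ev_on[idx, None], evgain[idx, None], 0.0) * ev[None, :]
        counts_base = _nb2_draw(rng, np.exp(np.clip(log_mu_base, -30, 30)),
                                theta[idx, None])
        counts_vid = _nb2_draw(rng, np.exp(np.clip(log_mu_vid, -30, 30)),
                               theta[idx, None])

        for phase, counts, nb in (("baseline", counts_base, N_BASELINE_BINS),
                                  ("video", counts_vid, n_vid_bins)):
            unit_ix = np.repeat(idx, nb)
            chunks.append(pd.DataFrame({
                "neuron_id": [population[k].neuron_id for k in unit_ix],
                "subject_id": [population[k].subject_id for k in unit_ix],
                "region": [population[k].region for k in unit_ix],
                "trial_number": trial.trial_index,
                "phase": phase,
                "bin_index": np.tile(np.arange(nb), len(idx)),
                "actor": spec.actor,
                "behavior": spec.behavior,
                "exemplar": spec.exemplar,
                "sound": spec.sound,
                "monitor": trial.monitor,
                "pair": spec.pair,
                "video": spec.video,
                "count": counts.reshape(-1),
            }))
    table = pd.concat(chunks, ignore_index=True)
    return table[SPIKE_COUNT_COLUMNS]


def generate_frame_pair(
    height: int,
    width: int,
    fg_mask_spec: dict | None = None,
    luminance_params: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two color frames sharing a background texture plus a foreground mask.

    The frames differ only in foreground luminance (means set exactly to
    ``fg_a`` and ``fg_b``), emulating a subject-vs-control frame pair for
    the equalization module.  Deterministic given ``seed``.
    """
    fg_mask_spec = fg_mask_spec or {}
    lum = {"fg_a": 0.6, "fg_b": 0.3, "bg": 0.4, "noise": 0.05}
    lum.update(luminance_params or {})

    shape = fg_mask_spec.get("shape", "ellipse")
    cy, cx = fg_mask_spec.get("center", (height / 2, width / 2))
    ry, rx = fg_mask_spec.get("size", (height / 4, width / 4))
    yy, xx = np.mgrid[0:height, 0:width]
    if shape == "ellipse":
        mask = ((yy - cy) / max(ry, 1e-9)) ** 2 + ((xx - cx) / max(rx, 1e-9)) ** 2 <= 1.0
    elif shape == "rect":
        mask = (np.abs(yy - cy) <= ry) & (np.abs(xx - cx) <= rx)
    else:
        raise ValueError(f"unknown mask shape {shape!r}")
    if not mask.any():
        raise ValueError("degenerate (empty) foreground mask")
    if cy - ry < 0 or cy + ry > height or cx - rx < 0 or cx + rx > width:
        raise ValueError("mask does not fit inside the frame")

    rng = np.random.default_rng(seed)
    bg_noise = rng.normal(0.0, lum["noise"], size=(height, width))
    fg_noise = rng.normal(0.0, lum["noise"], size=(height, width))

    def compose(fg_mean: float) -> np.ndarray:
        v = lum["bg"] + bg_noise
        v[mask] = fg_mean + fg_noise[mask]
        # hit the requested masked means exactly
        v[mask] += fg_mean - v[mask].mean()
        v[~mask] += lum["bg"] - v[~mask].mean()
        v = np.clip(v, 0.0, 1.0)
        return np.repeat(v[:, :, None], 3, axis=2)

    return compose(lum["fg_a"]), compose(lum["fg_b"]), mask
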