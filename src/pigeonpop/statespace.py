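"""Pseudo-simultaneous population state-space trajectories.

Per neuron and condition (video x actor, sound pooled), trial activity is
re-binned in 200 ms windows sliding by 40 ms, averaged across trials,
smoothed with a 200 ms Gaussian kernel and z-scored against the neuron's
baseline statistics (mean and SD of the 200 ms baseline counts over the
middle 2 s of the 6 s ITI).  The per-condition series -- a 600 ms baseline
prefix plus the full video -- are concatenated into a neurons x time
matrix, treated as pseudo-simultaneous, and reduced to the three leading
principal components.  Projections define one trajectory per condition;
pigeon-vs-greeble divergence for a video is the per-timepoint Euclidean
distance between the two trajectories in the 3-component space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA

from .stimuli import TWO_PIGEON

log = logging.getLogger(__name__)

WIDTH_MS = 200
STEP_MS = 40
KERNEL_MS = 200
BASELINE_TRIM_MS = 600
SD_FLOOR = 1e-6


def sliding_bin(data, width_ms: int = WIDTH_MS, step_ms: int = STEP_MS,
                kind: str = "counts", base_bin_ms: int = 200,
                duration_ms: float | None = None) -> np.ndarray:
    """Left-aligned half-open sliding windows.

    ``kind="times"``: ``data`` are spike times in ms, ``duration_ms``
    required; each window counts spikes in [t, t + width).
    ``kind="counts"``: ``data`` are counts in consecutive ``base_bin_ms``
    bins; window sums are obtained by linear resampling (each window of
    width equal to the base bin overlaps at most two base bins, weighted by
    fractional overlap).

    Returns ``floor((duration - width) / step) + 1`` values; empty when
    the duration is shorter than the window.
    """
    if width_ms % step_ms != 0:
        raise ValueError("width_ms must be a multiple of step_ms")
    if kind == "times":
        if duration_ms is None:
            raise ValueError("duration_ms required for spike-time input")
        times = np.asarray(data, dtype=float)
        dur = float(duration_ms)
        n = int((dur - width_ms) // step_ms) + 1
        if n <= 0:
            return np.empty(0)
        starts = np.arange(n) * step_ms
        return np.array([np.sum((times >= t) & (times < t + width_ms))
                         for t in starts], dtype=float)
    if kind != "counts":
        raise ValueError(f"unknown input kind {kind!r}")
    counts = np.asarray(data, dtype=float)
    if width_ms != base_bin_ms:
        raise ValueError("count resampling assumes width equal to the base bin")
    dur = len(counts) * base_bin_ms
    n = int((dur - width_ms) // step_ms) + 1
    if n <= 0:
        return np.empty(0)
    starts = np.arange(n) * step_ms
    i = starts // base_bin_ms
    r = (starts % base_bin_ms) / base_bin_ms
    nxt = np.minimum(i + 1, len(counts) - 1)
    return counts[i] * (1.0 - r) + counts[nxt] * r


def gaussian_sigma_steps(kernel_ms: int = KERNEL_MS, step_ms: int = STEP_MS,
                         interpretation: str = "sd") -> float:
    """Kernel width in sliding-window steps.

    The 200 ms kernel is read as the Gaussian SD by default; the FWHM
    reading is available via ``interpretation="fwhm"``.
    """
    if interpretation == "sd":
        return kernel_ms / step_ms
    if interpretation == "fwhm":
        return kernel_ms / (2.0 * np.sqrt(2.0 * np.log(2.0))) / step_ms
    raise ValueError(f"unknown kernel interpretation {interpretation!r}")


def condition_average_and_smooth(trials, kernel_ms: int = KERNEL_MS,
                                 step_ms: int = STEP_MS,
                                 interpretation: str = "sd") -> np.ndarray:
    """Pointwise mean across trials, then Gaussian smoothing (reflective
    boundaries, truncated at 3 SD)."""
    arr = np.asarray(trials, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("need at least one trial with at least one window")
    mean = arr.mean(axis=0)
    sigma = gaussian_sigma_steps(kernel_ms, step_ms, interpretation)
    return gaussian_filter1d(mean, sigma=sigma, mode="reflect", truncate=3.0)


@dataclass
class BaselineStats:
    """Per-neuron mean and SD of the 200 ms baseline counts."""
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "BaselineStats":
        base = table[table["phase"] == "baseline"]
        g = base.groupby("neuron_id")["count"]
        return cls(mean=g.mean().to_dict(), sd=g.std(ddof=0).to_dict())


def zscore_to_baseline(series: np.ndarray, mean: float, sd: float,
                       floor: float = SD_FLOOR) -> np.ndarray:
    """(x - baseline mean) / baseline SD; SD below floor is an error (the
    caller excludes such silent neurons)."""
    if sd < floor:
        raise ValueError("baseline SD below floor")
    return (np.asarray(series, dtype=float) - mean) / sd


@dataclass
class TrajectorySet:
    conditions: list                  # [(pair, actor), ...]
    times: dict                       # condition -> seconds (baseline < 0)
    trajectories: dict                # condition -> (T, k) coordinates
    variance_explained: np.ndarray    # k fractions, non-increasing
    loadings: np.ndarray              # neurons x k, orthonormal columns
    neuron_ids: list


def build_activity_matrix(table: pd.DataFrame,
                          baseline_trim_ms: int = BASELINE_TRIM_MS,
                          kernel_ms: int = KERNEL_MS,
                          step_ms: int = STEP_MS,
                          interpretation: str = "sd",
                          include_two_pigeon: bool = False):
    """Assemble the pseudo-simultaneous neurons x (condition, time) matrix.

    Returns ``(matrix, index, neuron_ids)`` where ``index`` is a list of
    ``(pair, actor, time_s)`` per column; baseline-prefix columns carry
    negative times.  Neurons with baseline SD below the floor are excluded
    (logged); a neuron missing any condition is an error.
    """
    stats = BaselineStats.from_table(table)
    neuron_ids = sorted(table["neuron_id"].unique())
    kept = [n for n in neuron_ids if stats.sd.get(n, 0.0) >= SD_FLOOR]
    for n in neuron_ids:
        if n not in kept:
            log.info("excluding silent neuron %s (baseline SD below floor)", n)
    if not kept:
        raise ValueError("no neuron has baseline SD above the floor")

    vid = table[table["phase"] == "video"]
    if not include_two_pigeon:
        vid = vid[vid["behavior"] != TWO_PIGEON]
    conditions = sorted({(p, a) for p, a in zip(vid["pair"], vid["actor"])})
    trim_steps = int(baseline_trim_ms // step_ms)

    rows, missing = [], []
    col_index: list | None = None
    for n_id in kept:
        nk = table[table["neuron_id"] == n_id]
        segs, idx = [], []
        for pair, actor in conditions:
            v = nk[(nk["phase"] == "video") & (nk["pair"] == pair)
                   & (nk["actor"] == actor)]
            if v.empty:
                missing.append((n_id, pair, actor))
                continue
            trials = sorted(v["trial_number"].unique())
            vid_series, base_series = [], []
            for t in trials:
                vt = v[v["trial_number"] == t].sort_values("bin_index")
                vid_series.append(sliding_bin(vt["count"].to_numpy(),
                                              step_ms=step_ms))
                bt = nk[(nk["phase"] == "baseline")
                        & (nk["trial_number"] == t)].sort_values("bin_index")
                base_series.append(sliding_bin(bt["count"].to_numpy(),
                                               step_ms=step_ms))
            base_avg = condition_average_and_smooth(base_series, kernel_ms,
                                                    step_ms, interpretation)
            vid_avg = condition_average_and_smooth(vid_series, kernel_ms,
                                                   step_ms, interpretation)
            z = zscore_to_baseline(
                np.concatenate([base_avg[-trim_steps:], vid_avg]),
                stats.mean[n_id], stats.sd[n_id])
            segs.append(z)
            t_base = (np.arange(trim_steps) - trim_steps) * step_ms / 1000.0
            t_vid = np.arange(len(vid_avg)) * step_ms / 1000.0
            idx.extend([(pair, actor, float(t)) for t in
                        np.concatenate([t_base, t_vid])])
        if missing:
            raise ValueError(f"missing (neuron, condition) cells: {missing}")
        rows.append(np.concatenate(segs))
        if col_index is None:
            col_index = idx
    return np.vstack(rows), col_index, kept


def pca_trajectories(matrix: np.ndarray, index: list, neuron_ids: list,
                     k: int = 3) -> TrajectorySet:
    """Row-centered PCA of the activity matrix; projections of the top-k
    components reassembled into per-condition trajectories."""
    n_neurons, n_cols = matrix.shape
    if n_cols <= k:
        raise ValueError("need more columns than components")
    k_eff = min(k, n_neurons)
    if k_eff < k:
        log.warning("rank allows only %d components", k_eff)
    pca = PCA(n_components=k_eff)
    proj = pca.fit_transform(matrix.T)          # (time samples) x k
    conditions = sorted({(p, a) for p, a, _t in index})
    times, trajs = {}, {}
    for cond in conditions:
        sel = np.array([i for i, (p, a, _t) in enumerate(index)
                        if (p, a) == cond])
        times[cond] = np.array([index[i][2] for i in sel])
        trajs[cond] = proj[sel]
    return TrajectorySet(conditions=conditions, times=times,
                         trajectories=trajs,
                         variance_explained=pca.explained_variance_ratio_,
                         loadings=pca.components_.T, neuron_ids=list(neuron_ids))


def trajectory_distance(traj_a: np.ndarray, traj_b: np.ndarray) -> np.ndarray:
    """Per-timepoint Euclidean distance between two trajectories."""
    a, b = np.asarray(traj_a, float), np.asarray(traj_b, float)
    if a.shape != b.shape:
        raise ValueError("trajectories must have equal shapes")
    return np.linalg.norm(a - b, axis=-1)


def divergence_series(ts: TrajectorySet, pair: str):
    """Times and pigeon-vs-greeble distances for one video pair."""
    a, b = (pair, "pigeon"), (pair, "greeble")
    if a not in ts.trajectories or b not in ts.trajectories:
        raise KeyError(f"pair {pair!r} lacks both actor trajectories")
    return ts.times[a], trajectory_distance(ts.trajectories[a],
                                            ts.trajectories[b])


def top_divergences(distances: np.ndarray, k: int = 2) -> np.ndarray:
    """Indices of the k largest distances, ties broken by earliest time."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    k = min(k, d.size)
    order = np.lexsort((np.arange(d.size), -d))
    return order[:k]
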