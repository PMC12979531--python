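"""Population time-course model: which 200 ms bins drive the modulation.

A labeled subpopulation (e.g. the pigeon-selective units of one region) is
fitted, one video at a time, with a count GLMM over actor x time-bin cells:

    count ~ cell + (1 | trial:bin) + (1 | subject:neuron)

``cell`` has one level per baseline bin (the middle 2 s of the ITI, pooled
across actors) and one level per video bin and actor.  The random
intercept for neuron identity (nested within subject) absorbs baseline
heterogeneity across units; the trial:bin intercept absorbs shared
trial-by-trial fluctuations.

Video bins whose pigeon-condition marginal mean departs from the pooled
baseline marginal mean are located with Holm-adjusted Wald contrasts; in
those bins the pigeon and greeble predictions are then compared
(Holm-adjusted within video).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contrasts import ContrastResult, adjust_contrasts, contrast
from .glmm import FitOptions, GlmmFit, ModelSpec, fit_glmm
from .simulate import N_BASELINE_BINS


@dataclass
class BinResult:
    video: str
    bin_index: int
    baseline_contrast: ContrastResult
    actor_contrast: ContrastResult | None = None


def prepare_m2(records: pd.DataFrame, pair: str) -> pd.DataFrame:
    """Rows of one video pair (both actors, sound pooled) plus the
    baseline bins of the same trials, with the cell factor attached."""
    vid = records[(records["pair"] == pair) & (records["phase"] == "video")]
    if vid.empty:
        raise ValueError(f"no video rows for pair {pair!r}")
    trials = vid["trial_number"].unique()
    base = records[(records["phase"] == "baseline")
                   & records["trial_number"].isin(trials)]
    df = pd.concat([base, vid], ignore_index=True).copy()
    is_base = df["phase"] == "baseline"
    df["cell"] = np.where(
        is_base,
        "base" + df["bin_index"].astype(int).astype(str).str.zfill(2),
        df["actor"].str[0] + "bin" + df["bin_index"].astype(int).astype(str).str.zfill(2))
    # BinNrInTrial: baseline bins then video bins, unique within trial
    df["binnr"] = np.where(is_base, df["bin_index"],
                           N_BASELINE_BINS + df["bin_index"]).astype(int)
    return df


def fit_m2(records: pd.DataFrame, pair: str,
           options: FitOptions | None = None) -> GlmmFit:
    """Fit the time-course model to a subpopulation for one video pair."""
    df = prepare_m2(records, pair)
    if df["neuron_id"].nunique() < 2:
        raise ValueError("need >= 2 neurons for the population model")
    if df["subject_id"].nunique() < 2:
        warnings.warn("single subject: subject-level variance is not "
                      "estimable; the neuron intercept absorbs it")
    spec = ModelSpec(
        "count", fixed=["cell"],
        random=["trial_number:binnr", "subject_id:neuron_id"],
        family="negbin", reference={"cell": "base00"})
    return fit_glmm(df, spec, options)


def _cells(fit: GlmmFit):
    levels = fit.design.factors["cell"]
    base = sorted(c for c in levels if c.startswith("base"))
    pigeon = sorted(c for c in levels if c.startswith("pbin"))
    greeble = sorted(c for c in levels if c.startswith("gbin"))
    return base, pigeon, greeble


def _cell_column(fit: GlmmFit, level: str) -> int | None:
    name = f"cell[{level}]"
    names = fit.design.column_names
    return names.index(name) if name in names else None


def baseline_contrasts(fit: GlmmFit, video: str = "") -> list[BinResult]:
    """Pigeon-condition marginal mean per video bin vs the pooled baseline
    marginal mean, Holm-adjusted across bins."""
    base, pigeon, _g = _cells(fit)
    n_cols = len(fit.design.column_names)
    results, bins = [], []
    for level in pigeon:
        L = np.zeros(n_cols)
        L[_cell_column(fit, level)] = 1.0
        for b in base:
            j = _cell_column(fit, b)
            if j is not None:       # the reference baseline cell is implicit
                L[j] -= 1.0 / len(base)
        results.append(contrast(fit, L, label=level))
        bins.append(int(level[4:]))
    adjust_contrasts(results)
    return [BinResult(video=video, bin_index=b, baseline_contrast=r)
            for b, r in zip(bins, results)]


def significant_bins(fit: GlmmFit, alpha: float = 0.05,
                     video: str = "") -> list[BinResult]:
    """Video bins where the subpopulation departs from its baseline."""
    return [br for br in baseline_contrasts(fit, video)
            if br.baseline_contrast.p_adjusted < alpha]


def actor_contrast_in_bins(fit: GlmmFit, bins: list[int]) -> list[ContrastResult]:
    """Pigeon-vs-greeble contrast in the given bins, Holm-adjusted."""
    if not bins:
        return []
    n_cols = len(fit.design.column_names)
    results = []
    for b in bins:
        tag = str(int(b)).zfill(2)
        L = np.zeros(n_cols)
        jp = _cell_column(fit, f"pbin{tag}")
        jg = _cell_column(fit, f"gbin{tag}")
        if jp is None or jg is None:
            raise ValueError(f"bin {b} has no pigeon/greeble cells")
        L[jp], L[jg] = 1.0, -1.0
        results.append(contrast(fit, L, label=f"bin{tag}"))
    return adjust_contrasts(results)


def simulate_m2_null(n_neurons: int = 4, n_subjects: int = 2,
                     n_trials: int = 12, n_video_bins: int = 11,
                     baseline_log_rate: float = np.log(2.0),
                     neuron_sd: float = 0.7, trial_bin_sd: float = 0.3,
                     theta: float = 2.0, event_bins: tuple = (),
                     event_gain: float = 0.0, event_actor: str = "pigeon",
                     seed: int = 0, pair: str = "v1") -> pd.DataFrame:
    """Spike-count records drawn directly from the time-course model's own
    generative form (independent trial:bin and neuron intercepts), used to
    calibrate the bin-detection error rate and power."""
    rng = np.random.default_rng(seed)
    u_n = rng.normal(0.0, neuron_sd, n_neurons)
    rows = []
    actors = np.where(np.arange(n_trials) % 2 == 0, "pigeon", "greeble")
    for t in range(n_trials):
        for phase, nb in (("baseline", N_BASELINE_BINS), ("video", n_video_bins)):
            for b in range(nb):
                u_tb = rng.normal(0.0, trial_bin_sd)
                for i in range(n_neurons):
                    eta = baseline_log_rate + u_n[i] + u_tb
                    if phase == "video" and b in event_bins \
                            and (event_actor in ("both", actors[t])):
                        eta += event_gain
                    mu = np.exp(eta)
                    y = rng.poisson(rng.gamma(theta, mu / theta))
                    rows.append((f"n{i}", f"s{i % n_subjects}", t, phase, b,
                                 actors[t], pair, int(y)))
    return pd.DataFrame(rows, columns=["neuron_id", "subject_id",
                                       "trial_number", "phase", "bin_index",
                                       "actor", "pair", "count"])
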