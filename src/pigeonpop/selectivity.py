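"""Per-unit selectivity classification from the single-neuron count GLMM.

Each unit's binned counts (baseline bins from the middle 2 s of the ITI
plus all video bins) are fitted with a negative-binomial mixed model whose
fixed effects are a combined condition factor -- level ``baseline`` for ITI
bins and one actor x behavior level per video cell -- plus actor-specific
sound-on terms, with a per-trial random intercept:

    count ~ condition + pigeon_sound + greeble_sound + (1 | trial)

Every condition coefficient therefore measures modulation relative to
baseline.  Baseline-vs-condition contrasts (equal-weight averages over the
sound on/off presentations, emmeans-style) are Holm-adjusted within unit
and the pattern of significant cells is mapped onto the selectivity
taxonomy:

* actor-selective -- significant cells for exclusively one actor across two
  or more behaviors (or both actors with consistently opposite signs:
  ``mixed_sign``, e.g. excited by pigeons, inhibited by greebles);
* behavior-selective -- exactly one behavior significant under both actors;
* actor-and-behavior-selective -- exactly one significant cell;
* visually selective -- broad modulation by both actors (three or more
  behaviors) without condition specificity;
* other -- two-behavior or two-pigeon-dominant patterns;
* non-selective -- no significant cell.

A unit is additionally flagged sound-modulated when an actor x sound
contrast survives Holm adjustment.  Units with singular fits are excluded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrasts import ContrastResult, adjust_contrasts, contrast, holm_adjust, proportion_test
from .glmm import FitOptions, GlmmFit, ModelSpec, fit_glmm
from .simulate import (ACTOR_MIXED, EXCLUDED, NON_SELECTIVE, OTHER_MULTI,
                       OTHER_TWO_PIGEON, VISUAL)
from .stimuli import TWO_PIGEON

M1_ALPHA = 0.05


@dataclass
class SelectivityLabel:
    category: str
    sound_modulated: bool = False
    # full contrast pattern kept for auditability
    condition_contrasts: list = field(default_factory=list)
    sound_contrasts: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "sound_modulated": bool(self.sound_modulated),
            "condition_contrasts": [vars(c) for c in self.condition_contrasts],
            "sound_contrasts": [vars(c) for c in self.sound_contrasts],
        }


def prepare_m1(records: pd.DataFrame) -> pd.DataFrame:
    """Add the combined condition factor and sound indicator columns."""
    df = records.copy()
    video = df["phase"] == "video"
    df["cond"] = "baseline"
    df.loc[video, "cond"] = df.loc[video, "actor"] + "." + df.loc[video, "behavior"]
    son = video & (df["sound"] == "on")
    df["pigeon_sound"] = (son & (df["actor"] == "pigeon")).astype(float)
    df["greeble_sound"] = (son & (df["actor"] == "greeble")).astype(float)
    return df


def fit_m1(records: pd.DataFrame, options: FitOptions | None = None) -> GlmmFit:
    """Fit the single-unit model to one neuron's records."""
    if records["neuron_id"].nunique() != 1:
        raise ValueError("fit_m1 expects records of exactly one neuron")
    if not (records["phase"] == "baseline").any():
        raise ValueError("baseline bins are required")
    df = prepare_m1(records)
    fixed = ["cond"]
    for col in ("pigeon_sound", "greeble_sound"):
        if df[col].any():
            fixed.append(col)
    spec = ModelSpec("count", fixed=fixed, random=["trial_number"],
                     family="negbin", reference={"cond": "baseline"})
    return fit_glmm(df, spec, options)


def condition_contrasts(fit: GlmmFit) -> list[ContrastResult]:
    """Baseline-vs-cell contrasts, averaged equally over sound on/off,
    Holm-adjusted as one within-unit family."""
    names = fit.design.column_names
    results = []
    for level in fit.design.factors["cond"]:
        if level == "baseline":
            continue
        actor = level.split(".", 1)[0]
        L = np.zeros(len(names))
        L[names.index(f"cond[{level}]")] = 1.0
        sound_col = f"{actor}_sound"
        if sound_col in names:
            L[names.index(sound_col)] = 0.5
        results.append(contrast(fit, L, label=level))
    return adjust_contrasts(results)


def sound_contrasts(fit: GlmmFit) -> list[ContrastResult]:
    """Actor x sound contrasts (sound-on vs sound-off within actor)."""
    names = fit.design.column_names
    results = []
    for col in ("pigeon_sound", "greeble_sound"):
        if col in names:
            L = np.zeros(len(names))
            L[names.index(col)] = 1.0
            results.append(contrast(fit, L, label=col))
    return adjust_contrasts(results)


def label_from_pattern(sig_cells: set, estimates: dict) -> str:
    """Deterministic classification rule on the set of significant
    (actor, behavior) cells; ``estimates`` maps cells to link-scale
    modulation for sign handling.  Total on any pattern."""
    if not sig_cells:
        return NON_SELECTIVE
    core = {c for c in sig_cells if c[1] != TWO_PIGEON}
    if not core:
        return OTHER_TWO_PIGEON
    if len(core) == 1:
        actor, beh = next(iter(core))
        return f"actor_and_behavior:{actor}:{beh}"
    actors = {a for a, _b in core}
    behaviors = {b for _a, b in core}
    if len(core) == 2 and len(behaviors) == 1 and len(actors) == 2:
        return f"behavior_selective:{next(iter(behaviors))}"
    if len(actors) == 1:
        return f"actor_selective:{next(iter(actors))}"
    p_signs = {np.sign(estimates[c]) for c in core if c[0] == "pigeon"}
    g_signs = {np.sign(estimates[c]) for c in core if c[0] == "greeble"}
    if p_signs and g_signs and len(p_signs) == 1 and len(g_signs) == 1 \
            and p_signs != g_signs:
        return ACTOR_MIXED
    if len(behaviors) >= 3:
        return VISUAL
    return OTHER_MULTI


def classify_unit(fit: GlmmFit, alpha: float = M1_ALPHA) -> SelectivityLabel:
    """Apply the taxonomy to one fitted unit."""
    if fit.singular or not fit.converged:
        return SelectivityLabel(category=EXCLUDED)
    cond = condition_contrasts(fit)
    snd = sound_contrasts(fit)
    sig, est = set(), {}
    for c in cond:
        actor, beh = c.label.split(".", 1)
        est[(actor, beh)] = c.estimate
        if c.p_adjusted < alpha:
            sig.add((actor, beh))
    category = label_from_pattern(sig, est)
    sound_mod = any(c.p_adjusted < alpha for c in snd)
    return SelectivityLabel(category=category, sound_modulated=sound_mod,
                            condition_contrasts=cond, sound_contrasts=snd)


def classify_population(table: pd.DataFrame, alpha: float = M1_ALPHA,
                        options: FitOptions | None = None) -> dict:
    """Fit m1 and classify every neuron in a spike-count table."""
    labels = {}
    for neuron_id, records in table.groupby("neuron_id", sort=True):
        fit = fit_m1(records, options)
        labels[str(neuron_id)] = classify_unit(fit, alpha)
    return labels


COARSE_CATEGORIES = ("actor_selective", "behavior_selective",
                     "actor_and_behavior", "visually_selective", "other",
                     "non_selective", "excluded")


def coarse_category(category: str) -> str:
    for c in COARSE_CATEGORIES:
        if category == c or category.startswith(c + ":") or \
                (c == "other" and category.startswith("other")):
            return c
    return category


def region_summary(labels_by_region: dict) -> pd.DataFrame:
    """Counts of units per coarse category and region, plus the
    sound-modulated tally; percentages are over task-modulated units."""
    rows = {}
    for region, labels in labels_by_region.items():
        counts = {c: 0 for c in COARSE_CATEGORIES}
        sound = 0
        for lab in labels:
            counts[coarse_category(lab.category)] += 1
            sound += lab.sound_modulated
        counts["sound_modulated"] = sound
        counts["n_units"] = len(labels)
        counts["task_modulated"] = len(labels) - counts[NON_SELECTIVE] \
            - counts[EXCLUDED]
        rows[region] = counts
    return pd.DataFrame(rows)


@dataclass
class ProportionComparison:
    pair: tuple
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str


def compare_regions(counts: dict, label: str = "") -> list[ProportionComparison]:
    """Pairwise proportion tests across regions, Holm-adjusted.

    ``counts`` maps region -> (hits, n).  Chi-squared or Fisher is chosen
    per pair by the expected-count rule.
    """
    regions = list(counts)
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    for r, (k, n) in counts.items():
        if n <= 0:
            raise ValueError(f"empty region {r!r}")
    out = []
    for a, b in itertools.combinations(regions, 2):
        stat, p, method = proportion_test(counts[a][0], counts[a][1],
                                          counts[b][0], counts[b][1])
        out.append(ProportionComparison(pair=(a, b), statistic=stat,
                                        p_raw=p, p_adjusted=np.nan,
                                        method=method))
    adj = holm_adjust([c.p_raw for c in out])
    for c, a in zip(out, adj):
        c.p_adjusted = float(a)
    return out
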