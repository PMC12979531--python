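"""Marginal means, contrasts and multiple-testing utilities.

Estimated marginal means are link-scale predictions on the full factor
grid, averaged with equal weights over the factors not kept; numeric
covariates are held at their training means.  Pairwise and custom
contrasts propagate the coefficient covariance, are tested with Wald Z
statistics, and p-values are adjusted with the Holm step-down procedure.

Proportions are compared with a 2x2 chi-squared test (no continuity
correction) when all expected counts are at least 5, and with Fisher's
exact test otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import GlmmFit


@dataclass
class ContrastResult:
    label: str
    estimate: float          # link (log-rate) scale
    se: float
    z: float
    p_raw: float
    p_adjusted: float = float("nan")


def contrast(fit: GlmmFit, L: np.ndarray, label: str = "") -> ContrastResult:
    """Wald test of the linear combination ``L @ beta``."""
    L = np.asarray(L, dtype=float)
    est = float(L @ fit.beta.to_numpy())
    var = float(L @ fit.cov_beta.to_numpy() @ L)
    se = float(np.sqrt(max(var, 0.0)))
    z = est / se if se > 0 else 0.0
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return ContrastResult(label=label, estimate=est, se=se, z=z, p_raw=p)


def marginal_means(fit: GlmmFit, factors_to_keep: list[str]):
    """Estimated marginal means for ``factors_to_keep``.

    Returns ``(table, cov)``: a DataFrame with one row per kept-factor
    combination (columns: the kept factors, ``estimate``, ``se``) and the
    covariance matrix of the estimates, propagated from ``cov(beta)``.
    """
    design = fit.design
    for f in factors_to_keep:
        if f not in design.factors:
            raise ValueError(f"{f!r} is not a factor in the model")
    all_factors = list(design.factors)
    grid = pd.DataFrame(
        list(itertools.product(*[design.factors[f] for f in all_factors])),
        columns=all_factors)
    for col, mean in design.numeric_means.items():
        grid[col] = mean
    Xg = design.build(grid)

    if factors_to_keep:
        keys = list(grid.groupby(factors_to_keep, sort=True).groups.items())
    else:
        keys = [("(all)", grid.index)]
    A = np.zeros((len(keys), len(grid)))
    rows = []
    for i, (key, idx) in enumerate(keys):
        A[i, np.asarray(idx)] = 1.0 / len(idx)
        rows.append(key if isinstance(key, tuple) else (key,))
    LX = A @ Xg
    est = LX @ fit.beta.to_numpy()
    cov = LX @ fit.cov_beta.to_numpy() @ LX.T
    out = pd.DataFrame(rows, columns=factors_to_keep or ["group"])
    out["estimate"] = est
    out["se"] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return out, cov


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def adjust_contrasts(results: list[ContrastResult]) -> list[ContrastResult]:
    """Holm-adjust a family of contrasts in place and return it."""
    adj = holm_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results


def proportion_test(count_a: int, n_a: int, count_b: int, n_b: int):
    """Compare two proportions; returns ``(statistic, p, method)``.

    Chi-squared (no Yates correction) on the 2x2 table when all expected
    counts are >= 5, otherwise Fisher's exact test (two-sided, statistic =
    sample odds ratio).
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= count_a <= n_a and 0 <= count_b <= n_b):
        raise ValueError("counts must not exceed group sizes")
    table = np.array([[count_a, n_a - count_a], [count_b, n_b - count_b]],
                     dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        res = stats.fisher_exact(table, alternative="two-sided")
        return float(res.statistic), float(res.pvalue), "fisher"
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), "chi2"
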