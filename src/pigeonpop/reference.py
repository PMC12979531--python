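"""Reference simulations: the study conditions exercised end to end.

Each function runs one validation scenario at its default problem size and
returns the measured quantities as a flat dict.  The scenarios mirror the
design constants of the experiment (72-video set, 432-trial sessions, 3
contralateral repetitions per video and sound condition, 200 ms bins) and
the generator's planted ground truth; problem sizes are chosen so the full
battery runs in a few minutes on one core.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import timecourse as tc
from .contrasts import holm_adjust, proportion_test
from .frames import FrameStack, compute_target_luminance, frame_dissimilarity, luminance_match, radial_profile, spatial_frequency_match
from .glmm import FitOptions, ModelSpec, fit_glmm
from .selectivity import classify_unit, fit_m1
from .simulate import NON_SELECTIVE, generate_frame_pair, make_population, simulate_spike_counts
from .statespace import build_activity_matrix, divergence_series, pca_trajectories, top_divergences
from .stimuli import build_stimulus_set, schedule_session


# ---------------------------------------------------------------------------
# stimulus set and session schedule


def stimulus_schedule_metrics(seed: int = 0) -> dict:
    stim = build_stimulus_set(seed=seed)
    sched = schedule_session(stim, seed=seed + 1)
    behavior = {v.video_id: v.behavior for v in stim.videos}
    cats = [behavior[t.video_id] for t in sched.trials]
    run = best = 1
    for a, b in zip(cats, cats[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    per_video = pd.Series([t.video_id for t in sched.trials]).value_counts()
    left = pd.Series([t.video_id for t in sched.trials
                      if t.monitor == "left"]).value_counts()
    return {
        "n_videos": len(stim),
        "n_visually_unique": stim.n_visually_unique,
        "n_trials": len(sched),
        "reps_per_video_min": int(per_video.min()),
        "reps_per_video_max": int(per_video.max()),
        "left_presentations_per_video": int(left.min()) if left.min() == left.max() else -1,
        "max_category_run_length": best,
        "n_reward_trials": int(sum(t.reward for t in sched.trials)),
    }


# ---------------------------------------------------------------------------
# GLMM engine


def _nb_mixed_data(rng, n_groups=200, per_group=10, beta0=1.0, beta1=0.5,
                   theta=2.0, sigma=0.5):
    g = np.repeat(np.arange(n_groups), per_group)
    u = rng.normal(0.0, sigma, n_groups)
    x = rng.integers(0, 2, g.size).astype(float)
    mu = np.exp(beta0 + beta1 * x + u[g])
    y = rng.poisson(rng.gamma(theta, mu / theta))
    return pd.DataFrame({"count": y, "x": x, "trial": g})


def glmm_recovery_metrics(seed: int = 0, n_reps: int = 200) -> dict:
    """NB parameter recovery: per-fit 3-SE agreement and 95% CI coverage
    of the planted effect over replicates."""
    spec = ModelSpec("count", ["x"], ["trial"], family="negbin")
    within, cover = 0, 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        fit = fit_glmm(_nb_mixed_data(rng), spec)
        z0 = (fit.beta["(Intercept)"] - 1.0) / fit.se["(Intercept)"]
        z1 = (fit.beta["x"] - 0.5) / fit.se["x"]
        within += (abs(z0) < 3) and (abs(z1) < 3)
        cover += abs(z1) < 1.96
    return {"recovery_within_3se_rate": within / n_reps,
            "ci95_coverage": cover / n_reps,
            "n_reps": n_reps}


def glm_oracle_metrics(seed: int = 0) -> dict:
    """Agreement with the plain Poisson IRLS GLM when the random-effect
    variance is pinned to zero."""
    rng = np.random.default_rng(seed)
    df = _nb_mixed_data(rng, theta=1e9, sigma=0.0)
    fit = fit_glmm(df, ModelSpec("count", ["x"], ["trial"], family="poisson"),
                   FitOptions(fix_sigma={"trial": 0.0}))
    X = np.column_stack([np.ones(len(df)), df["x"]])
    oracle = sm.GLM(df["count"], X, family=sm.families.Poisson()).fit()
    return {"poisson_glm_max_abs_diff":
            float(np.abs(fit.beta.to_numpy() - oracle.params).max()),
            "loglik_abs_diff": float(abs(fit.loglik - oracle.llf))}


def overdispersion_metrics(seed: int = 0) -> dict:
    """AIC comparison of NB vs Poisson null models on strongly
    overdispersed counts (theta = 0.5)."""
    rng = np.random.default_rng(seed)
    df = _nb_mixed_data(rng, theta=0.5, sigma=0.3)
    fp = fit_glmm(df, ModelSpec("count", ["x"], ["trial"], family="poisson"))
    fnb = fit_glmm(df, ModelSpec("count", ["x"], ["trial"], family="negbin"))
    return {"aic_nb_minus_poisson": float(fnb.aic - fp.aic)}


def wald_type1_metrics(seed: int = 0, n_reps: int = 1000) -> dict:
    """Type-I error of the Wald Z test for a null effect, n = 500 counts
    per fit (50 trials x 10 bins)."""
    spec = ModelSpec("count", ["x"], ["trial"], family="negbin")
    hits = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        df = _nb_mixed_data(rng, n_groups=50, beta0=np.log(2.0), beta1=0.0,
                            theta=2.0, sigma=0.3)
        fit = fit_glmm(df, spec)
        p = 2 * stats.norm.sf(abs(fit.beta["x"] / fit.se["x"]))
        hits += p < 0.05
    return {"wald_type1_error": hits / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# multiple testing


def _holm_oracle(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def multiple_testing_metrics(seed: int = 0) -> dict:
    """Holm vs brute-force sequential rejection on exhaustive small
    families; chi-squared vs the sum (O-E)^2/E oracle; Fisher rule."""
    rng = np.random.default_rng(seed)
    grid = rng.uniform(0, 1, 6)
    max_diff = 0.0
    for size in range(1, 7):
        for combo in itertools.combinations(range(6), size):
            p = grid[list(combo)]
            max_diff = max(max_diff,
                           float(np.abs(holm_adjust(p) - _holm_oracle(p)).max()))
    table = np.array([[14.0, 51.0], [4.0, 87.0]])
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    oracle = float(((table - expected) ** 2 / expected).sum())
    stat, _p, method = proportion_test(14, 65, 4, 91)
    _s, _p2, method_small = proportion_test(1, 10, 0, 10)
    return {"holm_max_abs_diff": max_diff,
            "chi2_textbook_stat": stat,
            "chi2_oracle_abs_diff": abs(stat - oracle),
            "fisher_rule_triggered": float(method_small == "fisher"
                                           and method == "chi2")}


# ---------------------------------------------------------------------------
# classification recovery (reference simulation: effect 1.0 log-units,
# 3 repetitions per video and sound condition, baseline 2 counts/bin)


REFERENCE_MIX = {
    "actor_selective:pigeon": 0.20,
    "actor_selective:greeble": 0.10,
    "actor_selective:mixed_sign": 0.10,
    "behavior_selective": 0.20,
    "actor_and_behavior": 0.20,
    "visually_selective": 0.10,
    "other:multi_behavior": 0.05,
    "other:two_pigeon": 0.05,
}


def _reference_tables(seed, n_units, mix):
    stim = build_stimulus_set(seed=seed)
    sched = schedule_session(stim, seed=seed + 1)
    pop = make_population(n_units, mix, effect_size=1.0, seed=seed + 2,
                          regions=("MVL",), baseline_mean_log=np.log(2.0),
                          baseline_sd=0.0, theta=2.0, sigma_trial=0.3)
    table = simulate_spike_counts(sched, stim, pop, seed=seed + 3)
    return pop, table


def classification_recovery_metrics(seed: int = 0, n_units: int = 40) -> dict:
    pop, table = _reference_tables(seed, n_units, REFERENCE_MIX)
    correct = total = 0
    for neuron in pop:
        records = table[table["neuron_id"] == neuron.neuron_id]
        label = classify_unit(fit_m1(records))
        if label.category == "excluded":
            continue
        total += 1
        correct += label.category == neuron.label
    return {"label_recovery_rate": correct / max(total, 1),
            "n_units_classified": total}


def null_selectivity_metrics(seed: int = 0, n_units: int = 40) -> dict:
    pop, table = _reference_tables(seed, n_units, {NON_SELECTIVE: 1.0})
    false_pos = total = 0
    for neuron in pop:
        records = table[table["neuron_id"] == neuron.neuron_id]
        label = classify_unit(fit_m1(records))
        if label.category == "excluded":
            continue
        total += 1
        false_pos += label.category != NON_SELECTIVE
    return {"null_false_selectivity_rate": false_pos / max(total, 1),
            "n_null_units": total}


# ---------------------------------------------------------------------------
# population time-course


def timecourse_fwer_metrics(seed: int = 0, n_reps: int = 60) -> dict:
    """Per-video family-wise error of baseline-departure detection on
    populations simulated under the model's own generative form."""
    hits = 0
    for rep in range(n_reps):
        rec = tc.simulate_m2_null(seed=seed + rep)
        fit = tc.fit_m2(rec, "v1")
        hits += len(tc.significant_bins(fit, 0.05)) > 0
    return {"bin_detection_fwer": hits / n_reps, "n_reps": n_reps}


def timecourse_power_metrics(seed: int = 0, n_reps: int = 3) -> dict:
    """Detection of a planted pigeon-only event (gain 1.0 in bins 5-6) and
    of its actor contrast."""
    detected = contrasted = 0
    for rep in range(n_reps):
        rec = tc.simulate_m2_null(seed=seed + 100 + rep, n_neurons=8,
                                  event_bins=(5, 6), event_gain=1.0,
                                  event_actor="pigeon")
        fit = tc.fit_m2(rec, "v1")
        bins = {b.bin_index for b in tc.significant_bins(fit, 0.05)}
        detected += {5, 6} <= bins
        actor = tc.actor_contrast_in_bins(fit, [5, 6])
        contrasted += all(c.p_adjusted < 0.05 for c in actor)
    return {"event_bin_detection_rate": detected / n_reps,
            "actor_contrast_detection_rate": contrasted / n_reps,
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# state space


def pca_oracle_metrics(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(5, 20))
    index = [("v", "pigeon", 0.04 * i) for i in range(20)]
    ts = pca_trajectories(m, index, [f"n{i}" for i in range(5)], k=3)
    centered = m - m.mean(axis=1, keepdims=True)
    evals = np.linalg.eigvalsh(centered @ centered.T / 19)[::-1]
    diff = float(np.abs(ts.variance_explained - evals[:3] / evals.sum()).max())
    traj = ts.trajectories[("v", "pigeon")]
    zero = float(np.max(np.linalg.norm(traj - traj, axis=1)))
    return {"pca_eigendecomposition_max_abs_diff": diff,
            "identical_trajectory_distance": zero}


def statespace_event_metrics(seed: int = 0, n_neurons: int = 20) -> dict:
    """End-to-end: 20% of neurons carry transient pigeon-only event gains
    of 1.0; divergence peaks should sit inside the planted windows and
    distances should return to baseline range outside them."""
    stim = build_stimulus_set(seed=seed)
    sched = schedule_session(stim, seed=seed + 1)
    pop = make_population(n_neurons, {NON_SELECTIVE: 1.0}, seed=seed + 2,
                          regions=("MVL",))
    for i, neuron in enumerate(pop):
        if i % 5 == 0:
            neuron.event_gain = 1.0
            neuron.event_actors = ("pigeon",)
    table = simulate_spike_counts(sched, stim, pop, seed=seed + 3)
    matrix, index, neurons = build_activity_matrix(table)
    ts = pca_trajectories(matrix, index, neurons)
    events = {v.pair: v.event_windows for v in stim.videos}
    pairs = sorted({p for p, _a in ts.conditions})
    base_d = [divergence_series(ts, p)[1][divergence_series(ts, p)[0] < 0]
              for p in pairs]
    q95 = float(np.percentile(np.concatenate(base_d), 95))
    hits = returned = 0
    for pair in pairs:
        t, d = divergence_series(ts, pair)
        top = top_divergences(d)
        hits += any(any(w[0] - 0.2 <= t[i] <= w[1] + 0.2
                        for w in events[pair]) for i in top)
        outside = t >= 0
        for s, e, _tag in events[pair]:
            outside &= ~((t >= s - 0.4) & (t <= e + 0.4))
        if outside.any():
            returned += np.median(d[outside]) <= q95
    return {"divergence_hit_rate": hits / len(pairs),
            "baseline_return_rate": returned / len(pairs),
            "n_videos": len(pairs)}


def statespace_null_metrics(seed: int = 0, n_reps: int = 4) -> dict:
    """Null populations: video-period distances exceed the pooled-baseline
    95th percentile only at chance level."""
    rates = []
    for rep in range(n_reps):
        s = seed + 10 * rep
        stim = build_stimulus_set(2, 2, include_two_pigeon=False, seed=s)
        sched = schedule_session(stim, seed=s + 1)
        pop = make_population(20, {NON_SELECTIVE: 1.0}, seed=s + 2,
                              regions=("MVL",))
        table = simulate_spike_counts(sched, stim, pop, seed=s + 3)
        matrix, index, neurons = build_activity_matrix(table)
        ts = pca_trajectories(matrix, index, neurons)
        base, vid = [], []
        for pair in sorted({p for p, _a in ts.conditions}):
            t, d = divergence_series(ts, pair)
            base.append(d[t < 0])
            vid.append(d[t >= 0])
        q95 = np.percentile(np.concatenate(base), 95)
        rates.append(float(np.mean(np.concatenate(vid) > q95)))
    return {"null_exceedance_rate": float(np.mean(rates)), "n_reps": n_reps}


# ---------------------------------------------------------------------------
# stimulus processing


def frames_metrics(seed: int = 0) -> dict:
    a, b, mask = generate_frame_pair(64, 64, seed=seed)
    stack_a = FrameStack(frames=[a], fg_masks=[mask])
    stack_b = FrameStack(frames=[b], fg_masks=[mask])
    fg, bg = compute_target_luminance([stack_a])
    matched = luminance_match(stack_b, fg, bg)
    from .frames import _value_channel
    v = _value_channel(matched.frames[0])
    lum_err = max(abs(v[mask].mean() - fg), abs(v[~mask].mean() - bg))
    eq_a, eq_b = spatial_frequency_match([stack_a, matched])
    p0 = radial_profile(eq_a.frames[0])
    p1 = radial_profile(eq_b.frames[0])
    nz = (p0 > 1e-9) & (p1 > 1e-9)
    nz[0] = False
    rel = float(np.abs(p0[nz] - p1[nz]).max() / p0[nz].max())
    self_corr = float(frame_dissimilarity(stack_a, stack_a)[0])
    return {"luminance_match_abs_error": float(lum_err),
            "radial_profile_max_rel_diff": rel,
            "identical_stack_correlation": self_corr}
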