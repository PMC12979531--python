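# Methods

## Generative model of the synthetic data

Each simulated neuron emits spike counts per 200 ms bin from an NB2 law,
`count ~ NB2(μ, θ)` with `Var = μ + μ²/θ` (smaller θ, more
overdispersion), realized as a gamma–Poisson mixture so that very large θ
(the Poisson limit) stays numerically exact.  The log rate is

    log μ = baseline + u_trial
            + phase · ( effect[actor, behavior]
                        + event_gain · 1[bin ∈ event window, actor in scope]
                        + sound_effect · 1[sound on, actor = pigeon] )

with `phase = 1` during the video and 0 during the baseline (the middle
2 s of the 6 s inter-trial interval, 10 bins), and `u_trial ~ N(0, σ²)`
drawn per neuron and trial.

Defaults and why:

* **Baseline log-rates** `N(log 2, 0.7²)` per bin — a plausible range for
  extracellular single units at these timescales that also produces
  near-zero-count neurons, so zero-inflation diagnostics and the silent-
  neuron exclusion path are genuinely exercised.  Recorded baseline-rate
  distributions are not publicly documented for these populations, so this
  is a stand-in, not a reproduction.
* **Dispersion** θ = 2 and **trial SD** σ = 0.3 — clearly overdispersed
  counts (the regime motivating the NB family) with moderate
  trial-to-trial drift for the random intercept to absorb.
* **Effect size** 1.0 log-units (≈ e-fold rate change) defines the
  reference recovery simulations, with 3 contralateral repetitions per
  video and sound condition and a fixed baseline of 2 counts/bin.
* **Event windows**: 1–3 per video, 200–600 ms, non-overlapping, shared
  between a pigeon video and its greeble control — discrete behavioral
  moments (bowing, wing flaps, steps) that transiently modulate rates via
  `event_gain`, optionally for one actor only (`event_actors`).
* **Sessions**: every video 6× (3 left / 3 right), category run-length
  ≤ 3 via shuffling with local swap repair (seed-deterministic; a
  scheduling error names the violated constraint after 10 000 attempts).
  With a single-category stimulus set the run-length constraint is
  vacuous and skipped.  Rewarded trials are exactly `round(0.10 · N)`
  drawn without replacement — 43 of 432, a realized fraction of 9.95%.
* **Laterality**: each subject has a fixed implanted hemisphere; by
  default only trials on the contralateral monitor are emitted (3 of 6
  per video), so a unit sees each video 3× with sound and 3× without.
  `contralateral_only=False` keeps everything.
* **Bin convention**: 0-based, left-aligned, half-open [t, t + 200 ms);
  a trailing partial video bin is dropped.  A bin counts as "inside" an
  event window when they overlap by at least half a bin.

What the generator does **not** emulate: spike waveforms and sorting
artifacts, adaptation and other non-stationarities beyond the trial
intercept, eye movements or behavioral state, correlated noise across
neurons (units are conditionally independent given the trial intercept),
and real video statistics.  Passing tests therefore demonstrate that the
estimation and classification machinery recovers the truth under its
assumed model family at realistic sizes — not that the assumptions hold
in recorded data.

## Count GLMMs with Laplace-approximate likelihood

For `η = Xβ + Σ_k Z_k u_k`, `u_k ~ N(0, σ_k² I)`, the random-effect mode
`u*` is found by damped Newton iteration (converged when the gradient
infinity-norm falls below 1e-8) and the marginal log-likelihood is the
standard Laplace form `l = l_joint(u*) − ½ log det D − ½ log det H`,
`H = Z'WZ + D⁻¹`.  Both supported families have concave per-observation
log-likelihoods in η (weights `μ` for Poisson, `(y+θ)θμ/(θ+μ)²` for NB2),
so the inner problem is well behaved; the linear predictor is clipped at
±30 to keep exponentials finite.

Structure exploitation: each `Z_k` is an indicator matrix, so `Z_k'WZ_k`
is diagonal.  With two (crossed or nested) factors the Newton system and
log-determinant are solved through a Schur complement on the smaller
factor, giving O(n + q₁q₂²) per iteration with dense numpy only.  This is
why thousands of per-unit and calibration fits run in minutes.

Outer estimation maximizes over `(β, log θ, log σ)` with L-BFGS-B and
finite-difference gradients, warm-starting the inner mode between
evaluations; bounds keep `σ ∈ [1e-6, e⁵]` and `θ ∈ [e⁻⁶, e²⁰]`.
Convergence is declared on the optimizer's relative-objective /
projected-gradient criteria; non-convergence is reported via
`converged=False`, never raised.  A fit is `singular` when any estimated
random-effect SD drops below 1e-4; downstream classification excludes
singular units.  When no free random intercepts remain (e.g. a variance
pinned to zero) the fit reduces to exact IRLS (to 1e-10), profiled over
log θ for the NB family — so the Laplace likelihood coincides with the
exact GLM likelihood at σ = 0, which is also how the engine is checked
against statsmodels.  An independent cross-check against glmmTMB
(Laplace NB2 GLMM via Rscript) on a small fixture agrees to ~1e-5 in
coefficients, dispersion, variance and log-likelihood.

`cov(β)` is the β-block of the inverse joint Hessian at the mode,
conditional on the variance parameters (the lme4 convention); Wald CIs
built from it show 0.90–0.99 coverage in the recovery simulations.
AIC counts β, θ (if estimated) and each free variance.

## Per-unit model and classification

m1 is fitted to the middle-2 s baseline bins plus all video bins of every
trial, with a pooled baseline as the reference level of a combined
condition factor (the alternative reading — a per-video baseline
intercept — is noted but not the default, since pooling uses all 2160
baseline bins to anchor every contrast).  Actor-specific sound-on
indicator columns implement the actor × sound interaction; baseline bins
carry no sound term.  Cell-vs-baseline contrasts average the sound-on and
sound-off predictions with equal weight (emmeans-style), are Holm-adjusted
as one family of 9 within unit, and the two actor × sound terms form a
second Holm family for the sound-modulated flag.

The label rule, applied to the set of significant cells (two-pigeon cells
tracked separately): none → non-selective; only two-pigeon → other;
exactly one cell → actor-and-behavior-selective; one behavior under both
actors and nothing else → behavior-selective; one actor only (≥ 2
behaviors) → actor-selective; both actors with consistently opposite
signs → actor-selective (mixed sign); both actors spanning ≥ 3
behaviors → visually selective; anything else (two behaviors, mixed
patterns) → other.  The rule is total, so permuting condition labels of a
null unit cannot change its label distribution, and the family-wise Holm
level bounds the false-selectivity rate.

Region summaries tabulate coarse categories; pairwise region comparisons
use the 2×2 χ² test without continuity correction, switching to Fisher's
exact test when any expected count is below 5 (the simplest documented
convention; the choice is stated in the output), Holm-adjusted over the
three region pairs.

## Population time-course

m2 is fitted per video pair to a labeled subpopulation, with one fixed
cell per baseline bin (pooled over actors) and per video-bin × actor, a
random intercept per trial × bin and one per subject-nested neuron.  The
"does bin b depart from baseline" contrast compares the pigeon cell
against the average of the ten baseline cells; the actor contrast
compares pigeon and greeble cells at one bin.  Both families are
Holm-adjusted within video (the adjustment procedure is not prescribed
elsewhere, so the package's general policy is applied).  Calibration
simulations draw directly from this model's own generative form
(independent trial×bin and neuron intercepts); the measured per-video
family-wise error of bin detection is ≈ 0.05 at the reference size
(4 neurons, 2 subjects, 12 trials, 11 video bins — small enough that 60
calibration fits run in under a minute).

## State space

Sliding 200 ms/40 ms windows are computed from spike times when
available; the simulator emits 200 ms base counts, from which window sums
are obtained by linear resampling (a window the width of a base bin
overlaps at most two bins).  The "200 ms Gaussian kernel" is read plainly
as SD = 200 ms (truncated at ±3 SD, reflective boundaries); an FWHM
reading is available as an option.  Sound conditions are pooled within
video × actor, and the two-pigeon videos (which have no greeble control)
are excluded from the condition set.  Neurons whose baseline SD falls
below 1e-6 counts are excluded and logged.  Rows (neurons) are mean-
centered before the decomposition, making the eigendecomposition oracle
exact; scikit-learn's PCA provides the factorization.  Each condition's
column block carries a 600 ms baseline prefix (15 windows) so divergence
series include a baseline reference segment.

Divergence validation uses two complementary checks.  With planted
transient pigeon-only events (gain 1.0), one of the two largest distance
peaks falls within ±200 ms (one kernel SD) of a planted window for ≥ 80%
of videos, and the median distance outside dilated event windows stays
below the 95th percentile of pooled baseline-period distances — the
"return to baseline range" property.  Under a null population the
*fraction* of video-period distances above that baseline percentile stays
at chance (≈ 0.10 measured; bounded at 0.25).  A literal "the peak never
exceeds the baseline 95th percentile" criterion would compare a maximum
over ~50–95 correlated timepoints against a quantile of 15 baseline
points and rejects honest nulls 25–75% of the time; the exceedance-rate
formulation tests the same scientific claim without that artifact.

## Numerical and design notes

* Treatment coding with explicit reference levels everywhere; interaction
  columns are products of non-reference dummies.  Rank deficiency raises
  an estimability error naming the aliased columns (QR with pivoting).
* Holm adjustment preserves input order and enforces monotonicity
  (delegated to statsmodels, verified against a brute-force sequential-
  rejection oracle on exhaustive small families).
* Zero-inflation: the observed zero count is compared with counts from
  datasets simulated from the fitted model with random intercepts redrawn;
  the ratio and a two-sided simulation p-value are returned.
* Spatial-frequency matching rescales FFT amplitudes per radial annulus
  (normalized frequency radius, so non-square frames work) toward the
  grand-average profile; phases and each frame's DC component are left
  untouched (mean luminance is owned by the luminance-matching step), and
  values are not clipped inside the operation so recomputed profiles match
  to numerical precision.
* The pipeline assigns transient pigeon-only event gains to the
  pigeon-selective units on top of their sustained effect; giving every
  neuron event modulation would make all units broadly visual and bury
  the planted taxonomy.
* All randomness flows through seeded numpy Generators; identical seeds
  give bit-identical tables, schedules and artifacts (hashes recorded in
  the pipeline report).

## Known limitations

The Laplace approximation can bias variance estimates at very low counts
or few levels per factor; no adaptive quadrature fallback is provided.
Random slopes, zero-inflated mixture families and Bayesian estimation are
out of scope, as is generic formula parsing beyond factors, interactions
and random intercepts (at most two random factors).  The m2 model treats
trial × bin intercepts as independent, so trial-level autocorrelation in
real data would be under-modeled.  Reported percentages from recorded
datasets (unit counts per region, variance-explained values) depend on
data that is not deposited and are deliberately not targets of the test
suite.
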