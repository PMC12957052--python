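# Methods

## The models

Multinomial processing tree (MPT) models express the probabilities of
discrete response categories as sums over the branches of processing
trees; each branch probability is a product of latent-process parameters
`p` and complements `1 − p`. This package implements the two MPT models
used in a three-phase memory-for-foils design (incidental encoding →
intermediate source-constrained retrieval with new foils → final memory
test), with one set of trees per retrieval condition.

**Two-high-threshold (2HT) recognition model.** For old words, "yes" is
reached by detection (probability `D`) or, failing detection, by guessing
"old" (`b`); "no" requires both failures. For foils, `D` is the
probability of detecting the item as new; undetected foils are guessed on
with the same `b`. Six trees: three word types (survival-judged,
pleasantness-judged, foil) × two retrieval conditions (`_SR`
survival-constrained, `_PR` pleasantness-constrained).

**2HT source-monitoring model.** Detected old words additionally yield
source memory with probability `d`; otherwise the source is guessed
("survival" with probability `g`). Undetected items guessed "old" (`b`)
receive the same source guess. Foils behave as in the recognition model
but answer among three categories. Six trees × three categories, with a
per-condition `g` (`_SR` / `_MR` moving-constrained retrieval).

**Base-model constraints.** Within each retrieval condition the foil
detection parameter is not separately identifiable from `b`, so it is
derived as the mean of the two old-word detection parameters,
`D_Foil = (D_old1 + D_old2) / 2` — the standard identifying assumption
for this design. That yields a saturated model; equating `b` across
retrieval conditions adds one testable degree of freedom. Constraints are
represented as equality classes, fixed values, and *affine* derived
expressions with nonnegative weights summing to at most one. The affine
restriction guarantees derived values stay in [0, 1] and makes the whole
constraint map a single matrix `θ = A·φ + c` from free parameters φ to
bound parameters θ, which the optimizer and the delta-method standard
errors reuse. General nonlinear reparameterizations are deliberately out
of scope.

## Estimation

The fit maximizes the product-multinomial log-likelihood
`ℓ(φ) = Σ_c n_c log p_c(θ(φ))` (equivalently minimizes
`G² = 2 Σ_c n_c log(n_c / N_t p_c)`). Free parameters are mapped to the
real line by a logit transform and `−ℓ` is minimized by L-BFGS-B with
analytic gradients assembled from the branch products and the constraint
matrix. Defaults: 20 starting points — one at 0.5, the rest uniform on
(0.1, 0.9) from a seed (default 1) — and objective tolerance 1e-10. The
winning start is then polished by Fisher scoring (Newton steps with the
expected information as Hessian, with step halving), which converges
quadratically and lets saturated models reach G² = 0 at machine precision;
without the polish, first-order termination leaves parameter error near
1e-6, visible in the category-permutation-invariance and exact-recovery
checks at 1e-8.

Numerical conventions: expected category probabilities are floored at
1e-12 inside the objective so that line searches never evaluate log(0);
observed zero cells contribute 0 to G²; a fitted G² below −1e-8 is an
error, smaller negative noise is clamped to 0. Estimates within 1e-4 of
the 0/1 boundary are flagged and their standard errors reported as NaN
rather than read off a near-singular information matrix.

**Standard errors** use the *expected* Fisher information of the
product-multinomial likelihood at the estimates,
`I(φ) = Σ_c (N_t / p_c) (∂p_c/∂φ)(∂p_c/∂φ)ᵀ`, inverted and propagated to
all bound parameters through `A Σ Aᵀ`. Expected (rather than observed)
information is the common choice in MPT software; for these sample sizes
the two differ well below the reporting precision, but comparisons against
published SEs should allow ±0.005.

**Identifiability** is checked numerically: the Jacobian of all category
probabilities with respect to the free parameters is evaluated at random
interior points and the model is locally identified when its minimum rank
equals the free-parameter count. The unconstrained six-tree recognition
model is rank-deficient (within a condition, foil detection and guessing
trade off); the base constraint sets restore full rank (5 and 11).

## Inference

Nested equality restrictions are tested by ΔG² = G²(restricted) −
G²(base), chi-square with Δdf under the null. Restricted models are refit
from scratch with fresh multi-starts rather than warm-started from the
base optimum; a restricted fit beating the base fit beyond −1e-6 is
treated as an optimization failure, not clamped. Nesting is verified
structurally (the restricted constraint set must imply the base one). No
multiple-testing correction is applied; raw p-values are reported.

Sensitivity analysis treats the test statistic under the alternative as
noncentral chi-square with noncentrality λ = w²·N, where w is Cohen's
effect size and N the total number of test decisions (participants × 160
here). Power is the mass above the central critical value; the minimal
detectable w solves power(w) = target by Brent root finding to 1e-10.

## Study reproduction

Counts are reconstructed from the shipped two-decimal proportion tables:
per tree, every category but the last gets `round(p × total)` and the last
("no") absorbs the residual, so tree totals equal the design sizes exactly
(1940 old / 3880 foil per cell in Experiment 1 with N = 97; 1960 / 3920 in
Experiment 2 with N = 98). The residual goes to the last category because
the printed rows visibly carry ±0.01 rounding slack there. Analyses run on
frequencies aggregated over participants (one G² per experiment), the only
reading consistent with a single reported fit statistic; with equal
per-participant cell sizes, pooled frequencies and means of participant
proportions coincide.

**Reconstruction error.** Each reconstructed cell can be off by up to
0.005 × tree total, and with tree totals near 4,000 that uncertainty is
material for fit statistics: a perturbation study over proportion tables
consistent with the printed rounding moves the Experiment 2 base G² over
roughly 0.5–9 and individual ΔG² values by several units. Parameter
estimates are far more stable (±0.01 or less). Comparisons of recomputed
G²/ΔG² values against published ones should therefore expect absolute
deviations of a few units on the largest trees, and this package's
own reproduction lands above the published base G² in Experiment 2 while
matching all parameter estimates, standard errors and effect directions.
The follow-up "matched retrieval" analyses are implemented as restrictions
on the same base models, equating the matched-retrieval recognition or
source parameters across encoding conditions.

## Synthetic data

The simulator draws an independent multinomial per participant × tree cell
from the category probabilities of a fully bound parameter vector, with
the study's cell sizes as defaults (20 old words per encoding × retrieval
cell, 40 foils per retrieval cell). A master seed spawns one child stream
per participant (`SeedSequence.spawn`), so datasets are reproducible under
serial or parallel generation. Sampling is participant-level so that
per-participant descriptives can be emulated; fitting consumes the
aggregate. The generator emulates the design's multinomial sampling only:
no word-level item effects, serial position, block order, or
participant-level parameter heterogeneity. Passing recovery tests
therefore show that the estimation machinery is calibrated for the
homogeneous aggregate model, not that real participants satisfy it.

Recovery studies at the study's own scale (97/98 participants, 200
replicates, truth set to the fitted estimates) show absolute bias below
0.01 for every free parameter and 95%-interval coverage within
[0.91, 0.99]; the full simulate → aggregate → fit → ΔG² chain under a true
null restriction rejects at the nominal 5% rate within Monte-Carlo error
(500 replicates). Simulation fits use 3 multi-starts — ample for data
generated from the model — while the study analyses keep the default 20.

## Known limitations

- Derived parameters are restricted to range-safe affine combinations;
  the averaging constraint needs nothing more.
- No hierarchical/latent-class MPT extensions, Bayesian estimation,
  bootstrap or profile-likelihood intervals, or FIA/BIC complexity
  measures.
- G²-based comparisons against published values inherit the
  proportion-rounding uncertainty quantified above; exact reproduction
  would require the archived raw frequencies, which are deliberately not a
  dependency.
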