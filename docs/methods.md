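# Methods

This document records the statistical models, the synthetic-cohort
calibration, and the numerical choices behind `wqslearn`. The package
implements a two-stage analysis of sex-specific effects of a metal mixture
(Mn, Pb, Cr, Cu measured in blood, urine, hair, nails and saliva — 20
components) on visuospatial learning in an eight-trial virtual radial-arm-maze
(VRAM) session.

## Stage 1 — learning-curve mixed models

For each of the four outcomes a per-subject *learning slope* is extracted
from a covariate-adjusted random-slope model. Covariates in every model:
age, socio-economic status (3 levels, reference `low`), videogame use
(6 levels, reference `do_not_play`) and IQ.

**Continuous outcomes** (`time` in seconds, `distance` in digital units):

y_ij = β₀ + β_t·t_ij + x_i'γ + b₀ᵢ + b₁ᵢ·t_ij + ε_ij,
(b₀ᵢ, b₁ᵢ) ~ N(0, G), ε_ij ~ N(0, σ²)

fitted by REML via `statsmodels.MixedLM` with `re_formula="~trial"`. The
per-subject slope is β_t + b̂₁ᵢ, where b̂₁ᵢ is the BLUP. Its conditional
standard error comes from the conditional covariance
(ZᵢᵀZᵢ/σ² + G⁻¹)⁻¹, computed explicitly.

**Count outcomes** (`wm_errors`, `rm_errors`): zero-inflated Poisson with
the same correlated random intercept + slope on the log-rate scale:

P(y=0) = π + (1−π)e^{−λ}, P(y=k) = (1−π)λᵏe^{−λ}/k! (k>0),
log λ_ij = β₀ + β_t·t_ij + x_i'γ + b₀ᵢ + b₁ᵢ·t_ij.

The marginal likelihood is integrated by **adaptive Gauss–Hermite
quadrature** (product rule over the 2-D random effect, order 7, probabilists'
weights), centred at per-subject posterior modes found by a vectorized 2-D
Newton iteration with backtracking; where the zero-inflation branch makes the
conditional Hessian indefinite, the prior precision is substituted to keep the
adaptive scaling positive definite. Optimization runs in two phases: a Laplace
(order-1) fit for a cheap start, then L-BFGS-B on the order-7 likelihood with
warm-started mode caching. Wald standard errors come from a central
finite-difference Hessian at the optimum. Internally, non-intercept design
columns are standardized and coefficients mapped back.

Per-subject slopes from count models are **log-rate slopes** (a count change
per trial is not comparable across subjects with different baselines). The
implementation was validated against `glmmTMB` (R) on identical data: trial
coefficients agree to ~1e-4 and the zero-inflation probability to ~2e-3
(see `tests/test_zipmm.py::test_against_glmmtmb_oracle`).

## Stage 2 — generalized WQS regression

Exposure columns are scored into deciles (0–9) by **average rank, floored
into equal-count bins**; tied values always share a bin, so integer-heavy
columns are reproducible and any strictly monotone transform of a column
(unit changes included) leaves everything downstream unchanged.

For a direction d ∈ {pos, neg} the WQS index is Σᵢ wᵢ·q_ij with w on the
simplex. Weights are estimated by an ensemble of B=100 bootstrap resamples;
each resample solves

min over (β₀, β₁, w): ‖y − β₀ − β₁·Qw‖² s.t. w ≥ 0, Σw = 1, sign(β₁) = d

with SLSQP using an analytic gradient, a simplex equality constraint and a
sign bound on β₁. The response is standardized inside the solver so the
convergence tolerance is scale-free; coefficients are mapped back. Aggregation
over converged replicates is the plain mean (default) or an |t(β₁)|-weighted
mean (`aggregation="signif"`). Replicate b always draws from spawned child b
of the master `SeedSequence`, so individual resamples are independent of B
and execution order. More than 20% non-converged replicates raises `FitError`.

The final model is OLS of the stage-1 slopes on the fixed-weight index,
optionally with a sex main effect and a sex×index product (girl=1, boy=0),
or refitted within sex strata (weights re-estimated per stratum; stratum
seeds are `2·seed` for girls and `2·seed+1` for boys). No training/validation
split is used (sample size n=188 precludes it); weights and index test share
the full sample — consequences are quantified below. Attribution sums
weights by metal (5 components each) or by matrix (4 components each), in
percent. Sensitivity analysis adds a WQS² term (plus sex×WQS² when the
interaction is present) and reports the LRT (df 1 or 2) and ΔAIC. The
submixture scan fits the 9 sub-mixtures (5 per-matrix, 4 per-metal) within
each sex and direction, with Bonferroni correction across the 9 subsets.

## Synthetic-cohort calibration

The generator (`wqslearn.simulate`, configured by `GeneratorConfig`) draws:

- 188 subjects, 88 girls / 100 boys by exact quota; age ~ truncated normal
  on [10, 14]; SES, videogame use and IQ with sex-specific marginals.
- 20 exposure components, lognormal with configured geometric means/GSDs
  (four components have sex-specific marginals), correlated on the log scale:
  0.4 within a metal across matrices, 0.1 across metals.
- Eight VRAM trials per subject from the stage-1 generative models, with
  per-subject random intercepts and slopes; times censored to (0, 180] s.

**Planted mixture effect.** Each sex has its own true weight vector: girls'
mass concentrates on Mn (0.50 total) and Cu (0.40); boys' on Cr (0.75). A
subject's *own-sex* index z (centred at 4.5) shifts their learning slope by
+c·z for girls and −c·z for boys.

**Cross-index leakage.** Because metals are correlated across subjects, the
girls' index partially tracks the boys' index. Regressing the estimated
interaction on the planted effect shows the fitted sex contrast equals
c·(1+λ) where λ is the cross-index regression leakage; under the default
correlation structure λ ≈ 0.52, measured once at large n and frozen as
`INDEX_CROSS_LEAKAGE`. Defaults therefore set c = target/(1+λ) per outcome,
with interaction targets 0.87 (time), 222 (distance) and 0.06 (wm/rm on the
log-rate scale).

**Slope recovery.** Random-slope SDs and residual noise were chosen so BLUP
shrinkage k = τ²/(τ² + σ²/Sxx) (Sxx = 42 for trials 1–8) stays ≥ ~0.92,
keeping stage-1 per-subject slopes close to the generative ones.

**Known generator limitations.**

- The arithmetic mean of the count outcomes can *rise* over trials even
  though the typical subject improves: with log-rate slope b₁ ~ N(−0.17,
  0.2²), E[e^{b₁t}] grows in t (lognormal mean). Medians and per-subject
  trends decline, which is what the stage-1 models estimate.
- Weight estimation inflates the fitted interaction by roughly 10% relative
  to the true-weights oracle (weight concentration/selection on the full
  sample); this sits within replicate Monte-Carlo error at 10 replicates.
- Without a training/validation split, the WQS **index** test under a null
  embedding can reject above the nominal 5% (the weights are chosen on the
  same data that tests them). The **interaction** test is close to nominal,
  because weights are estimated from the main-effects objective. Measured at
  1000 simulations (n = 120, B = 20) by the property test in
  `tests/test_acceptance.py`: index rejection 0.155, interaction rejection
  0.052 (nominal band 0.05 ± 0.021).

## Determinism and seeds

All seeds are derived deterministically and stay below 2³¹:

- Generator: `SeedSequence(config.seed).spawn(3)` — one child per stage
  (subjects, exposures, trials).
- Bootstrap: replicate b uses spawned child b+1 of the master seed.
- Strata: girls `2·seed`, boys `2·seed+1` (mod 2³¹).
- Submixture subsets: `(seed·1000003 + k) mod 2³¹` for subset k.
- Pipeline slots: `(seed·1000003 + 64·outcome + 8·direction + analysis)
  mod 2³¹`.

Re-running `run_all` with the same master seed reproduces byte-identical
output files; `manifest.json` records SHA-256 digests of every artifact.

## Problem sizes and runtimes (1 CPU)

- Gaussian mixed model, n=188×8: ~0.7 s.
- ZIP mixed model (Laplace phase + AGQ-7 + FD Hessian): ~9 s.
- 100-bootstrap weight estimation, n=188, c=20: ~2 s.
- Full `run_all` without submixtures, B=100: ~1 min; submixture scan adds
  36 constrained fits × B per outcome.
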