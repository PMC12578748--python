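# Methods

## Problem and estimands

`mixsurv` estimates the effect of a mixture of correlated, continuous
environmental exposures **M** = (M₁, …, M_J) on a right-censored
time-to-event outcome, conditional on confounders **C**. Effects are
summarized by interquartile-range (IQR) contrasts between counterfactual
covariate profiles:

- **Mixture hazard ratio** λ⁷⁵(t|C) / λ²⁵(t|C): all exposures jointly at
  their 75th vs their 25th empirical percentiles.
- **Mixture survival probability difference** S⁷⁵(t|C) − S²⁵(t|C) at a
  pre-specified evaluation time `t_spec` (default: the 80th percentile of
  observed follow-up).
- **Single-exposure HR/SPD**: exposure j moves across its IQR while
  co-exposures sit at their medians.
- **Multiplicative interaction** between exposures j and k: the symmetric
  double contrast λ(q75ⱼ,q75ₖ)·λ(q25ⱼ,q25ₖ) / [λ(q75ⱼ,q25ₖ)·λ(q25ⱼ,q75ₖ)],
  which equals 1 for any hazard without a j×k product term.
- **Exposure-response curves**: S(t_spec) as exposure j sweeps its
  0.05, 0.10, …, 0.95 quantile grid, all else at medians.

Profile conventions: empirical quantiles use linear interpolation between
order statistics everywhere (profiles, `t_spec`, time bins). Confounders
enter profiles at their medians, except that a two-valued (binary)
confounder is fixed at its lower (reference) level: the sample median of a
balanced binary covariate flips between its levels across datasets, which
would inject spurious between-replicate variance into every conditional
estimand while estimating nothing.

## Modeling frameworks

**Proportional hazards (PH).** λ(t; m, c) = λ₀(t)·exp(f(m, c)). The five
PH learners differ in how f is estimated:

| learner | f(m, c) | fitting |
|---|---|---|
| `cox_ph` | linear main effects | partial likelihood (in-package Newton solver) |
| `cox_ph_int` | + all pairwise exposure products | partial likelihood |
| `cox_ph_ps` | penalized cubic B-spline per exposure (10 basis functions), tensor-product interaction smooths when J=5, linear confounders | penalized partial likelihood |
| `cox_en` | linear main effects | elastic net (coxnet path), confounders unpenalized |
| `cox_en_int` | + pairwise products, all exposure terms penalized | elastic net |

Survival predictions compose the Breslow baseline cumulative-hazard
estimator (step interpolation) with exp(f); the log hazard contrast is a
difference of linear predictors and is constant in t.

The Newton solver implements the Breslow-ties partial likelihood with an
optional quadratic penalty matrix; it exists because the simulation study
refits Cox models thousands of times (bootstrap × replicates) and the
general-purpose fitters carry ~0.2 s per-fit overhead. It is validated
against lifelines (coefficients, standard errors, survival predictions) in
the test suite.

For `cox_ph_ps` the penalty is the exact integrated squared second
derivative of each exposure's spline (so heavy smoothing shrinks toward a
*linear* effect — a plain coefficient ridge would shrink toward a
distorted non-constant shape and bias the contrasts) plus a ridge on the
interaction tensors (shrinking toward no interaction). One common
smoothing parameter is chosen by k-fold cross-validated held-out partial
likelihood over a log-spaced grid (default {10, 10³, 10⁵}, 3 folds). With
J=10 the pairwise interaction smooths are dropped with a warning; the
saturated tensor model is not reliably estimable there.

`cox_en`/`cox_en_int` select (l1_ratio, α) over the grid
l1_ratio ∈ {0.25, 0.5, 0.75, 1.0} × a 20-point α path by k-fold (default 5)
cross-validated held-out partial likelihood; confounders have penalty
factor 0.

**Discrete time.** Follow-up is cut into R bins (default R = 5; R = 10 as
sensitivity) at the 1/R, …, 1 empirical quantiles of observed times,
left-closed/right-open, boundary times belonging to the right bin. Each
subject contributes one person-period row per bin up to the bin containing
their observed time; the binary outcome Y is 1 only in the final row of an
event subject. Any binary classifier fit on this table with the bin's
representative time (midpoint) as a covariate estimates the discrete
hazard h_r(x); survival is recovered as S = Π_{r}(1−h_r). For a time t
inside bin r the partial bin contributes geometrically, (1−h_r)^frac with
frac the fraction of the bin elapsed — without this, an evaluation time at
a bin's left edge would be charged the full bin hazard. The discrete
hazard ratio between two profiles is h_a[r]/h_b[r] in the bin containing
`t_spec`; when per-bin probabilities are small it approximates the
continuous-time hazard ratio (at R=10 under the log-linear variant the
discretization attenuation of the mixture HR is ≈4%; at R=5 it is ≈9%,
which is why bias-sensitive comparisons for the discrete learners use
R=10).

Two discrete-time learners:

- `mars_dt` — adaptive hinge-basis logistic regression in the spirit of
  multivariate adaptive regression splines: reflected hinge pairs
  max(x−k, 0)/max(k−x, 0) at candidate knots (7 interior quantiles per
  predictor, including the bin time) are grown forward by correlation with
  the working residuals of the current logistic fit; degree-2 terms are
  products of a candidate hinge with an existing term. The number of
  retained terms and the interaction degree are cross-validated by
  subject-blocked deviance over {11, 21, 31} × {1, 2} by default. This is
  an in-package implementation (no MARS package exists in the supported
  environment); the model metadata records it.
- `bart_dt` — a probabilistic tree ensemble with logit link: each of
  n_draws (default 100) posterior draws refits a gradient-boosted tree
  ensemble (lightgbm; 50 trees, 8 leaves, learning rate 0.1) on the
  person-period table with subject-level Bayesian-bootstrap (Dirichlet)
  weights. Estimands are computed per draw; their spread is the posterior
  uncertainty. Shallow trees, shrinkage and draw averaging play the
  regularizing role of a tree prior. This is an in-package substitute for
  a native Bayesian additive tree sampler, recorded in the model metadata.

## Uncertainty

Frequentist learners: nonparametric bootstrap over subjects (resampling
*before* person-period expansion, preserving within-subject row
dependence), with a full refit — including cross-validation, re-binning
and recomputation of the counterfactual profiles from the resample — per
resample. Default B=200 (100 at desk scale). Bayesian learner: the
estimand evaluated on each posterior draw (≥100 draws required). Both
report the SD of the draws and percentile 2.5/97.5 limits; percentile
intervals are order statistics and are not forced to contain the point
estimate (a warning flags the pathological case).

## Synthetic scenarios and ground truth

The generator emulates a prospective cohort: n=3000 subjects, J positive
exposures with lognormal(0, 0.5) marginals through a Gaussian copula, two
confounders (one Bernoulli(½), one standard normal, both weakly coupled to
the exposures with latent correlation 0.12), a Weibull baseline hazard
(shape 1.2, rate 0.004, time in years) multiplied by exp(f(m, c)), and
independent Uniform(0, c_max) censoring with c_max calibrated by bisection
on a 100 000-subject fixed-seed sample to a ~67% censored fraction.

The latent exposure–exposure correlations are drawn once per structure
from U[0.1, 0.4] (scenarios 1, 2, 4) or U[0.7, 0.9] (scenario 3) with a
fixed internal seed, so the correlation matrix — and therefore the ground
truth — is a property of the scenario, not of the dataset seed. A
non-positive-definite draw would be projected to the nearest correlation
matrix (logged); the default structures are positive definite as drawn.

The log relative hazard mixes the effect shapes the scenarios call for:

    f(m, c) = 0.35·m₁ + 0·m₂ + 1.0·log m₃ + 1.5·max(m₄ − 1, 0)
              + 0.25·m₅ + 0.2·m₁m₅ + 0.4·c₁ + 0.25·c₂

Exposure 2 is exactly null (its truth values are HR=1, SPD=0, a flat
curve); exposures 6–10 in the high-dimensional scenario alternate null and
weak linear (0.1). The log and hinge coefficients are set so that
log-linear models visibly misfit the two nonlinear curves, the regime the
comparison is about; milder settings make every learner's curve
near-linear and the comparison uninformative. In scenario 4 the PH
violation is a decaying exposure-1 coefficient, β₁(t) = β₁(1 − t/30),
giving a smooth, integrable hazard whose cumulative has a closed
incomplete-gamma form; event times are inverted exactly with
`gammaincinv`, with a cured fraction (subjects whose total cumulative
hazard stays below the drawn exponential deviate) capped at t=500, far
beyond any attainable censoring time. Two auxiliary link variants support
calibration studies: `linear` (all exposures log-linear, exposure 2 still
null) and `null` (no exposure effects).

Truth values are closed-form: HR = exp(Δf), S = exp(−Λ₀(t)e^f) with
Weibull Λ₀ (incomplete-gamma Λ in scenario 4; a quadrature cross-check to
1e-8 is in the tests). Truth-side percentiles come from a fixed-seed
10⁶-sample of the exposure distribution, so the truth is one number per
scenario; estimators use each analysis dataset's own empirical
percentiles, as an analyst would.

**What the generator does not emulate:** covariate-dependent or
informative censoring, time-varying exposures, measurement error,
missing data, competing risks, and real-world departures from the Gaussian
copula / lognormal marginal family. Passing tests therefore certify the
estimation machinery under a known, well-behaved mixture DGP — not
performance on any particular cohort.

## Simulation study and metrics

`run_study` crosses scenarios × learners × replicates: generate a dataset,
take `t_spec` from the scenario rule, fit each learner, compute each
estimand with uncertainty, join with truth. Per-cell JSON checkpoints make
a finished study byte-stable under resumption. Metrics follow the printed
formulas: relative bias (Ω_truth − Ω̂_f)/Ω_truth (overestimates are
negative; SPD truths within 1e-3 of zero are summarized as raw bias with a
flag); coverage (1/F)·Σ 1{ll_f ≤ Ω_truth ≤ ul_f}, boundaries inclusive;
MISE = mean over replicates of the mean squared survival difference on the
19-point quantile grid. Summaries report the median (and its absolute
value) of relative bias and the median SD, with means in secondary
columns.

Desk-scale defaults are F=50 replicates and B=100 bootstrap resamples
(F=500/B=200 are configuration choices away); the acceptance checks use
F=50 for the calibration study and F=30 for the ordering comparisons.

## Known limitations

- The discrete-hazard-ratio estimand is attenuated relative to the
  continuous HR when per-bin event probabilities are large; use more bins
  or the SPD when this matters.
- Person-period augmentation treats a subject censored inside a bin as at
  risk for the whole bin (the convention the augmentation defines), which
  slightly understates discrete hazards under heavy censoring; the Cox
  family handles censoring exactly and does not share this.
- Bootstrap intervals after variable selection (the elastic net) inherit
  the usual post-selection undercoverage; no correction is applied.
- The interaction and single-exposure contrasts are conditional,
  profile-based quantities; they are not averaged over the co-exposure
  distribution.
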