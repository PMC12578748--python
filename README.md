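# mixsurv

Joint, individual and interaction effects of environmental exposure
mixtures on survival outcomes.

Environmental epidemiology increasingly analyzes the *whole* mixture of
correlated, continuous exposures (e.g. a metal panel) rather than one
pollutant at a time, but most mixture methods target continuous or binary
outcomes. `mixsurv` brings the mixture viewpoint to right-censored
time-to-event data. It is aimed at biostatisticians and environmental
epidemiologists who want comparable effect estimates — with honest
uncertainty — from both classical proportional-hazards models and
flexible machine-learning-style learners, plus a simulation harness with
closed-form ground truth to study when each approach can be trusted.

## Estimands

For exposures **M** = (M₁, …, M_J) and confounders **C**, with λ^q(t|C)
and S^q(t|C) the hazard and survival when every exposure sits at its qth
percentile, the package estimates at a pre-specified time t_spec:

- mixture hazard ratio **λ⁷⁵(t|C)/λ²⁵(t|C)** and survival probability
  difference **S⁷⁵(t|C) − S²⁵(t|C)** (an interquartile-range contrast of
  the whole mixture);
- the same contrasts for a single exposure, co-exposures at medians;
- the multiplicative interaction between two exposures (a ratio of hazard
  ratios, 1 under no interaction);
- exposure-response curves: S(t_spec) over an exposure's
  0.05 … 0.95 quantile grid.

Seven learners span two frameworks: Cox proportional hazards (plain, with
pairwise interactions, with penalized splines, and elastic net with and
without interactions) and discrete-time survival via person-period
augmentation (an adaptive hinge-basis logistic model in the spirit of
MARS, and a Bayesian-bootstrap tree ensemble with posterior draws).
Frequentist learners get subject-level bootstrap intervals with full
refits; the tree ensemble gets posterior percentile intervals. See
`docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import numpy as np
from mixsurv import (
    ScenarioConfig, generate_dataset, compute_truth, LearnerSpec, fit,
    mixture_effect, choose_t_spec, EstimandRequest, bootstrap_estimand,
)

config = ScenarioConfig(scenario_id=1, n_subjects=3000, seed=7)
data = generate_dataset(config)
print(f"censored fraction: {data.censored_fraction:.3f}")

t_spec = choose_t_spec(data, "percentile", 0.8)
print(f"t_spec (80th pct of follow-up): {t_spec:.2f} years")

model = fit(LearnerSpec("cox_ph_ps", {"seed": 0}), data)
hr, spd = mixture_effect(model, data, t_spec)
print(f"mixture HR  (75th vs 25th): {hr.point:.2f}")
print(f"mixture SPD (75th vs 25th): {spd.point:+.3f}")

boot = bootstrap_estimand(
    LearnerSpec("cox_ph"), data, EstimandRequest("mixture_hr", t_spec),
    n_boot=100, seed=1,
)
print(f"cox_ph mixture HR 95% CI: [{boot.ci_low:.2f}, {boot.ci_high:.2f}] (sd {boot.sd:.2f})")

truth = compute_truth(config)
print(f"true mixture HR: {truth.hr_mixture:.2f}; true SPD: {truth.spd_mixture:+.3f}")
```

Output:

```
censored fraction: 0.679
t_spec (80th pct of follow-up): 15.36 years
mixture HR  (75th vs 25th): 10.14
mixture SPD (75th vs 25th): -0.510
cox_ph mixture HR 95% CI: [7.77, 10.47] (sd 0.72)
true mixture HR: 7.24; true SPD: -0.478
```

Reading it: about 68% of subjects are censored, matching the scenario's
calibrated target. Moving every exposure from its 25th to its 75th
percentile multiplies the hazard by ~7 in truth; the penalized-spline fit
estimates ~10 on this dataset (flexible learners are variable at a single
n=3000 replicate), and survival at 15.4 years drops by ~0.51. The plain
Cox model's bootstrap interval sits above the truth — this base-case
mixture has nonlinear components that a log-linear model mis-attributes,
which is precisely the phenomenon the simulation study quantifies.

Real datasets enter the same way through `SurvivalDataset.from_frame` on
a table with columns `time,event,M1..MJ,C1..CL`.

## Simulation study

`mixsurv simulate` writes a scenario dataset (and optionally its truth
manifest); `mixsurv evaluate --config study.yaml --out results/` runs the
scenario × learner × replicate study, writing per-replicate rows,
bias/SD/coverage summaries, per-learner curve tables, MISE tables and
figures. Scenarios: (1) base case, J=5 correlated exposures with
nonlinear effects, PH holds; (2) as 1 with J=10; (3) as 1 with high
correlations; (4) as 1 with a PH violation. Ground truth is closed-form
throughout.

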