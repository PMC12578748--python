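"""Counterfactual estimands: mixture, single-exposure, interaction and
exposure-response-curve effects from any fitted survival model.

The central contrast is the interquartile-range (IQR) mixture effect: the
hazard ratio lambda^75(t|C) / lambda^25(t|C) and the survival probability
difference S^75(t|C) - S^25(t|C) comparing all exposures jointly at their
75th versus their 25th empirical percentiles, confounders at reference
values.  Single-exposure effects move one exposure across its IQR while
holding co-exposures at their medians; the interaction effect between two
exposures is the symmetric double-contrast ratio of hazard ratios; and the
exposure-response curve traces the survival probability at ``t_spec`` as
one exposure moves across its 0.05..0.95 quantile grid.

Empirical percentiles use the linear-interpolation quantile convention
throughout (profiles, t_spec, time bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .learners import FittedSurvivalModel
from .scenarios import CURVE_GRID, SurvivalDataset

__all__ = [
    "CounterfactualProfile",
    "EstimandEstimate",
    "build_profile",
    "mixture_effect",
    "single_exposure_effect",
    "interaction_effect",
    "exposure_response_curve",
    "choose_t_spec",
]


@dataclass
class CounterfactualProfile:
    """A complete covariate vector with exposures at stated percentiles of
    the training data and confounders at reference values."""

    exposures: np.ndarray
    confounders: np.ndarray
    percentile_labels: tuple

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.exposures, self.confounders])


@dataclass
class EstimandEstimate:
    """A point estimate of one quantity of interest at ``t_spec``."""

    kind: str  # mixture_hr | mixture_spd | single_hr | single_spd | interaction | curve
    t_spec: float
    point: float | np.ndarray
    exposures_involved: tuple = ()
    curve_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind in ("mixture_hr", "single_hr", "interaction"):
            if not np.all(np.asarray(self.point) > 0):
                raise ValueError(f"{self.kind} must be positive, got {self.point}")
        if self.kind in ("mixture_spd", "single_spd"):
            if not -1.0 <= float(self.point) <= 1.0:
                raise ValueError(f"{self.kind} must lie in [-1, 1], got {self.point}")
        if self.kind == "curve":
            pts = np.asarray(self.point)
            if np.any((pts < 0) | (pts > 1)):
                raise ValueError("curve values must lie in [0, 1]")


def build_profile(
    data: SurvivalDataset,
    percentiles: float | np.ndarray,
    confounder_rule: str = "medians",
) -> CounterfactualProfile:
    """Set each exposure to its stated empirical percentile; confounders at
    their medians (the only rule currently defined)."""
    if data.n_subjects == 0:
        raise ValueError("empty dataset")
    j = len(data.exposure_names)
    labels = np.broadcast_to(np.asarray(percentiles, dtype=float), (j,))
    if np.any((labels <= 0) | (labels >= 1)):
        raise ValueError("percentile labels must lie in (0, 1)")
    exposures = np.array(
        [data.exposures.iloc[:, a].quantile(labels[a]) for a in range(j)]
    )
    if confounder_rule != "medians":
        raise ValueError(f"unknown confounder rule {confounder_rule!r}")
    confounders = reference_confounders(data.confounders)
    return CounterfactualProfile(exposures, confounders, tuple(labels))


def reference_confounders(confounders) -> np.ndarray:
    """Reference confounder values: medians for continuous columns; the
    lower (reference) level for two-valued columns.

    The sample median of a balanced binary covariate flips between its two
    levels across datasets, which would inject spurious between-replicate
    variance into every conditional estimand; a fixed reference level keeps
    the conditioning stable.
    """
    out = np.empty(confounders.shape[1])
    for i, col in enumerate(confounders.columns):
        vals = confounders[col].to_numpy()
        uniq = np.unique(vals)
        out[i] = uniq.min() if len(uniq) <= 2 else np.median(vals)
    return out


def mixture_effect(
    model: FittedSurvivalModel,
    data: SurvivalDataset,
    t_spec: float,
    draw: int | None = None,
) -> tuple[EstimandEstimate, EstimandEstimate]:
    """IQR mixture effect: (hazard ratio, survival probability difference)
    for all exposures jointly at their 75th vs 25th percentiles."""
    p75 = build_profile(data, 0.75)
    p25 = build_profile(data, 0.25)
    hr = float(
        np.exp(model.predict_log_hazard_contrast(p75.values, p25.values, t_spec, draw=draw))
    )
    spd = model.predict_survival(p75.values, t_spec, draw=draw) - model.predict_survival(
        p25.values, t_spec, draw=draw
    )
    return (
        EstimandEstimate("mixture_hr", t_spec, hr),
        EstimandEstimate("mixture_spd", t_spec, float(spd)),
    )


def _single_profiles(data: SurvivalDataset, j: int):
    jj = len(data.exposure_names)
    if not 0 <= j < jj:
        raise IndexError(f"exposure index {j} out of range for J={jj}")
    hi_labels = np.full(jj, 0.5)
    hi_labels[j] = 0.75
    lo_labels = np.full(jj, 0.5)
    lo_labels[j] = 0.25
    return build_profile(data, hi_labels), build_profile(data, lo_labels)


def single_exposure_effect(
    model: FittedSurvivalModel,
    data: SurvivalDataset,
    j: int,
    t_spec: float,
    draw: int | None = None,
) -> tuple[EstimandEstimate, EstimandEstimate]:
    """IQR effect of exposure ``j`` (0-based) with co-exposures held at
    their medians, confounders at medians."""
    hi, lo = _single_profiles(data, j)
    hr = float(
        np.exp(model.predict_log_hazard_contrast(hi.values, lo.values, t_spec, draw=draw))
    )
    spd = model.predict_survival(hi.values, t_spec, draw=draw) - model.predict_survival(
        lo.values, t_spec, draw=draw
    )
    return (
        EstimandEstimate("single_hr", t_spec, hr, exposures_involved=(j,)),
        EstimandEstimate("single_spd", t_spec, float(spd), exposures_involved=(j,)),
    )


def interaction_effect(
    model: FittedSurvivalModel,
    data: SurvivalDataset,
    j: int,
    k: int,
    t_spec: float,
    draw: int | None = None,
) -> EstimandEstimate:
    """Multiplicative interaction between exposures ``j`` and ``k``: the
    ratio of the exposure-j hazard ratio evaluated with exposure k at its
    75th vs its 25th percentile (a symmetric double contrast on the hazard
    scale), other exposures and confounders at medians.  Equals 1 for any
    model without a j-k product term."""
    if j == k:
        raise ValueError("interaction requires two distinct exposures")
    jj = len(data.exposure_names)
    labels = np.full(jj, 0.5)

    def profile(qj: float, qk: float) -> np.ndarray:
        lab = labels.copy()
        lab[j] = qj
        lab[k] = qk
        return build_profile(data, lab).values

    hh, hl = profile(0.75, 0.75), profile(0.75, 0.25)
    lh, ll = profile(0.25, 0.75), profile(0.25, 0.25)
    log_ratio = model.predict_log_hazard_contrast(
        hh, hl, t_spec, draw=draw
    ) - model.predict_log_hazard_contrast(lh, ll, t_spec, draw=draw)
    return EstimandEstimate(
        "interaction", t_spec, float(np.exp(log_ratio)), exposures_involved=tuple(sorted((j, k)))
    )


def exposure_response_curve(
    model: FittedSurvivalModel,
    data: SurvivalDataset,
    j: int,
    t_spec: float,
    draw: int | None = None,
) -> EstimandEstimate:
    """Survival probability at ``t_spec`` as exposure ``j`` moves across
    the 0.05..0.95 quantile grid, all else at medians."""
    jj = len(data.exposure_names)
    if not 0 <= j < jj:
        raise IndexError(f"exposure index {j} out of range for J={jj}")
    curve = np.empty(len(CURVE_GRID))
    for qi, q in enumerate(CURVE_GRID):
        labels = np.full(jj, 0.5)
        labels[j] = q
        prof = build_profile(data, labels)
        curve[qi] = model.predict_survival(prof.values, t_spec, draw=draw)
    return EstimandEstimate(
        "curve", t_spec, curve, exposures_involved=(j,), curve_grid=CURVE_GRID.copy()
    )


def choose_t_spec(data: SurvivalDataset, rule: str = "percentile", value: float = 0.8) -> float:
    """Evaluation time: ``percentile`` returns the empirical quantile of
    observed follow-up (default the 80th percentile); ``fixed`` passes
    ``value`` through."""
    if rule == "fixed":
        return float(value)
    if rule == "percentile":
        if not 0.0 < value < 1.0:
            raise ValueError("percentile must lie in (0, 1)")
        return float(np.quantile(data.time, value))
    raise ValueError(f"unknown t_spec rule {rule!r}")
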