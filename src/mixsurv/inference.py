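"""Uncertainty for estimands: nonparametric bootstrap or posterior draws.

Frequentist learners get subject-level bootstrap resampling with a full
refit per resample (cross-validation, time bins and counterfactual
profiles are all recomputed on the resampled data, mirroring what an
analyst would do); Bayesian learners get the estimand evaluated on each
posterior draw.  Both report the SD of the draws and percentile 2.5/97.5
interval limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import estimands as est
from .learners import FittedSurvivalModel, LearnerSpec, fit
from .scenarios import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "EstimandRequest",
    "UncertaintySummary",
    "evaluate_request",
    "bootstrap_estimand",
    "posterior_estimand",
]

#: minimum posterior draws a Bayesian learner must expose
MIN_POSTERIOR_DRAWS = 100


@dataclass(frozen=True)
class EstimandRequest:
    """Which quantity to compute: kind plus exposure indices and t_spec.

    ``kind`` is one of mixture_hr, mixture_spd, single_hr, single_spd,
    interaction, curve.  ``j``/``k`` are 0-based exposure indices where
    relevant.
    """

    kind: str
    t_spec: float
    j: int | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        kinds = ("mixture_hr", "mixture_spd", "single_hr", "single_spd", "interaction", "curve")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind in ("single_hr", "single_spd", "curve") and self.j is None:
            raise ValueError(f"{self.kind} requires an exposure index j")
        if self.kind == "interaction" and (self.j is None or self.k is None):
            raise ValueError("interaction requires exposure indices j and k")


def evaluate_request(
    request: EstimandRequest,
    model: FittedSurvivalModel,
    data: SurvivalDataset,
    draw: int | None = None,
) -> float | np.ndarray:
    """Point value of a requested estimand for one fitted model."""
    t = request.t_spec
    if request.kind == "mixture_hr":
        return est.mixture_effect(model, data, t, draw=draw)[0].point
    if request.kind == "mixture_spd":
        return est.mixture_effect(model, data, t, draw=draw)[1].point
    if request.kind == "single_hr":
        return est.single_exposure_effect(model, data, request.j, t, draw=draw)[0].point
    if request.kind == "single_spd":
        return est.single_exposure_effect(model, data, request.j, t, draw=draw)[1].point
    if request.kind == "interaction":
        return est.interaction_effect(model, data, request.j, request.k, t, draw=draw).point
    return est.exposure_response_curve(model, data, request.j, t, draw=draw).point


@dataclass
class UncertaintySummary:
    """SD and percentile interval of an estimand, from bootstrap resamples
    or posterior draws.

    Percentile intervals are order statistics of the draws, so for scalar
    estimands ci_low <= ci_high always holds; the interval is not forced to
    contain the point estimate (flagged when it does not).
    """

    sd: float | np.ndarray
    ci_low: float | np.ndarray
    ci_high: float | np.ndarray
    n_draws: int
    mechanism: str  # bootstrap | posterior
    draws: np.ndarray | None = None

    def contains(self, value: float) -> bool:
        return bool(self.ci_low <= value <= self.ci_high)

    def flag_point(self, point: float) -> None:
        if np.isscalar(point) and not (self.ci_low <= point <= self.ci_high):
            logger.warning(
                "percentile interval [%.4g, %.4g] excludes the point estimate %.4g",
                self.ci_low,
                self.ci_high,
                point,
            )


def _summarize(draws: np.ndarray, mechanism: str, keep_draws: bool) -> UncertaintySummary:
    draws = np.asarray(draws, dtype=float)
    sd = draws.std(axis=0, ddof=1)
    lo = np.quantile(draws, 0.025, axis=0)
    hi = np.quantile(draws, 0.975, axis=0)
    if draws.ndim == 1:
        sd, lo, hi = float(sd), float(lo), float(hi)
    return UncertaintySummary(
        sd=sd,
        ci_low=lo,
        ci_high=hi,
        n_draws=len(draws),
        mechanism=mechanism,
        draws=draws if keep_draws else None,
    )


def bootstrap_estimand(
    spec: LearnerSpec,
    data: SurvivalDataset,
    request: EstimandRequest,
    n_boot: int = 200,
    seed: int = 0,
    keep_draws: bool = False,
    max_failure_fraction: float = 0.1,
) -> UncertaintySummary:
    """Nonparametric bootstrap of a requested estimand.

    Subjects are resampled with replacement; each resample is refit from
    scratch.  Resamples whose refit fails are dropped and counted; more
    than ``max_failure_fraction`` failures is an error.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    rng = np.random.default_rng(seed)
    n = data.n_subjects
    values = []
    failures = 0
    last_error: Exception | None = None
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resample = SurvivalDataset(
            time=data.time[idx],
            event=data.event[idx],
            exposures=data.exposures.iloc[idx].reset_index(drop=True),
            confounders=data.confounders.iloc[idx].reset_index(drop=True),
        )
        try:
            model = fit(spec, resample)
            values.append(evaluate_request(request, model, resample))
        except (RuntimeError, ValueError, ZeroDivisionError) as err:
            failures += 1
            last_error = err
    if not values:
        raise RuntimeError(f"all bootstrap refits failed; last error: {last_error}")
    if failures > max_failure_fraction * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap refits failed; last error: {last_error}"
        )
    if failures:
        logger.warning("%d/%d bootstrap refits failed and were dropped", failures, n_boot)
    return _summarize(np.asarray(values), "bootstrap", keep_draws)


def posterior_estimand(
    model: FittedSurvivalModel,
    data: SurvivalDataset,
    request: EstimandRequest,
    keep_draws: bool = False,
) -> UncertaintySummary:
    """Posterior summary of a requested estimand from a posterior-capable
    fitted model (>= 100 draws required)."""
    n_draws = getattr(model, "n_posterior_draws", 0)
    if n_draws < MIN_POSTERIOR_DRAWS:
        raise ValueError(
            f"model exposes {n_draws} posterior draws; need >= {MIN_POSTERIOR_DRAWS}"
        )
    values = [evaluate_request(request, model, data, draw=d) for d in range(n_draws)]
    return _summarize(np.asarray(values), "posterior", keep_draws)
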