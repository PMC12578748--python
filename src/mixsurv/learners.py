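"""Survival-model adapters: one fitted-model contract, seven learners.

Two modeling frameworks share the contract.  Proportional-hazards (PH)
learners estimate a log relative hazard f(m, c) under lambda(t) =
lambda0(t) exp(f) with a Breslow baseline; discrete-time learners fit a
binary-outcome model for the per-bin event probability on the person-period
table and recover survival as a product of per-bin survival probabilities.

Learners
--------
==============  ===================  ============
name            framework            uncertainty
==============  ===================  ============
``cox_ph``      proportional_hazards bootstrap
``cox_ph_int``  proportional_hazards bootstrap
``cox_ph_ps``   proportional_hazards bootstrap
``cox_en``      proportional_hazards bootstrap
``cox_en_int``  proportional_hazards bootstrap
``mars_dt``     discrete_time        bootstrap
``bart_dt``     discrete_time        posterior
==============  ===================  ============

``cox_ph``/``cox_ph_int`` are linear Cox fits (the latter adds all pairwise
exposure products); ``cox_ph_ps`` replaces each exposure main effect by a
penalized B-spline (plus tensor-product interaction smooths when J=5; these
are dropped with a warning when J=10, where the saturated interaction model
does not fit reliably); ``cox_en``/``cox_en_int`` are the same linear
predictors with an elastic-net penalty on exposure terms only, tuned by
cross-validated held-out partial likelihood; ``mars_dt`` is an adaptive
hinge-basis (piecewise-linear) logistic model with optional degree-2
products, selected forward on the person-period table; ``bart_dt`` is a
probabilistic tree ensemble with a logit link whose posterior draws come
from Bayesian-bootstrap reweighting of subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import BSpline

from ._cox import breslow_baseline, breslow_cumhaz_at, fit_cox_newton
from .discrete_time import TimeBins, augment, make_time_bins, survival_from_bin_hazards
from .scenarios import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = ["LearnerSpec", "FittedSurvivalModel", "fit", "LEARNER_NAMES"]

LEARNER_NAMES = (
    "cox_ph",
    "cox_ph_int",
    "cox_ph_ps",
    "cox_en",
    "cox_en_int",
    "mars_dt",
    "bart_dt",
)

_DISCRETE = {"mars_dt", "bart_dt"}


@dataclass
class LearnerSpec:
    """A learner name plus hyperparameter overrides.

    Framework and uncertainty mechanism are functions of the name:
    ``cox_*`` learners are proportional-hazards models with bootstrap
    uncertainty; ``mars_dt`` is discrete-time with bootstrap; ``bart_dt``
    is discrete-time with posterior draws.
    """

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in LEARNER_NAMES:
            raise ValueError(f"unknown learner {self.name!r}; choose from {LEARNER_NAMES}")

    @property
    def framework(self) -> str:
        return "discrete_time" if self.name in _DISCRETE else "proportional_hazards"

    @property
    def uncertainty(self) -> str:
        return "posterior" if self.name == "bart_dt" else "bootstrap"

    def hyper(self, key: str, default):
        return self.hyperparameters.get(key, default)


class FittedSurvivalModel:
    """Contract shared by all fitted learners.

    A fitted model answers ``predict_survival(profile, t)`` for any time
    within observed follow-up and any complete covariate profile (exposures
    then confounders, in training-column order), and
    ``predict_log_hazard_contrast(a, b, t)`` for the log relative hazard
    between two profiles.  Posterior-capable models additionally expose
    ``n_posterior_draws`` >= 100 and accept a ``draw`` index.
    """

    def __init__(self, spec: LearnerSpec, data: SurvivalDataset, metadata: dict):
        self.spec = spec
        self.columns = data.exposure_names + data.confounder_names
        self.n_exposures = len(data.exposure_names)
        self.exposure_quantiles = data.exposures.quantile
        self.confounder_medians = data.confounders.median().to_numpy()
        self.max_time = float(data.time.max())
        self.metadata = metadata
        self.n_posterior_draws = 0

    # -- subclass API ------------------------------------------------------
    def _survival(self, profile: np.ndarray, t: float, draw: int | None) -> float:
        raise NotImplementedError

    def _log_hazard_contrast(
        self, a: np.ndarray, b: np.ndarray, t: float, draw: int | None
    ) -> float:
        raise NotImplementedError

    # -- contract ----------------------------------------------------------
    def _check_profile(self, profile: np.ndarray) -> np.ndarray:
        p = np.asarray(profile, dtype=float).ravel()
        if len(p) != len(self.columns):
            raise ValueError(
                f"profile has {len(p)} components, expected {len(self.columns)} "
                f"({self.columns})"
            )
        return p

    def _check_time(self, t: float) -> float:
        if t < 0:
            raise ValueError("t must be nonnegative")
        if t > self.max_time:
            logger.warning(
                "t=%.3g beyond observed follow-up %.3g; clamping", t, self.max_time
            )
            return self.max_time
        return float(t)

    def predict_survival(self, profile: np.ndarray, t: float, draw: int | None = None) -> float:
        """Conditional survival probability S(t | profile), in [0, 1]."""
        return self._survival(self._check_profile(profile), self._check_time(t), draw)

    def predict_log_hazard_contrast(
        self, profile_a: np.ndarray, profile_b: np.ndarray, t: float, draw: int | None = None
    ) -> float:
        """Log relative hazard between two profiles at time t (t is ignored
        by PH learners, whose hazard ratio is constant)."""
        a = self._check_profile(profile_a)
        b = self._check_profile(profile_b)
        return self._log_hazard_contrast(a, b, self._check_time(t), draw)


# ==========================================================================
# Proportional-hazards adapters
# ==========================================================================


class _PHModel(FittedSurvivalModel):
    """Any PH learner: a design-matrix map, coefficients and a Breslow
    baseline fully determine predictions."""

    def __init__(
        self,
        spec: LearnerSpec,
        data: SurvivalDataset,
        design_fn: Callable[[np.ndarray], np.ndarray],
        beta: np.ndarray,
        baseline_times: np.ndarray,
        baseline_increments: np.ndarray,
        metadata: dict,
    ):
        super().__init__(spec, data, metadata)
        self._design_fn = design_fn
        self.coef_ = beta
        self._baseline_times = baseline_times
        self._baseline_increments = baseline_increments

    def linear_predictor(self, profiles: np.ndarray) -> np.ndarray:
        return self._design_fn(np.atleast_2d(profiles)) @ self.coef_

    def _survival(self, profile: np.ndarray, t: float, draw) -> float:
        lp = self.linear_predictor(profile)[0]
        lam0 = breslow_cumhaz_at(self._baseline_times, self._baseline_increments, t)[0]
        return float(np.exp(-lam0 * np.exp(lp)))

    def _log_hazard_contrast(self, a, b, t, draw) -> float:
        lps = self.linear_predictor(np.vstack([a, b]))
        return float(lps[0] - lps[1])


def _pairwise_products(m: np.ndarray) -> np.ndarray:
    j = m.shape[1]
    cols = [m[:, a] * m[:, b] for a in range(j) for b in range(a + 1, j)]
    return np.column_stack(cols) if cols else np.empty((len(m), 0))


def _linear_design(n_exposures: int, interactions: bool) -> Callable[[np.ndarray], np.ndarray]:
    def design(profiles: np.ndarray) -> np.ndarray:
        m = profiles[:, :n_exposures]
        c = profiles[:, n_exposures:]
        parts = [m]
        if interactions:
            parts.append(_pairwise_products(m))
        parts.append(c)
        return np.column_stack(parts)

    return design


def _fit_cox_linear(spec: LearnerSpec, data: SurvivalDataset, interactions: bool) -> _PHModel:
    design = _linear_design(len(data.exposure_names), interactions)
    x = design(
        np.column_stack([data.exposures.to_numpy(), data.confounders.to_numpy()])
    )
    fit_res = fit_cox_newton(x, data.time, data.event)
    if not fit_res.converged:
        raise RuntimeError(f"{spec.name}: Cox partial-likelihood fit did not converge")
    meta = {"converged": True, "n_iter": fit_res.n_iter, "n_columns": x.shape[1]}
    model = _PHModel(
        spec, data, design, fit_res.beta,
        fit_res.baseline_times, fit_res.baseline_increments, meta,
    )
    model.standard_errors_ = fit_res.standard_errors()
    return model


# -- penalized splines -----------------------------------------------------


def _bspline_knots(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """Knot vector giving ``df`` B-spline basis functions over the range of
    the training values, interior knots at quantiles."""
    n_interior = df - degree - 1
    if n_interior < 0:
        raise ValueError("df too small for the spline degree")
    lo, hi = float(np.min(x)), float(np.max(x))
    interior = (
        np.quantile(x, np.arange(1, n_interior + 1) / (n_interior + 1))
        if n_interior
        else np.empty(0)
    )
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _bspline_eval(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    xc = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()


def _curvature_penalty(knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Integrated squared second derivative of the B-spline basis:
    Omega_ij = int B_i''(x) B_j''(x) dx.

    This is the smoothing-spline penalty: linear functions cost nothing,
    so heavy smoothing shrinks each exposure effect toward a straight line
    rather than toward zero.  For cubic splines the integrand is piecewise
    quadratic, so 2-point Gauss-Legendre per inter-knot interval is exact.
    """
    df = len(knots) - degree - 1
    breaks = np.unique(knots)
    gauss_x, gauss_w = np.polynomial.legendre.leggauss(2)
    omega = np.zeros((df, df))
    d2 = [
        BSpline.construct_fast(knots, np.eye(df)[i], degree).derivative(2)
        for i in range(df)
    ]
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        pts = mid + half * gauss_x
        vals = np.array([f(pts) for f in d2])  # df x 2
        omega += half * (vals * gauss_w) @ vals.T
    return omega


def _spline_design_builder(
    data: SurvivalDataset, df_main: int, include_interactions: bool
):
    """Build (design_fn, penalty_matrix) for the penalized-spline Cox model.

    Each exposure gets ``df_main`` cubic B-spline basis functions (first
    dropped: the basis partitions unity and the Cox model has no
    intercept); each exposure pair gets a 3 x 3 tensor of quadratic
    B-splines when interactions are included.  Confounders are linear and
    unpenalized.  The penalty is the P-spline second-difference form
    D2'D2 on each exposure's spline coefficients (so heavy smoothing
    shrinks toward a linear-in-basis effect rather than toward zero) and a
    ridge on the interaction tensors (shrinking toward no interaction).
    """
    m = data.exposures.to_numpy()
    j = m.shape[1]
    main_knots = [_bspline_knots(m[:, a], df_main, 3) for a in range(j)]
    int_knots = [_bspline_knots(m[:, a], 3, 2) for a in range(j)]

    def design(profiles: np.ndarray) -> np.ndarray:
        mm = profiles[:, :j]
        cc = profiles[:, j:]
        parts = [
            _bspline_eval(mm[:, a], main_knots[a], 3)[:, 1:] for a in range(j)
        ]
        if include_interactions:
            bases = [_bspline_eval(mm[:, a], int_knots[a], 2) for a in range(j)]
            for a in range(j):
                for b in range(a + 1, j):
                    parts.append(
                        (bases[a][:, :, None] * bases[b][:, None, :]).reshape(len(mm), -1)[:, 1:]
                    )
        parts.append(cc)
        return np.column_stack(parts)

    block = df_main - 1
    n_main = j * block
    n_int = (j * (j - 1) // 2) * 8 if include_interactions else 0
    n_conf = len(data.confounder_names)
    p_total = n_main + n_int + n_conf
    penalty = np.zeros((p_total, p_total))
    for a in range(j):
        # drop the first basis function's row/column to match the design;
        # the curvature penalty is invariant to the constant shift that the
        # drop represents
        omega = _curvature_penalty(main_knots[a], 3)[1:, 1:]
        # normalize so one smoothing parameter acts comparably across
        # exposures with different scales
        scale = np.trace(omega) / (block if np.trace(omega) > 0 else 1.0)
        sl = slice(a * block, (a + 1) * block)
        penalty[sl, sl] = omega / max(scale, 1e-300)
    if n_int:
        sl = slice(n_main, n_main + n_int)
        penalty[sl, sl] = np.eye(n_int)
    return design, penalty


def _cv_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    idx = np.random.default_rng(seed).permutation(n)
    return np.array_split(idx, k)


def _heldout_partial_likelihood(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> float:
    """Breslow log partial likelihood of a fixed coefficient vector."""
    from ._cox import _PartialLikelihood

    pl = _PartialLikelihood(x - x.mean(axis=0), time, event)
    return -pl.negll(beta, np.zeros((x.shape[1], x.shape[1])))


def _fit_cox_splines(spec: LearnerSpec, data: SurvivalDataset) -> _PHModel:
    j = len(data.exposure_names)
    want_interactions = spec.hyper("interactions", True)
    if want_interactions and j > 5:
        warnings.warn(
            "cox_ph_ps: pairwise smooth interactions are omitted for mixtures "
            "with more than 5 components (the saturated interaction model "
            "does not fit reliably)",
            stacklevel=2,
        )
        want_interactions = False
    df_main = spec.hyper("df", 10)
    grid = spec.hyper("penalty_grid", (10.0, 1e3, 1e5))
    folds = spec.hyper("cv_folds", 3)
    seed = spec.hyper("seed", 0)

    design, pen_matrix = _spline_design_builder(data, df_main, want_interactions)
    profiles = np.column_stack([data.exposures.to_numpy(), data.confounders.to_numpy()])
    x = design(profiles)

    chosen = grid[0]
    if len(grid) > 1:
        scores = {}
        splits = _cv_folds(len(x), folds, seed)
        for rho in grid:
            total = 0.0
            for i in range(folds):
                test = splits[i]
                train = np.concatenate([splits[a] for a in range(folds) if a != i])
                f = fit_cox_newton(
                    x[train], data.time[train], data.event[train], penalty=rho * pen_matrix
                )
                total += _heldout_partial_likelihood(
                    x[test], data.time[test], data.event[test], f.beta
                )
            scores[rho] = total
        chosen = max(scores, key=scores.get)
    fit_res = fit_cox_newton(x, data.time, data.event, penalty=chosen * pen_matrix)
    meta = {
        "converged": fit_res.converged,
        "penalty": chosen,
        "interactions": want_interactions,
        "n_columns": x.shape[1],
    }
    return _PHModel(
        spec, data, design, fit_res.beta,
        fit_res.baseline_times, fit_res.baseline_increments, meta,
    )


# -- elastic net -----------------------------------------------------------


def _fit_cox_elastic_net(
    spec: LearnerSpec, data: SurvivalDataset, interactions: bool
) -> _PHModel:
    """Elastic-net Cox fit (scikit-survival coxnet path); confounders are
    unpenalized; (l1_ratio, alpha) chosen by cross-validated held-out
    partial likelihood."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    design = _linear_design(len(data.exposure_names), interactions)
    profiles = np.column_stack([data.exposures.to_numpy(), data.confounders.to_numpy()])
    x = design(profiles)
    n_conf = len(data.confounder_names)
    pen_factor = np.concatenate([np.ones(x.shape[1] - n_conf), np.zeros(n_conf)])
    y = Surv.from_arrays(data.event.astype(bool), data.time)

    l1_grid = spec.hyper("l1_ratio_grid", (0.25, 0.5, 0.75, 1.0))
    folds = spec.hyper("cv_folds", 5)
    seed = spec.hyper("seed", 0)
    n_alphas = spec.hyper("n_alphas", 20)
    forced_alpha = spec.hyper("alpha", None)

    if forced_alpha is not None:
        l1 = l1_grid[0] if np.isscalar(l1_grid) or len(l1_grid) else 0.5
        best = (float(l1), float(forced_alpha))
    else:
        splits = _cv_folds(len(x), folds, seed)
        best_score, best = -np.inf, None
        for l1 in l1_grid:
            path = CoxnetSurvivalAnalysis(
                l1_ratio=l1, penalty_factor=pen_factor, n_alphas=n_alphas,
                alpha_min_ratio=0.01,
            ).fit(x, y)
            alphas = path.alphas_
            fold_scores = np.zeros(len(alphas))
            for i in range(folds):
                test = splits[i]
                train = np.concatenate([splits[a] for a in range(folds) if a != i])
                sub = CoxnetSurvivalAnalysis(
                    l1_ratio=l1, penalty_factor=pen_factor, alphas=alphas,
                ).fit(x[train], y[train])
                sub_alphas = np.asarray(sub.alphas_)
                for ai, alpha in enumerate(alphas):
                    # the path may stop early; use the nearest fitted alpha
                    pos = int(np.argmin(np.abs(np.log(sub_alphas) - np.log(alpha))))
                    beta = sub.coef_[:, pos]
                    fold_scores[ai] += _heldout_partial_likelihood(
                        x[test], data.time[test], data.event[test], beta
                    )
            ai = int(np.argmax(fold_scores))
            if fold_scores[ai] > best_score:
                best_score, best = fold_scores[ai], (float(l1), float(alphas[ai]))

    l1, alpha = best
    final = CoxnetSurvivalAnalysis(
        l1_ratio=l1, penalty_factor=pen_factor, alphas=[alpha],
        tol=spec.hyper("tol", 1e-7),
    ).fit(x, y)
    beta = final.coef_[:, 0]
    times, increments = breslow_baseline(x @ beta, data.time, data.event)
    meta = {"l1_ratio": l1, "alpha": alpha, "n_columns": x.shape[1], "converged": True}
    return _PHModel(spec, data, design, beta, times, increments, meta)


# ==========================================================================
# Discrete-time adapters
# ==========================================================================


class _DiscreteTimeModel(FittedSurvivalModel):
    """Any discrete-time learner: time bins plus a per-bin event-probability
    predictor determine predictions.

    ``hazard_fn(X, draw)`` maps rows of [exposures, confounders, bin_time]
    to conditional event probabilities.
    """

    def __init__(
        self,
        spec: LearnerSpec,
        data: SurvivalDataset,
        bins: TimeBins,
        hazard_fn: Callable[[np.ndarray, int | None], np.ndarray],
        metadata: dict,
    ):
        super().__init__(spec, data, metadata)
        self.bins = bins
        self._hazard_fn = hazard_fn

    def bin_hazards(self, profile: np.ndarray, draw: int | None = None) -> np.ndarray:
        """Predicted discrete hazard in every bin for one profile."""
        rep = self.bins.representative
        rows = np.column_stack(
            [np.tile(profile, (len(rep), 1)), rep]
        )
        return self._hazard_fn(rows, draw)

    def _survival(self, profile: np.ndarray, t: float, draw) -> float:
        if t == 0:
            return 1.0
        r = int(self.bins.bin_index(t)[0])
        b = self.bins.boundaries
        # fractional exposure to the bin containing t: geometric
        # interpolation (1 - h_r)^frac avoids charging the full bin hazard
        # for a time just past the bin's left edge
        frac = np.clip((t - b[r - 1]) / (b[r] - b[r - 1]), 0.0, 1.0)
        if t >= b[-1]:
            frac = 1.0

        def one(d):
            h = self.bin_hazards(profile, d)
            return survival_from_bin_hazards(h, r - 1) * (1.0 - h[r - 1]) ** frac

        if draw is None and self.n_posterior_draws:
            return float(np.mean([one(d) for d in range(self.n_posterior_draws)]))
        return float(one(draw))

    def _log_hazard_contrast(self, a, b, t, draw) -> float:
        r = int(self.bins.bin_index(t)[0])
        if draw is None and self.n_posterior_draws:
            vals = [
                self._contrast_one(a, b, r, d) for d in range(self.n_posterior_draws)
            ]
            return float(np.mean(vals))
        return self._contrast_one(a, b, r, draw)

    def _contrast_one(self, a, b, r, draw) -> float:
        h_a = self.bin_hazards(a, draw)
        h_b = self.bin_hazards(b, draw)
        from .discrete_time import bin_hazard_contrast

        return float(np.log(bin_hazard_contrast(h_a, h_b, r)))


def _person_period_design(data: SurvivalDataset, bins: TimeBins):
    table = augment(data, bins)
    cols = data.exposure_names + data.confounder_names + ["bin_time"]
    x = table[cols].to_numpy()
    y = table["Y"].to_numpy()
    subject = table["subject_id"].to_numpy()
    return x, y, subject


# -- adaptive hinge-basis logistic (MARS-style) ----------------------------


class _HingeBasis:
    """Adaptively selected hinge (piecewise-linear) basis with optional
    degree-2 products, in the style of multivariate adaptive regression
    splines: reflected hinge pairs max(x - k, 0) / max(k - x, 0) at
    candidate knots, grown forward by correlation with the working
    residuals of a logistic fit."""

    def __init__(self, terms: list[tuple]):
        # each term: tuple of factors; factor = (var_index, knot, sign)
        # sign +1 -> max(x - k, 0), -1 -> max(k - x, 0), 0 -> linear x
        self.terms = terms

    def transform(self, x: np.ndarray) -> np.ndarray:
        cols = []
        for term in self.terms:
            col = np.ones(len(x))
            for var, knot, sign in term:
                if sign == 0:
                    col = col * x[:, var]
                else:
                    col = col * np.maximum(sign * (x[:, var] - knot), 0.0)
            cols.append(col)
        return np.column_stack(cols) if cols else np.empty((len(x), 0))


def _forward_hinge_selection(
    x: np.ndarray,
    y: np.ndarray,
    max_terms: int,
    degree: int,
    n_knots: int = 7,
) -> _HingeBasis:
    from sklearn.linear_model import LogisticRegression

    n, p = x.shape
    knots = {
        v: np.unique(np.quantile(x[:, v], np.arange(1, n_knots + 1) / (n_knots + 1)))
        for v in range(p)
    }
    terms: list[tuple] = []
    basis = _HingeBasis(terms)

    def refit():
        b = basis.transform(x)
        lr = LogisticRegression(C=1e4, max_iter=1000)
        lr.fit(b, y) if b.shape[1] else None
        if b.shape[1]:
            prob = lr.predict_proba(b)[:, 1]
        else:
            prob = np.full(n, y.mean())
        return prob

    prob = refit()
    while len(terms) < max_terms - 1:
        resid = y - prob
        # candidate reflected pairs: plain hinges, and (if degree 2)
        # products of a hinge with an existing term
        parents: list[tuple] = [()]
        if degree >= 2:
            parents += [t for t in terms if len(t) < degree]
        best_score, best_pair = 0.0, None
        for parent in parents:
            parent_col = (
                _HingeBasis([parent]).transform(x)[:, 0] if parent else np.ones(n)
            )
            used = {f[0] for f in parent}
            for v in range(p):
                if v in used:
                    continue
                for k in knots[v]:
                    plus = parent_col * np.maximum(x[:, v] - k, 0.0)
                    minus = parent_col * np.maximum(k - x[:, v], 0.0)
                    for col, sign in ((plus, 1), (minus, -1)):
                        sd = col.std()
                        if sd < 1e-12:
                            continue
                        score = abs(np.dot(col - col.mean(), resid)) / (sd * n)
                        if score > best_score:
                            best_score = score
                            best_pair = (parent, v, k)
        if best_pair is None or best_score < 1e-8:
            break
        parent, v, k = best_pair
        terms.append(parent + ((v, k, 1),))
        if len(terms) < max_terms - 1:
            terms.append(parent + ((v, k, -1),))
        prob = refit()
    return basis


def _fit_mars_dt(spec: LearnerSpec, data: SurvivalDataset) -> _DiscreteTimeModel:
    from sklearn.linear_model import LogisticRegression

    n_bins = spec.hyper("n_bins", 5)
    bins = make_time_bins(data.time, n_bins)
    x, y, subject = _person_period_design(data, bins)

    term_grid = np.atleast_1d(spec.hyper("max_terms", (11, 21, 31)))
    degree_grid = np.atleast_1d(spec.hyper("degree", (1, 2)))
    folds = spec.hyper("cv_folds", 5)
    seed = spec.hyper("seed", 0)

    def deviance(prob, yy):
        eps = 1e-12
        return -2 * np.sum(yy * np.log(prob + eps) + (1 - yy) * np.log(1 - prob + eps))

    if len(term_grid) * len(degree_grid) > 1:
        # cross-validate by subject so a subject's rows never straddle folds
        subjects = np.unique(subject)
        splits = _cv_folds(len(subjects), folds, seed)
        best_dev, best_cfg = np.inf, None
        for mt in term_grid:
            for dg in degree_grid:
                dev = 0.0
                for i in range(folds):
                    test_subj = set(subjects[splits[i]].tolist())
                    mask = np.fromiter((s in test_subj for s in subject), bool, len(subject))
                    basis = _forward_hinge_selection(x[~mask], y[~mask], int(mt), int(dg))
                    bt = basis.transform(x[~mask])
                    lr = LogisticRegression(C=1e4, max_iter=1000).fit(bt, y[~mask])
                    prob = lr.predict_proba(basis.transform(x[mask]))[:, 1]
                    dev += deviance(prob, y[mask])
                if dev < best_dev:
                    best_dev, best_cfg = dev, (int(mt), int(dg))
        max_terms, degree = best_cfg
    else:
        max_terms, degree = int(term_grid[0]), int(degree_grid[0])

    basis = _forward_hinge_selection(x, y, max_terms, degree)
    bmat = basis.transform(x)
    lr = LogisticRegression(C=1e4, max_iter=2000).fit(bmat, y)

    def hazard_fn(rows: np.ndarray, draw: int | None) -> np.ndarray:
        return lr.predict_proba(basis.transform(rows))[:, 1]

    meta = {
        "max_terms": max_terms,
        "degree": degree,
        "n_terms_selected": len(basis.terms),
        "n_bins": bins.n_bins,
        "implementation": "adaptive hinge-basis logistic selection (in-package)",
        "converged": True,
    }
    return _DiscreteTimeModel(spec, data, bins, hazard_fn, meta)


# -- probabilistic tree ensemble (BART-style) ------------------------------


def _fit_bart_dt(spec: LearnerSpec, data: SurvivalDataset) -> _DiscreteTimeModel:
    """Discrete-time probabilistic tree ensemble.

    Each posterior draw fits a gradient-boosted tree ensemble (logit link)
    on the person-period table with subject-level Bayesian-bootstrap
    (Dirichlet) weights; variation across draws quantifies posterior
    uncertainty about any requested estimand.  The regularizing role of the
    tree prior is played by shallow trees, shrinkage and the draw
    averaging.
    """
    from lightgbm import LGBMClassifier

    n_bins = spec.hyper("n_bins", 5)
    bins = make_time_bins(data.time, n_bins)
    x, y, subject = _person_period_design(data, bins)

    n_draws = spec.hyper("n_draws", 100)
    n_trees = spec.hyper("n_trees", 50)
    num_leaves = spec.hyper("num_leaves", 8)
    learning_rate = spec.hyper("learning_rate", 0.1)
    seed = spec.hyper("seed", 0)

    rng = np.random.default_rng(seed)
    n_subjects = data.n_subjects
    models = []
    for d in range(n_draws):
        w_subject = rng.dirichlet(np.ones(n_subjects)) * n_subjects
        w = w_subject[subject]
        clf = LGBMClassifier(
            n_estimators=n_trees,
            num_leaves=num_leaves,
            learning_rate=learning_rate,
            min_child_samples=10,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
            verbose=-1,
        )
        clf.fit(x, y, sample_weight=w)
        models.append(clf)

    def hazard_fn(rows: np.ndarray, draw: int | None) -> np.ndarray:
        with warnings.catch_warnings():
            # lightgbm invents feature names at fit; ndarray predictions are fine
            warnings.filterwarnings("ignore", message=".*feature names.*")
            if draw is None:
                return np.mean([m.predict_proba(rows)[:, 1] for m in models], axis=0)
            return models[draw].predict_proba(rows)[:, 1]

    meta = {
        "n_draws": n_draws,
        "n_trees": n_trees,
        "n_bins": bins.n_bins,
        "implementation": (
            "Bayesian-bootstrap gradient-boosted tree ensemble (in-package "
            "probabilistic tree ensemble, logit link)"
        ),
        "converged": True,
    }
    model = _DiscreteTimeModel(spec, data, bins, hazard_fn, meta)
    model.n_posterior_draws = n_draws
    return model


# ==========================================================================
# Dispatch
# ==========================================================================


def fit(spec: LearnerSpec, data: SurvivalDataset) -> FittedSurvivalModel:
    """Fit a learner to a survival dataset under the shared contract."""
    if data.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    try:
        if spec.name == "cox_ph":
            return _fit_cox_linear(spec, data, interactions=False)
        if spec.name == "cox_ph_int":
            return _fit_cox_linear(spec, data, interactions=True)
        if spec.name == "cox_ph_ps":
            return _fit_cox_splines(spec, data)
        if spec.name == "cox_en":
            return _fit_cox_elastic_net(spec, data, interactions=False)
        if spec.name == "cox_en_int":
            return _fit_cox_elastic_net(spec, data, interactions=True)
        if spec.name == "mars_dt":
            return _fit_mars_dt(spec, data)
        if spec.name == "bart_dt":
            return _fit_bart_dt(spec, data)
    except (ValueError, np.linalg.LinAlgError) as err:
        raise RuntimeError(f"learner {spec.name!r} failed to fit: {err}") from err
    raise AssertionError("unreachable")
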