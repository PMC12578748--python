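"""Discrete-time survival machinery: quantile time bins, person-period
augmentation, and recovery of survival/hazard quantities from bin-level
event probabilities.

The discrete-time approach recodes a censored time-to-event outcome as a
sequence of binary outcomes: time is cut into ``R`` bins at the 1/R, ...,
1 empirical quantiles of observed times, and each subject contributes one
row per bin up to (and including) the bin containing their observed time,
with the binary outcome ``Y`` equal to 1 only in the last row of a subject
who experienced the event.  Any binary-outcome learner fit on this
person-period table estimates the discrete-time hazard ``h_r(x) = P(event
in bin r | at risk at bin r, x)``, from which survival is recovered as the
product of per-bin survival probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TimeBins",
    "make_time_bins",
    "augment",
    "survival_from_bin_hazards",
    "bin_hazard_contrast",
    "life_table_survival",
]


@dataclass(frozen=True)
class TimeBins:
    """Discretization of follow-up time into left-closed right-open bins.

    ``boundaries`` has length R+1, starts at 0, and is strictly increasing;
    the last bin is closed on the right so the largest observed time falls
    in bin R.  ``representative`` holds the bin midpoints used as the time
    covariate in discrete-time models.
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) < 2:
            raise ValueError("need at least 1 bin (2 boundaries)")
        if b[0] != 0.0 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must start at 0 and be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    @property
    def representative(self) -> np.ndarray:
        """Midpoint of each bin, used as the time covariate."""
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    def bin_index(self, times: np.ndarray | float) -> np.ndarray:
        """1-based bin index of each time; times beyond the last boundary
        are assigned to the last bin (logged)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        idx = np.searchsorted(self.boundaries, t, side="right")
        # t exactly on the final boundary, or beyond it, belongs to bin R
        over = idx > self.n_bins
        if np.any(t > self.boundaries[-1]):
            logger.info(
                "%d time(s) beyond the last bin boundary assigned to the last bin",
                int(np.sum(t > self.boundaries[-1])),
            )
        idx[over] = self.n_bins
        idx[idx == 0] = 1  # t == 0 edge: first bin
        return idx


def make_time_bins(times: np.ndarray, n_bins: int) -> TimeBins:
    """Cut observed event/censoring times into ``n_bins`` quantile bins.

    Interior boundaries sit at the 1/R, 2/R, ..., 1 empirical quantiles of
    ``times`` (linear-interpolation quantile convention), with 0 as the
    left edge.  Duplicate quantiles are merged, reducing R with a warning.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if n_bins < 2:
        raise ValueError(f"need at least 2 bins, requested {n_bins}")
    qs = np.arange(1, n_bins + 1) / n_bins
    edges = np.quantile(times, qs)
    boundaries = np.concatenate([[0.0], edges])
    unique = np.unique(boundaries)
    if len(unique) < len(boundaries):
        logger.warning(
            "duplicate quantile boundaries merged: %d bins requested, %d kept",
            n_bins,
            len(unique) - 1,
        )
    if len(unique) < 3:
        # all times identical: a single degenerate bin
        if unique[-1] <= 0:
            raise ValueError("all times are zero; cannot build bins")
        logger.warning("fewer than 2 distinct bins after merging; using a single bin")
        return TimeBins(boundaries=np.array([0.0, unique[-1]]))
    return TimeBins(boundaries=unique)


def augment(data: SurvivalDataset, bins: TimeBins) -> pd.DataFrame:
    """Build the person-period table.

    A subject whose observed time falls in bin ``r_i`` contributes rows for
    bins 1..r_i, covariates repeated, with ``Y = 1`` only in the last row
    and only if the event occurred.  Columns: ``subject_id``, ``bin``
    (1-based), ``bin_time`` (midpoint), ``Y``, then exposures and
    confounders.
    """
    if np.any(data.time < 0):
        raise ValueError("negative follow-up time")
    r_i = bins.bin_index(data.time)
    n = data.n_subjects
    reps = r_i.astype(int)
    subject = np.repeat(np.arange(n), reps)
    bin_idx = np.concatenate([np.arange(1, r + 1) for r in reps])
    is_last = np.concatenate([np.arange(1, r + 1) == r for r in reps])
    y = (is_last & np.repeat(data.event == 1, reps)).astype(int)
    table = pd.DataFrame(
        {
            "subject_id": subject,
            "bin": bin_idx,
            "bin_time": bins.representative[bin_idx - 1],
            "Y": y,
        }
    )
    covars = pd.concat(
        [data.exposures.reset_index(drop=True), data.confounders.reset_index(drop=True)],
        axis=1,
    )
    covars = covars.iloc[subject].reset_index(drop=True)
    return pd.concat([table, covars], axis=1)


def survival_from_bin_hazards(hazards: np.ndarray, r_stop: int | None = None) -> float:
    """Survival through bin ``r_stop``: the product of (1 - h_r).

    ``hazards`` holds per-bin conditional event probabilities h_r; the
    survival probability at the end of bin r_stop is
    ``prod_{r<=r_stop} (1 - h_r)``.
    """
    h = np.asarray(hazards, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("bin hazards must lie in [0, 1]")
    if r_stop is None:
        r_stop = len(h)
    if not 0 <= r_stop <= len(h):
        raise ValueError(f"r_stop must be in [0, {len(h)}]")
    return float(np.prod(1.0 - h[:r_stop]))


def bin_hazard_contrast(
    hazards_a: np.ndarray, hazards_b: np.ndarray, bin_index: int
) -> float:
    """Discrete-hazard ratio h_a[r] / h_b[r] in the bin containing t_spec.

    ``bin_index`` is 1-based.  A zero denominator is an error; the
    survival-probability-difference estimand is the robust alternative for
    profiles with vanishing discrete hazard.
    """
    h_a = np.asarray(hazards_a, dtype=float)
    h_b = np.asarray(hazards_b, dtype=float)
    for h in (h_a, h_b):
        if np.any((h < 0) | (h > 1)):
            raise ValueError("bin hazards must lie in [0, 1]")
    if not 1 <= bin_index <= min(len(h_a), len(h_b)):
        raise ValueError(f"bin_index {bin_index} out of range")
    denom = h_b[bin_index - 1]
    if denom == 0:
        raise ZeroDivisionError(
            "reference profile has zero discrete hazard in this bin; "
            "consider the survival probability difference estimand instead"
        )
    return float(h_a[bin_index - 1] / denom)


def life_table_survival(data: SurvivalDataset, bins: TimeBins) -> np.ndarray:
    """Covariate-free life-table (actuarial) survival at each bin boundary.

    Per bin, the hazard estimate is (events in bin) / (subjects at risk at
    the start of the bin); survival is the cumulative product of (1 - h).
    This is the oracle that an intercept-per-bin discrete-time fit must
    reproduce exactly.
    """
    r_i = bins.bin_index(data.time)
    R = bins.n_bins
    surv = np.empty(R)
    s = 1.0
    for r in range(1, R + 1):
        at_risk = int(np.sum(r_i >= r))
        events = int(np.sum((r_i == r) & (data.event == 1)))
        h = events / at_risk if at_risk > 0 else 0.0
        s *= 1.0 - h
        surv[r - 1] = s
    return surv
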