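"""Parameter-recovery validation battery.

Four complementary diagnostics certify that the estimation machinery
recovers the ground truth of simulated meals:

* :func:`coverage` — proportion of cases whose true parameter value lies
  inside the recovered profile-likelihood confidence interval (expected to
  be at least the nominal level).
* :func:`distinguishability` — for each estimate, the number of *other*
  cases' confidence intervals that contain it; an estimate is distinct
  when that count is below 15% of the sample, and a case's curve is
  distinct when any of its parameters is.  This proxies the power to
  detect individual differences.
* :func:`gof_index` — |recovered - true| scaled by the generating
  distribution's parameter median; always positive, 0 is perfect.
* :func:`curve_error` — RMSE and pseudo-R^2 of the recovered curve in both
  directions: predicted intake at the true bite times, and predicted
  timing at the true cumulative intake.  Non-feasible predicted bites are
  counted (a case with more than 10% is non-convergent and excluded from
  the error summaries) and excluded from the error sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import FitResult
from .models import (
    BiteSequence,
    FeasibilityFlags,
    classify_feasibility,
    model_intake,
    model_time,
)

__all__ = [
    "coverage",
    "distinguishability",
    "gof_index",
    "curve_error",
    "CurveError",
    "rmse",
    "pseudo_r2",
    "DISTINCT_THRESHOLD_FRAC",
]

#: an estimate is distinct when it falls inside fewer than this fraction of
#: the other cases' confidence intervals (15 of 100 at the default study size)
DISTINCT_THRESHOLD_FRAC = 0.15


def coverage(true_values: dict[str, np.ndarray], fits: list[FitResult]) -> dict[str, float]:
    """Per-parameter fraction of cases with ``lower <= true <= upper``.

    ``true_values`` maps parameter name to the aligned vector of truths.
    Open CI sides (profile never reached the cutoff) are treated as
    infinite and therefore always cover.
    """
    out = {}
    for name, truth in true_values.items():
        truth = np.asarray(truth, dtype=float)
        if len(truth) != len(fits):
            raise ValueError("true values and fits must be aligned and equal length")
        hits = 0
        for tv, fit in zip(truth, fits):
            lo, hi = fit.ci[name]
            if lo <= tv <= hi:
                hits += 1
        out[name] = hits / len(fits)
    return out


def distinguishability(
    fits: list[FitResult],
    threshold_frac: float = DISTINCT_THRESHOLD_FRAC,
) -> pd.DataFrame:
    """Overlap counts and distinct flags for all fits of one condition.

    For each estimate ``i`` and parameter ``p``, counts the cases
    ``j != i`` whose CI for ``p`` contains estimate ``i``.  The estimate is
    distinct when the count is below ``threshold_frac * n``; the case's
    curve is distinct when any of its parameters is (``any_distinct``,
    repeated on every row of the case).
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits")
    n = len(fits)
    cutoff = threshold_frac * n
    names = fits[0].free_names
    rows = []
    dist_flags = np.zeros((n, len(names)), dtype=bool)
    for pi, name in enumerate(names):
        est = np.array([f.estimate(name) for f in fits])
        lo = np.array([f.ci[name][0] for f in fits])
        hi = np.array([f.ci[name][1] for f in fits])
        inside = (est[:, None] >= lo[None, :]) & (est[:, None] <= hi[None, :])
        np.fill_diagonal(inside, False)
        counts = inside.sum(axis=1)
        dist_flags[:, pi] = counts < cutoff
        for i in range(n):
            rows.append(
                {
                    "case": i,
                    "parameter": name,
                    "overlap_count": int(counts[i]),
                    "distinct": bool(dist_flags[i, pi]),
                }
            )
    df = pd.DataFrame(rows)
    any_distinct = dist_flags.any(axis=1)
    df["any_distinct"] = any_distinct[df["case"].to_numpy()]
    return df


def gof_index(true_params, recovered_params, dist_medians: dict[str, float]) -> dict[str, float]:
    """Goodness-of-Fit Index: |recovered - true| / |median| per parameter.

    Medians come from the generating parameter distribution; scaling by
    them makes parameters of different magnitude comparable, and the
    absolute value makes the index sign-free (parameters differ in their
    expected sign).  Smaller is better; 0 is perfect recovery.
    """
    out = {}
    for name, rec in recovered_params.as_dict().items():
        if name not in dist_medians:
            continue  # fixed parameters (e.g. emax) are not scored
        med = dist_medians[name]
        if med == 0:
            raise ValueError(f"degenerate generating distribution: median of {name!r} is 0")
        out[name] = abs(rec - getattr(true_params, name)) / abs(med)
    return out


# ---------------------------------------------------------------------------
# curve error
# ---------------------------------------------------------------------------


def rmse(true: np.ndarray, pred: np.ndarray) -> float:
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    return float(np.sqrt(np.mean((pred - true) ** 2)))


def pseudo_r2(true: np.ndarray, pred: np.ndarray) -> float:
    """1 - SS_res/SS_tot: proportion of variance in the true values
    explained by the predictions (can be negative; 1 is perfect)."""
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    ss_res = float(np.sum((true - pred) ** 2))
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


@dataclass
class CurveError:
    """Two-direction prediction error of a recovered curve for one case."""

    timing_rmse: float
    timing_r2: float
    intake_rmse: float
    intake_r2: float
    timing_flags: FeasibilityFlags
    intake_flags: FeasibilityFlags
    n_nonfeasible: int = field(init=False)
    convergent: bool = field(init=False)

    def __post_init__(self) -> None:
        # a bite is non-feasible when flagged in either direction
        bad = [
            a != "none" or b != "none"
            for a, b in zip(self.timing_flags.reasons, self.intake_flags.reasons)
        ]
        self.n_nonfeasible = sum(bad)
        n = self.timing_flags.n_bites
        self.convergent = self.n_nonfeasible / n <= 0.10


def curve_error(true_params, recovered_params, true_bites: BiteSequence) -> CurveError:
    """Compare the recovered curve with the true data in both directions.

    Predicted cumulative intake is evaluated at the true bite times
    (model intake at ``t_i`` plus half the bite increment, undoing the
    midpoint convention); predicted bite timing is the model's inverse at
    the true midpoint-corrected intake.  RMSE and pseudo-R^2 are computed
    over the feasible predicted bites of each direction; the case is
    non-convergent when more than 10% of bites are non-feasible in either
    direction combined.
    """
    t_true = true_bites.times
    e_true = true_bites.intake
    half = true_bites.increments / 2.0

    pred_t = np.asarray(model_time(recovered_params, true_bites.midpoint_intake()))
    pred_e = np.asarray(model_intake(recovered_params, t_true)) + half

    timing_flags = classify_feasibility(predicted_times=pred_t)
    intake_flags = classify_feasibility(predicted_intake=pred_e)

    mt = timing_flags.feasible_mask
    me = intake_flags.feasible_mask
    if mt.any():
        t_rmse, t_r2 = rmse(t_true[mt], pred_t[mt]), pseudo_r2(t_true[mt], pred_t[mt])
    else:
        t_rmse, t_r2 = np.nan, np.nan
    if me.any():
        e_rmse, e_r2 = rmse(e_true[me], pred_e[me]), pseudo_r2(e_true[me], pred_e[me])
    else:
        e_rmse, e_r2 = np.nan, np.nan

    return CurveError(
        timing_rmse=t_rmse,
        timing_r2=t_r2,
        intake_rmse=e_rmse,
        intake_r2=e_r2,
        timing_flags=timing_flags,
        intake_flags=intake_flags,
    )
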