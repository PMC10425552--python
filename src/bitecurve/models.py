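"""Cumulative intake curve models.

Two closed-form models of within-meal cumulative intake ``E(t)`` (grams
consumed by minute ``t`` of the eating episode):

* **Quadratic** (Kissileff): ``E(t) = a t^2 + b t + c``.  The linear
  coefficient ``b`` is the initial eating rate (g/min), the quadratic
  coefficient ``a`` the change in eating rate across the meal (g/min^2;
  negative for a decelerating, satiating meal) and ``c`` an uninterpreted
  intercept.  The inverted-U shape means the model can predict
  *non-feasible* intake (declining cumulative intake late in the meal,
  negative intake early on).

* **LODE** (Thomas): the solution of the logistic ordinary differential
  equation ``dE/dt = (theta + r E)(1 - E/Emax)``::

      E(t) = (e^{kt} - 1) / (e^{kt}/Emax + r/theta),   k = (Emax r + theta)/Emax

  with ``theta`` the initial eating rate (g/min), ``r`` the doubling rate
  (1/min; ``1/r`` approximates the time to double intake) and ``Emax`` the
  total intake of the episode, which the curve approaches asymptotically.
  By construction the curve is strictly increasing and bounded by
  ``Emax``, so it can only predict feasible intake patterns.

Both models expose a forward map (time -> intake) and an inverse map
(intake -> time).  Inverse evaluations that fall outside the model's
feasible range return ``nan`` markers rather than raising: non-feasible
predictions are data for the downstream recovery diagnostics, which count
them (a fit is non-convergent when more than 10% of its predicted bites
are non-feasible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "QuadraticParams",
    "LODEParams",
    "BiteSequence",
    "FeasibilityFlags",
    "InvalidParameterError",
    "DegenerateModelError",
    "quadratic_intake",
    "quadratic_time",
    "lode_k",
    "lode_intake",
    "lode_time",
    "model_intake",
    "model_time",
    "classify_feasibility",
    "read_bite_csv",
    "write_bite_csv",
    "NONCONVERGENT_FRACTION",
]

#: a case is non-convergent when more than this fraction of bites is non-feasible
NONCONVERGENT_FRACTION = 0.10


class InvalidParameterError(ValueError):
    """Model parameters violate their domain (non-finite or non-positive)."""


class DegenerateModelError(ValueError):
    """The model curve is constant and cannot be inverted (a == b == 0)."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadraticParams:
    """Quadratic model parameters ``E(t) = a t^2 + b t + c``.

    ``a <= 0`` marks a decelerating (satiating) curve; the sign is recorded,
    not enforced.
    """

    a: float  # quadratic coefficient, g/min^2
    b: float  # linear coefficient (initial eating rate), g/min
    c: float  # intercept, g

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"quadratic parameter {name!r} is not finite: {v}")

    @property
    def decelerating(self) -> bool:
        return self.a <= 0

    @property
    def vertex_time(self) -> float:
        """Time of the parabola's apex, ``-b/(2a)``; ``inf`` when a == 0."""
        if self.a == 0:
            return math.inf
        return -self.b / (2.0 * self.a)

    @property
    def max_intake(self) -> float:
        """Largest intake reachable on the increasing branch (apex value)."""
        if self.a >= 0:
            return math.inf
        return self.c + self.b**2 / (-4.0 * self.a)

    def as_dict(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b, "c": self.c}


@dataclass(frozen=True)
class LODEParams:
    """LODE model parameters (theta, r, emax), all strictly positive."""

    theta: float  # initial eating rate, g/min
    r: float      # doubling rate, 1/min
    emax: float   # total meal intake (asymptote), g

    def __post_init__(self) -> None:
        for name in ("theta", "r", "emax"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidParameterError(
                    f"LODE parameter {name!r} must be finite and > 0, got {v}"
                )

    @property
    def k(self) -> float:
        """Exponential rate constant ``(emax r + theta)/emax`` (1/min)."""
        return lode_k(self)

    def as_dict(self) -> dict[str, float]:
        return {"theta": self.theta, "r": self.r, "emax": self.emax}


#: parameter names per model tag (free + fixed)
PARAM_NAMES = {"quadratic": ("a", "b", "c"), "lode": ("theta", "r")}


# ---------------------------------------------------------------------------
# bite sequences
# ---------------------------------------------------------------------------


@dataclass
class BiteSequence:
    """One meal's ordered bite record: timestamps (min) and cumulative intake (g).

    Invariants (checked on construction): equal lengths, strictly increasing
    positive times bounded by ``meal_duration``, non-decreasing non-negative
    intake whose last value is the meal's total intake.
    """

    case_id: str
    times: np.ndarray
    intake: np.ndarray
    meal_duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intake = np.asarray(self.intake, dtype=float)
        self.validate()

    def validate(self) -> None:
        t, e = self.times, self.intake
        if t.ndim != 1 or e.ndim != 1 or len(t) != len(e):
            raise ValueError(f"{self.case_id}: times and intake must be 1-d and equal length")
        if len(t) == 0:
            raise ValueError(f"{self.case_id}: empty bite sequence")
        bad = _first_invalid_bite(t, e, self.meal_duration)
        if bad is not None:
            i, why = bad
            raise ValueError(f"{self.case_id}: bite {i + 1}: {why}")

    @property
    def bite_count(self) -> int:
        return len(self.times)

    @property
    def total_intake(self) -> float:
        return float(self.intake[-1])

    @property
    def increments(self) -> np.ndarray:
        """Per-bite intake jumps Delta_i = e_i - e_{i-1} (e_0 = 0)."""
        return np.diff(self.intake, prepend=0.0)

    @property
    def avg_bite_size(self) -> float:
        return self.total_intake / self.bite_count

    def midpoint_intake(self) -> np.ndarray:
        """Midpoint-corrected intake ``e_i - Delta_i/2``.

        Cumulative intake is a step function that jumps by ``Delta_i`` at
        bite ``i``; the smooth model curve is taken to cross the middle of
        each jump.  This is the value at which the model's inverse is
        evaluated to obtain bite times, and it is always strictly below the
        meal total, keeping the LODE inverse finite at the final bite.
        """
        return self.intake - self.increments / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": self.case_id,
                "bite": np.arange(1, self.bite_count + 1),
                "time_min": self.times,
                "intake_g": self.intake,
            }
        )


def _first_invalid_bite(t: np.ndarray, e: np.ndarray, duration: float):
    """Return (index, reason) for the first bite violating the invariants."""
    prev_t = 0.0
    prev_e = 0.0
    for i in range(len(t)):
        if not np.isfinite(t[i]) or t[i] <= 0:
            return i, f"bite time must be positive and finite, got {t[i]}"
        if t[i] <= prev_t:
            return i, f"bite times must be strictly increasing ({t[i]} <= {prev_t})"
        if t[i] > duration * (1 + 1e-12):
            return i, f"bite time {t[i]} exceeds meal duration {duration}"
        if not np.isfinite(e[i]) or e[i] < 0:
            return i, f"cumulative intake must be non-negative and finite, got {e[i]}"
        if e[i] < prev_e:
            return i, f"cumulative intake must be non-decreasing ({e[i]} < {prev_e})"
        prev_t, prev_e = t[i], e[i]
    return None


# ---------------------------------------------------------------------------
# forward / inverse evaluation
# ---------------------------------------------------------------------------


def _validate_quadratic(params: QuadraticParams) -> None:
    if not isinstance(params, QuadraticParams):
        raise TypeError("expected QuadraticParams")


def quadratic_intake(params: QuadraticParams, t):
    """Quadratic cumulative intake ``a t^2 + b t + c`` at time(s) ``t`` (min).

    No clamping is applied: non-feasible (e.g. negative) values are returned
    as-is and left to :func:`classify_feasibility`.
    """
    _validate_quadratic(params)
    t = np.asarray(t, dtype=float)
    out = params.a * t**2 + params.b * t + params.c
    return out if out.ndim else float(out)

def quadratic_time(params: QuadraticParams, e):
    """Invert the quadratic model: time (min) at which intake reaches ``e`` (g).

    Solves ``a t^2 + b t + c = e`` on the *increasing* branch (pre-vertex
    for a < 0): intake at a bite must be locally increasing.  Evaluated via
    the numerically stable form ``t = 2(e-c) / (b + sqrt(b^2 - 4a(c-e)))``,
    which reduces to ``(e-c)/b`` as ``a -> 0``.  Returns ``nan`` where no
    such root exists (discriminant < 0, i.e. ``e`` above the apex) or where
    the root is negative (``e`` below the intercept): those are non-feasible
    predictions, not errors.
    """
    _validate_quadratic(params)
    if params.a == 0 and params.b == 0:
        raise DegenerateModelError("constant curve (a == b == 0) cannot be inverted")
    e = np.asarray(e, dtype=float)
    disc = params.b**2 - 4.0 * params.a * (params.c - e)
    with np.errstate(invalid="ignore", divide="ignore"):
        root = np.sqrt(np.where(disc >= 0, disc, np.nan))
        denom = params.b + root
        t = np.where(np.abs(denom) > 0, 2.0 * (e - params.c) / denom, np.nan)
    t = np.where(t >= 0, t, np.nan)
    return t if t.ndim else float(t)


def lode_k(params: LODEParams) -> float:
    """Rate constant ``k = (emax r + theta)/emax`` of the LODE solution."""
    if not isinstance(params, LODEParams):
        raise TypeError("expected LODEParams")
    return params.r + params.theta / params.emax


def lode_intake(params: LODEParams, t):
    """LODE cumulative intake at time(s) ``t`` (min).

    Evaluated in the overflow-safe factored form
    ``(1 - e^{-kt}) / (1/emax + (r/theta) e^{-kt})`` so that large ``k t``
    returns the asymptote ``emax`` instead of overflowing.
    """
    k = lode_k(params)
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        decay = np.exp(-k * t)
    out = (1.0 - decay) / (1.0 / params.emax + (params.r / params.theta) * decay)
    return out if out.ndim else float(out)


def lode_time(params: LODEParams, e):
    """Invert the LODE model: time (min) at which intake reaches ``e`` (g).

    ``t = (1/k) ln[(1 + e r/theta) / (1 - e/emax)]`` — the exact inverse of
    :func:`lode_intake` on ``0 <= e < emax``.  Values at or above the
    asymptote (never attained in finite time) and negative values return
    ``nan`` markers.
    """
    k = lode_k(params)
    e = np.asarray(e, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (1.0 + e * params.r / params.theta) / (1.0 - e / params.emax)
        t = np.where((e >= 0) & (e < params.emax), np.log(ratio) / k, np.nan)
    return t if t.ndim else float(t)


def model_intake(params, t):
    """Forward evaluation dispatched on the parameter type."""
    if isinstance(params, LODEParams):
        return lode_intake(params, t)
    return quadratic_intake(params, t)


def model_time(params, e):
    """Inverse evaluation dispatched on the parameter type."""
    if isinstance(params, LODEParams):
        return lode_time(params, e)
    return quadratic_time(params, e)


def model_tag(params) -> str:
    return "lode" if isinstance(params, LODEParams) else "quadratic"


# ---------------------------------------------------------------------------
# feasibility classification
# ---------------------------------------------------------------------------


@dataclass
class FeasibilityFlags:
    """Per-bite feasibility verdicts for a vector of predicted bites."""

    n_bites: int
    n_nonfeasible: int
    reasons: list[str] = field(repr=False)
    convergent: bool = field(init=False)

    def __post_init__(self) -> None:
        self.convergent = self.n_nonfeasible / self.n_bites <= NONCONVERGENT_FRACTION

    @property
    def feasible_mask(self) -> np.ndarray:
        return np.array([r == "none" for r in self.reasons])


def classify_feasibility(
    predicted_times=None,
    predicted_intake=None,
) -> FeasibilityFlags:
    """Flag each predicted bite as feasible or not, and apply the 10% rule.

    A predicted bite is non-feasible when its predicted time is negative or
    could not be computed (inversion failure marker ``nan``), when its
    predicted intake is negative, or when predicted intake decreases
    relative to the previous bite.  The case is *convergent* when at most
    10% of bites are non-feasible.

    Either or both of ``predicted_times`` / ``predicted_intake`` may be
    given; they must be equal length when both are.
    """
    if predicted_times is None and predicted_intake is None:
        raise ValueError("at least one of predicted_times / predicted_intake is required")
    t = None if predicted_times is None else np.asarray(predicted_times, dtype=float)
    e = None if predicted_intake is None else np.asarray(predicted_intake, dtype=float)
    if t is not None and e is not None and len(t) != len(e):
        raise ValueError("predicted times and intake must be equal length")
    n = len(t) if t is not None else len(e)
    if n == 0:
        raise ValueError("empty prediction sequence")

    reasons = ["none"] * n
    if t is not None:
        prev = 0.0
        for i, ti in enumerate(t):
            if not np.isfinite(ti):
                reasons[i] = "non-invertible"
            elif ti < 0:
                reasons[i] = "negative-time"
            elif ti < prev:
                reasons[i] = "decreasing-time"
            else:
                prev = ti
    if e is not None:
        prev = 0.0
        for i, ei in enumerate(e):
            if reasons[i] != "none":
                continue
            if not np.isfinite(ei):
                reasons[i] = "non-invertible"
            elif ei < 0:
                reasons[i] = "negative-intake"
            elif ei < prev:
                reasons[i] = "decreasing-intake"
            else:
                prev = ei
    n_bad = sum(r != "none" for r in reasons)
    return FeasibilityFlags(n_bites=n, n_nonfeasible=n_bad, reasons=reasons)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["case_id", "bite", "time_min", "intake_g"]


def write_bite_csv(path, sequences: Iterable[BiteSequence]) -> None:
    """Write bite sequences as ``case_id,bite,time_min,intake_g`` CSV."""
    frames = [s.to_frame() for s in sequences]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_bite_csv(path) -> list[BiteSequence]:
    """Read the ``case_id,bite,time_min,intake_g`` dialect.

    Rows are sorted by 1-based bite ordinal within each case, then the
    BiteSequence invariants are validated; the error message of the first
    violated row carries the case and bite it occurred at.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for case_id, grp in df.groupby("case_id", sort=False):
        grp = grp.sort_values("bite")
        times = grp["time_min"].to_numpy(dtype=float)
        intake = grp["intake_g"].to_numpy(dtype=float)
        out.append(
            BiteSequence(
                case_id=str(case_id),
                times=times,
                intake=intake,
                meal_duration=float(times[-1]) if len(times) else 0.0,
            )
        )
    return out
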