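"""Generating model: plausible child meal microstructure and feasible
model-parameter distributions.

The pipeline mirrors how one would bootstrap simulation inputs from the
summary statistics of an observational study of children's meals:

1. :func:`sample_microstructure` draws meal-level behavior profiles
   (bite count, total intake, meal duration) from a truncated multivariate
   normal built from configurable reference moments.
2. :func:`generate_bite_timings` turns a profile into a bite sequence:
   bite times are sorted draws from a zero-truncated (half-) logistic
   distribution, max-scaled to the meal duration, and jittered — the
   decreasing half-logistic density front-loads bites, producing the
   decelerating cumulative intake curves typical of satiating meals.
   Intake rises by one average bite per bite.
3. :func:`build_parameter_distribution` fits the chosen model to each
   generated meal, keeps only fits whose implied curve is feasible
   (non-decreasing over the meal, reaching the meal total), and summarizes
   the retained fits jointly with bite count and total intake as a
   multivariate normal plus per-parameter medians.
4. :func:`sample_true_parameters` draws "true" parameter sets from that
   multivariate normal, rejection-sampling away draws that cannot produce
   a complete feasible meal.

The default reference moments are documented approximations of child meal
microstructure (bite count 40 +/- 15, total intake 300 +/- 100 g, meal
duration 15 +/- 5 min with mild positive correlations) and are fully
overridable through the study config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .fitting import NonConvergenceError, fit_model
from .models import (
    BiteSequence,
    LODEParams,
    QuadraticParams,
    PARAM_NAMES,
    model_time,
)

__all__ = [
    "ReferenceStats",
    "MicrostructureProfile",
    "ParameterDistribution",
    "TrueCase",
    "GenerationError",
    "sample_microstructure",
    "generate_bite_timings",
    "build_parameter_distribution",
    "sample_true_parameters",
    "as_rng",
]

log = logging.getLogger(__name__)

_BEHAVIOR_NAMES = ("n_bites", "total_intake", "meal_duration")


class GenerationError(RuntimeError):
    """The configured reference statistics cannot produce feasible data."""


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# reference statistics and profiles
# ---------------------------------------------------------------------------


@dataclass
class ReferenceStats:
    """Mean/SD/correlation of meal-level behaviors (configurable).

    ``means``/``sds`` are in the order (n_bites, total_intake g,
    meal_duration min); ``corr`` is the 3x3 correlation matrix, which must
    be positive semi-definite.
    """

    means: dict[str, float] = field(
        default_factory=lambda: {"n_bites": 40.0, "total_intake": 300.0, "meal_duration": 15.0}
    )
    sds: dict[str, float] = field(
        default_factory=lambda: {"n_bites": 15.0, "total_intake": 100.0, "meal_duration": 5.0}
    )
    corr: np.ndarray = field(
        default_factory=lambda: np.array(
            [[1.0, 0.5, 0.4], [0.5, 1.0, 0.3], [0.4, 0.3, 1.0]]
        )
    )

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        if any(self.sds[k] < 0 for k in _BEHAVIOR_NAMES):
            raise ValueError("reference SDs must be non-negative")
        eig = np.linalg.eigvalsh(self.corr)
        if eig.min() < -1e-10:
            raise ValueError("reference correlation matrix must be positive semi-definite")

    @property
    def mean_vector(self) -> np.ndarray:
        return np.array([self.means[k] for k in _BEHAVIOR_NAMES])

    @property
    def covariance(self) -> np.ndarray:
        s = np.array([self.sds[k] for k in _BEHAVIOR_NAMES])
        return self.corr * np.outer(s, s)

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceStats":
        kwargs = {}
        if "means" in d:
            kwargs["means"] = {k: float(v) for k, v in d["means"].items()}
        if "sds" in d:
            kwargs["sds"] = {k: float(v) for k, v in d["sds"].items()}
        if "corr" in d:
            kwargs["corr"] = np.asarray(d["corr"], dtype=float)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {"means": dict(self.means), "sds": dict(self.sds), "corr": self.corr.tolist()}


@dataclass
class MicrostructureProfile:
    """One simulated case's meal-level behaviors."""

    case_id: str
    n_bites: int
    total_intake: float  # g
    meal_duration: float  # min

    def __post_init__(self) -> None:
        if self.n_bites < 2:
            raise ValueError("a meal needs at least 2 bites")
        if self.total_intake <= 0 or self.meal_duration <= 0:
            raise ValueError("total intake and meal duration must be positive")

    @property
    def avg_bite_size(self) -> float:
        return self.total_intake / self.n_bites

    @property
    def eating_rate(self) -> float:
        """Average eating rate over the meal (g/min)."""
        return self.total_intake / self.meal_duration


def sample_microstructure(ref: ReferenceStats, n: int, seed) -> list[MicrostructureProfile]:
    """Draw ``n`` meal profiles from the reference distribution.

    Draws come from the multivariate normal implied by ``ref`` and are
    truncated to the feasible region (all behaviors positive, at least two
    bites) by rejection.  Bite counts are rounded to integers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    mean, cov = ref.mean_vector, ref.covariance
    out: list[MicrostructureProfile] = []
    attempts = 0
    while len(out) < n:
        m = max(2 * (n - len(out)), 16)
        draws = rng.multivariate_normal(mean, cov, size=m, method="eigh")
        for row in draws:
            nb = int(round(row[0]))
            if nb >= 2 and row[1] > 0 and row[2] > 0:
                out.append(
                    MicrostructureProfile(
                        case_id=f"gen{len(out):04d}",
                        n_bites=nb,
                        total_intake=float(row[1]),
                        meal_duration=float(row[2]),
                    )
                )
                if len(out) == n:
                    break
        attempts += m
        if attempts > 200 * n + 1000:
            raise GenerationError(
                "reference statistics place almost no mass on feasible meals"
            )
    return out


# ---------------------------------------------------------------------------
# bite timing generation
# ---------------------------------------------------------------------------


def _repair_times(t: np.ndarray, duration: float) -> np.ndarray | None:
    """Sort, pin the last bite to the meal end, and enforce strict increase
    inside (0, duration].  Jitter that pushes a bite before the meal start
    is reflected back into the meal.  Returns None when irreparable."""
    t = np.sort(np.abs(np.asarray(t, dtype=float)))
    t[-1] = duration
    floor = 1e-3 * duration  # no bite meaningfully earlier than ~0.1% of the meal
    eps = 1e-6 * duration
    t = np.clip(t, floor, duration)
    # backward pass: make room below the pinned endpoint
    for i in range(len(t) - 2, -1, -1):
        if t[i] >= t[i + 1]:
            t[i] = t[i + 1] - eps
    if t[0] <= 0:
        return None
    return t


def generate_bite_timings(
    profile: MicrostructureProfile,
    jitter_sd: float | None = None,
    seed=None,
    max_attempts: int = 20,
) -> BiteSequence:
    """Generate one meal's bite sequence from a microstructure profile.

    Bite times: ``n_bites`` draws from a zero-truncated standard logistic
    (location 0, scale 1 — equivalently half-logistic; the scale cancels
    under max-normalization), sorted ascending, scaled by
    ``duration * value / max(value)`` so the last bite lands at the meal
    end, then Gaussian-jittered (default SD 2% of meal duration) and
    repaired to be positive, strictly increasing and <= duration.  Intake
    rises by one average bite per bite.  Irreparable draws are regenerated
    from a fresh substream (logged).
    """
    if jitter_sd is None:
        jitter_sd = 0.02 * profile.meal_duration
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = as_rng(seed)
    n, dur = profile.n_bites, profile.meal_duration
    for attempt in range(max_attempts):
        raw = np.abs(rng.logistic(loc=0.0, scale=1.0, size=n))
        raw.sort()
        t = dur * raw / raw[-1]
        t = t + rng.normal(0.0, jitter_sd, size=n)
        t = _repair_times(t, dur)
        if t is not None:
            break
        log.debug("%s: irreparable bite timings, regenerating (attempt %d)",
                  profile.case_id, attempt + 1)
    else:
        raise GenerationError(f"{profile.case_id}: could not generate valid bite timings")
    intake = profile.avg_bite_size * np.arange(1, n + 1)
    intake[-1] = profile.total_intake  # guard rounding
    return BiteSequence(
        case_id=profile.case_id, times=t, intake=intake, meal_duration=dur
    )


# ---------------------------------------------------------------------------
# parameter distributions
# ---------------------------------------------------------------------------


@dataclass
class ParameterDistribution:
    """Multivariate-normal summary of feasible model parameters.

    The joint vector is ``model parameters + (n_bites, total_intake)``;
    ``medians`` (of the retained fits) scale the Goodness-of-Fit Index.
    """

    model: str
    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    medians: dict[str, float]
    n_retained: int
    provenance: dict = field(default_factory=dict)  # seeds / config notes

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        eig = np.linalg.eigvalsh(self.cov)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("covariance must be positive semi-definite")

    def to_json(self, path) -> None:
        payload = {
            "model": self.model,
            "names": list(self.names),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "medians": self.medians,
            "n_retained": self.n_retained,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ParameterDistribution":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model=d["model"],
            names=tuple(d["names"]),
            mean=np.asarray(d["mean"]),
            cov=np.asarray(d["cov"]),
            medians={k: float(v) for k, v in d["medians"].items()},
            n_retained=int(d["n_retained"]),
            provenance=d.get("provenance", {}),
        )


def _ladder_invertible(params, n_bites: int, total: float) -> bool:
    """Feasibility predicate: the curve must produce a complete meal.

    The whole midpoint bite ladder (avg increments up to ``total``) must
    invert to finite, positive, strictly increasing times on the model's
    increasing branch.  The LODE curve satisfies this for any valid
    parameters; a quadratic fails when its apex sits below the meal total
    or its intercept above the first bite.
    """
    if isinstance(params, LODEParams):
        return True
    avg = total / n_bites
    ladder = avg * np.arange(1, n_bites + 1) - avg / 2.0
    t = model_time(params, ladder)
    return bool(np.all(np.isfinite(t)) and t[0] > 0 and np.all(np.diff(t) > 0))


def build_parameter_distribution(
    profiles: list[MicrostructureProfile],
    model: str,
    seed,
    jitter_frac: float | None = None,
    max_iter: int = 10,
) -> ParameterDistribution:
    """Fit the model to generated meals and summarize the feasible fits.

    For each profile: generate bite timings, fit the model, and keep the
    fit if its implied curve is feasible over the meal; otherwise
    regenerate the timings from a fresh substream and refit, up to
    ``max_iter`` times.  Errors out when more than half the profiles yield
    no feasible fit — the configured reference statistics are then
    incompatible with the model.
    """
    if len(profiles) < 50:
        raise ValueError("need at least 50 profiles to estimate a covariance")
    rng = as_rng(seed)
    names = PARAM_NAMES[model] + ("n_bites", "total_intake")
    rows = []
    for profile in profiles:
        jitter_sd = None if jitter_frac is None else jitter_frac * profile.meal_duration
        for _ in range(max_iter):
            bites = generate_bite_timings(profile, jitter_sd=jitter_sd, seed=rng)
            try:
                fit = fit_model(bites, model)
            except (NonConvergenceError, ValueError):
                continue
            if _ladder_invertible(fit.params, profile.n_bites, profile.total_intake):
                rows.append(
                    [fit.estimate(p) for p in PARAM_NAMES[model]]
                    + [profile.n_bites, profile.total_intake]
                )
                break
        else:
            log.debug("%s: no feasible %s fit after %d attempts",
                      profile.case_id, model, max_iter)
    if len(rows) < 0.5 * len(profiles):
        raise GenerationError(
            f"only {len(rows)}/{len(profiles)} profiles produced feasible {model} fits; "
            "check the reference statistics"
        )
    arr = np.asarray(rows, dtype=float)
    medians = {name: float(np.median(arr[:, i])) for i, name in enumerate(names)}
    return ParameterDistribution(
        model=model,
        names=names,
        mean=arr.mean(axis=0),
        cov=np.cov(arr, rowvar=False),
        medians=medians,
        n_retained=len(rows),
    )


# ---------------------------------------------------------------------------
# true-parameter draws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueCase:
    """One drawn ground-truth case for the simulation study."""

    case_id: str
    params: QuadraticParams | LODEParams
    n_bites: int
    total_intake: float


def _draw_is_feasible(model: str, vec: np.ndarray) -> bool:
    """Positivity plus full constant-bite constructibility of the draw."""
    nb = int(round(vec[-2]))
    total = vec[-1]
    if nb < 3 or total <= 0:
        return False
    if model == "lode":
        theta, r = vec[0], vec[1]
        return theta > 0 and r > 0
    if vec[1] <= 0:  # the meal must start at a positive eating rate
        return False
    return _ladder_invertible(QuadraticParams(a=vec[0], b=vec[1], c=vec[2]), nb, total)


def sample_true_parameters(
    dist: ParameterDistribution, n: int, seed
) -> list[TrueCase]:
    """Draw ``n`` feasible true-parameter cases from the joint normal.

    Draws violating positivity or failing to produce a complete feasible
    meal are rejected and redrawn (logged); for LODE draws ``emax`` is set
    equal to the drawn total intake, its defining value.  A rejection rate
    above 90% raises — the distribution is then degenerate.
    """
    rng = as_rng(seed)
    out: list[TrueCase] = []
    n_drawn = 0
    n_rejected = 0
    while len(out) < n:
        m = max(2 * (n - len(out)), 16)
        draws = rng.multivariate_normal(dist.mean, dist.cov, size=m, method="eigh")
        for vec in draws:
            n_drawn += 1
            if not _draw_is_feasible(dist.model, vec):
                n_rejected += 1
                continue
            nb = int(round(vec[-2]))
            total = float(vec[-1])
            if dist.model == "lode":
                params = LODEParams(theta=float(vec[0]), r=float(vec[1]), emax=total)
            else:
                params = QuadraticParams(a=float(vec[0]), b=float(vec[1]), c=float(vec[2]))
            out.append(
                TrueCase(
                    case_id=f"case{len(out):04d}",
                    params=params,
                    n_bites=nb,
                    total_intake=total,
                )
            )
            if len(out) == n:
                break
        if n_drawn >= 50 and n_rejected / n_drawn > 0.90:
            raise GenerationError(
                f"rejection rate {n_rejected/n_drawn:.0%} sampling from the "
                f"{dist.model} parameter distribution"
            )
    if n_rejected:
        log.debug("rejected %d/%d %s draws as infeasible", n_rejected, n_drawn, dist.model)
    return out
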