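"""Simulated test datasets for the three study conditions.

Given a drawn ground-truth parameter set, three nested noise conditions
emulate increasingly realistic measurement processes:

* **constant** — simplified cumulative intake: every bite is the average
  bite size and bite times are computed exactly from the true model's
  inverse; no noise anywhere.
* **variable** — idealized continuous weight measurement: per-bite process
  noise makes bite sizes vary, but times are still computed exactly from
  the (jittered) intake through the true model, so there is no measurement
  error in the recorded pairs.
* **measurement_error** — video-coded meals: after computing times as in
  the variable condition, recorded intake is replaced by the constant
  average-bite ladder (intake measurement error) and times are jittered
  (timing measurement error).

With all noise SDs set to zero the three conditions emit identical data.
Total intake at the final bite always equals the drawn total (conservation);
every emitted case passes the BiteSequence validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .generator import TrueCase, as_rng
from .models import BiteSequence, LODEParams, QuadraticParams, model_tag, model_time

__all__ = [
    "SimulatedCase",
    "NonFeasibleDraw",
    "CONDITIONS",
    "DEFAULT_PROCESS_SD_FRAC",
    "DEFAULT_TIMING_JITTER_SD",
    "simulate_constant_bite",
    "simulate_variable_bite",
    "simulate_measurement_error",
    "simulate_condition",
]

CONDITIONS = ("constant", "variable", "measurement_error")

#: process-noise SD as a fraction of the average bite size
DEFAULT_PROCESS_SD_FRAC = 0.10
#: timing measurement noise SD in minutes (~2 s of video-coding error)
DEFAULT_TIMING_JITTER_SD = 2.0 / 60.0


class NonFeasibleDraw(RuntimeError):
    """The true parameters cannot produce a complete feasible meal
    (possible only for quadratic draws); the caller should resample."""


@dataclass
class SimulatedCase:
    """One simulated meal plus its ground truth and noise record."""

    case_id: str
    condition: str
    model: str
    true_params: QuadraticParams | LODEParams
    bites: BiteSequence
    noise: dict[str, float] = field(default_factory=dict)


def _ladder(n_bites: int, total: float) -> np.ndarray:
    e = (total / n_bites) * np.arange(1, n_bites + 1)
    e[-1] = total
    return e


def _times_from_intake(params, intake: np.ndarray, case_id: str) -> np.ndarray:
    """Exact bite times from the true model at midpoint-corrected intake."""
    mid = intake - np.diff(intake, prepend=0.0) / 2.0
    t = np.asarray(model_time(params, mid), dtype=float)
    if not np.all(np.isfinite(t)) or t[0] <= 0 or np.any(np.diff(t) <= 0):
        raise NonFeasibleDraw(
            f"{case_id}: true {model_tag(params)} parameters cannot invert the bite ladder"
        )
    return t


def simulate_constant_bite(
    true_params, n_bites: int, total_intake: float, case_id: str = "case"
) -> SimulatedCase:
    """Constant-bite condition: noise-free data exactly on the true curve."""
    if n_bites < 2:
        raise ValueError("need at least 2 bites")
    intake = _ladder(n_bites, total_intake)
    times = _times_from_intake(true_params, intake, case_id)
    bites = BiteSequence(
        case_id=case_id, times=times, intake=intake, meal_duration=float(times[-1])
    )
    return SimulatedCase(
        case_id=case_id,
        condition="constant",
        model=model_tag(true_params),
        true_params=true_params,
        bites=bites,
        noise={"process_sd": 0.0, "timing_jitter_sd": 0.0},
    )


def _jitter_intake(intake: np.ndarray, process_sd: float, rng) -> np.ndarray:
    """Add process noise to cumulative intake, then repair.

    Repair: jittered cumulative values are sorted (restoring monotonicity
    while preserving the set of values), clipped positive, rescaled so the
    final value equals the true total, and strictly separated.
    """
    total = intake[-1]
    e = intake + rng.normal(0.0, process_sd, size=len(intake))
    e = np.sort(e)
    eps = 1e-9 * total
    e = np.clip(e, eps, None)
    e *= total / e[-1]
    for i in range(1, len(e)):  # enforce strict increase
        if e[i] <= e[i - 1]:
            e[i] = e[i - 1] + eps
    e[-1] = total
    return e


def simulate_variable_bite(
    true_params,
    n_bites: int,
    total_intake: float,
    process_sd: float | None = None,
    seed=None,
    case_id: str = "case",
) -> SimulatedCase:
    """Variable-bite condition: process noise on intake, exact timings.

    ``process_sd`` defaults to 10% of the average bite size.  With
    ``process_sd=0`` the output equals the constant-bite condition.
    """
    if process_sd is None:
        process_sd = DEFAULT_PROCESS_SD_FRAC * total_intake / n_bites
    if process_sd < 0:
        raise ValueError("process_sd must be >= 0")
    rng = as_rng(seed)
    intake = _ladder(n_bites, total_intake)
    if process_sd > 0:
        intake = _jitter_intake(intake, process_sd, rng)
    times = _times_from_intake(true_params, intake, case_id)
    bites = BiteSequence(
        case_id=case_id, times=times, intake=intake, meal_duration=float(times[-1])
    )
    return SimulatedCase(
        case_id=case_id,
        condition="variable",
        model=model_tag(true_params),
        true_params=true_params,
        bites=bites,
        noise={"process_sd": float(process_sd), "timing_jitter_sd": 0.0},
    )


def simulate_measurement_error(
    true_params,
    n_bites: int,
    total_intake: float,
    process_sd: float | None = None,
    timing_jitter_sd: float | None = None,
    seed=None,
    case_id: str = "case",
) -> SimulatedCase:
    """Measurement-error condition: video-coded-style data.

    Runs the variable-bite procedure, then — strictly after the timings
    have been computed — (a) replaces recorded intake with the constant
    average-bite ladder and (b) jitters the recorded timings (default SD
    ~2 s), re-sorted and repaired.  Both recorded intake and timing
    therefore carry measurement error relative to the true curve.
    """
    if timing_jitter_sd is None:
        timing_jitter_sd = DEFAULT_TIMING_JITTER_SD
    if timing_jitter_sd < 0:
        raise ValueError("timing_jitter_sd must be >= 0")
    rng = as_rng(seed)
    var = simulate_variable_bite(
        true_params, n_bites, total_intake,
        process_sd=process_sd, seed=rng, case_id=case_id,
    )
    times = var.bites.times.copy()
    if timing_jitter_sd > 0:
        times = np.sort(times + rng.normal(0.0, timing_jitter_sd, size=len(times)))
        eps = 1e-9 * max(times[-1], 1.0)
        times[0] = max(times[0], eps)
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                times[i] = times[i - 1] + eps
    intake = _ladder(n_bites, total_intake)
    bites = BiteSequence(
        case_id=case_id, times=times, intake=intake, meal_duration=float(times[-1])
    )
    return SimulatedCase(
        case_id=case_id,
        condition="measurement_error",
        model=model_tag(true_params),
        true_params=true_params,
        bites=bites,
        noise={
            "process_sd": var.noise["process_sd"],
            "timing_jitter_sd": float(timing_jitter_sd),
        },
    )


def simulate_condition(
    condition: str,
    case: TrueCase,
    process_sd: float | None = None,
    timing_jitter_sd: float | None = None,
    seed=None,
) -> SimulatedCase:
    """Dispatch one true case through the named condition."""
    if condition == "constant":
        return simulate_constant_bite(
            case.params, case.n_bites, case.total_intake, case_id=case.case_id
        )
    if condition == "variable":
        return simulate_variable_bite(
            case.params, case.n_bites, case.total_intake,
            process_sd=process_sd, seed=seed, case_id=case.case_id,
        )
    if condition == "measurement_error":
        return simulate_measurement_error(
            case.params, case.n_bites, case.total_intake,
            process_sd=process_sd, timing_jitter_sd=timing_jitter_sd,
            seed=seed, case_id=case.case_id,
        )
    raise ValueError(f"unknown condition {condition!r}")
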