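"""Forward/inverse model evaluation, feasibility rules, and the CSV dialect."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from bitecurve.models import (
    BiteSequence,
    DegenerateModelError,
    InvalidParameterError,
    LODEParams,
    QuadraticParams,
    classify_feasibility,
    lode_intake,
    lode_k,
    lode_time,
    quadratic_intake,
    quadratic_time,
    read_bite_csv,
    write_bite_csv,
)

LODE = LODEParams(theta=10.0, r=0.3, emax=300.0)


# ---------------------------------------------------------------------------
# quadratic model
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "params, t, expected",
    [
        ((0.0, 0.0, 5.0), 7.0, 5.0),        # constant curve
        ((0.0, 20.0, 0.0), 3.0, 60.0),      # pure linear eating rate
        ((-0.5, 20.0, 0.0), 10.0, 150.0),   # decelerating curve
    ],
)
def test_quadratic_intake_values(params, t, expected):
    assert quadratic_intake(QuadraticParams(*params), t) == pytest.approx(expected)


@pytest.mark.parametrize(
    "params, e, expected",
    [
        ((0.0, 20.0, 0.0), 60.0, 3.0),
        ((-0.5, 20.0, 0.0), 150.0, 10.0),
    ],
)
def test_quadratic_time_values(params, e, expected):
    q = QuadraticParams(*params)
    t = quadratic_time(q, e)
    assert t == pytest.approx(expected, rel=1e-12)
    # independent oracle: numeric root finding on the forward curve
    t_oracle = brentq(lambda x: quadratic_intake(q, x) - e, 0.0, q.vertex_time if q.a < 0 else 1e3)
    assert t == pytest.approx(t_oracle, rel=1e-9)


def test_quadratic_time_beyond_apex_is_nonfeasible():
    q = QuadraticParams(a=-0.5, b=20.0, c=0.0)
    assert q.max_intake == pytest.approx(200.0)  # apex value b^2/(-4a) + c
    assert math.isnan(quadratic_time(q, 300.0))


def test_quadratic_degenerate_and_invalid():
    with pytest.raises(DegenerateModelError):
        quadratic_time(QuadraticParams(0.0, 0.0, 5.0), 5.0)
    with pytest.raises(InvalidParameterError):
        QuadraticParams(float("nan"), 1.0, 0.0)


# ---------------------------------------------------------------------------
# LODE model
# ---------------------------------------------------------------------------


def test_lode_k_value_and_limits():
    assert lode_k(LODE) == pytest.approx(1.0 / 3.0)
    # k -> r as theta -> 0+, k -> theta/emax as r -> 0+
    assert lode_k(LODEParams(1e-9, 0.3, 300.0)) == pytest.approx(0.3, abs=1e-10)
    assert lode_k(LODEParams(300.0, 1e-12, 300.0)) == pytest.approx(1.0, abs=1e-9)


def test_lode_intake_values():
    assert lode_intake(LODE, 0.0) == 0.0
    k = lode_k(LODE)
    naive = (math.exp(k * 5) - 1) / (math.exp(k * 5) / LODE.emax + LODE.r / LODE.theta)
    assert lode_intake(LODE, 5.0) == pytest.approx(naive, rel=1e-12)
    assert lode_intake(LODE, 5.0) == pytest.approx(90.13, abs=0.01)
    # overflow-safe asymptote
    assert lode_intake(LODE, 1e6) == pytest.approx(LODE.emax)


def test_lode_time_asymptote_behavior():
    assert lode_time(LODE, 0.0) == 0.0
    assert math.isnan(lode_time(LODE, 300.0))
    assert math.isnan(lode_time(LODE, -1.0))
    near = lode_time(LODE, 299.9999)
    assert np.isfinite(near) and near > 30.0


def test_lode_round_trip_with_numeric_oracle():
    e = lode_intake(LODE, 5.0)
    assert lode_time(LODE, e) == pytest.approx(5.0, rel=1e-10)
    t_oracle = brentq(lambda x: lode_intake(LODE, x) - e, 0.0, 1e3)
    assert lode_time(LODE, e) == pytest.approx(t_oracle, rel=1e-8)


def test_lode_invalid_parameters():
    for bad in [(0.0, 0.3, 300.0), (10.0, -0.3, 300.0), (10.0, 0.3, 0.0)]:
        with pytest.raises(InvalidParameterError):
            LODEParams(*bad)


valid_lode = st.builds(
    LODEParams,
    theta=st.floats(0.5, 200.0),
    r=st.floats(0.01, 2.0),
    emax=st.floats(50.0, 1000.0),
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(valid_lode)
def test_lode_curve_increasing_and_bounded(params):
    t = np.linspace(0.0, 10.0 / lode_k(params), 200)
    e = lode_intake(params, t)
    assert np.all(np.diff(e) > 0)
    assert np.all(e < params.emax)
    assert e[0] == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(valid_lode, st.floats(0.01, 1.0))
def test_lode_inverse_is_exact(params, frac):
    t = frac * 10.0 / lode_k(params)
    assert lode_time(params, lode_intake(params, t)) == pytest.approx(t, rel=1e-8)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(valid_lode)
def test_lode_matches_ode_integration(params):
    """The closed form solves dE/dt = (theta + r E)(1 - E/Emax), E(0) = 0."""
    t_end = 5.0 / lode_k(params)

    def rhs(t, e):
        return (params.theta + params.r * e) * (1.0 - e / params.emax)

    sol = solve_ivp(rhs, (0.0, t_end), [0.0], t_eval=np.linspace(0.1, t_end, 20),
                    rtol=1e-10, atol=1e-12)
    expected = lode_intake(params, sol.t)
    assert np.allclose(sol.y[0], expected, rtol=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.floats(-2.0, -0.05), st.floats(5.0, 80.0), st.floats(-20.0, 20.0),
    st.floats(0.05, 0.95),
)
def test_quadratic_inverse_on_increasing_branch(a, b, c, frac):
    q = QuadraticParams(a, b, c)
    t = frac * q.vertex_time
    e = quadratic_intake(q, t)
    t_back = quadratic_time(q, e)
    if t > 0:
        assert t_back == pytest.approx(t, rel=1e-8, abs=1e-10)


# ---------------------------------------------------------------------------
# feasibility classification
# ---------------------------------------------------------------------------


def test_classify_all_feasible():
    flags = classify_feasibility(
        predicted_times=np.linspace(1, 20, 20), predicted_intake=np.linspace(5, 100, 20)
    )
    assert flags.n_nonfeasible == 0 and flags.convergent


def test_ten_percent_convergence_rule():
    t = np.linspace(1, 20, 20)
    t2 = t.copy(); t2[[3, 7]] = np.nan          # 2/20 = 10% -> still convergent
    assert classify_feasibility(predicted_times=t2).convergent
    t3 = t.copy(); t3[[3, 7, 11]] = np.nan      # 3/20 = 15% -> non-convergent
    flags = classify_feasibility(predicted_times=t3)
    assert flags.n_nonfeasible == 3 and not flags.convergent


def test_classify_reasons_and_errors():
    flags = classify_feasibility(
        predicted_times=[-1.0, 2.0, np.nan], predicted_intake=[5.0, 3.0, 10.0]
    )
    assert flags.reasons[0] == "negative-time"
    assert flags.reasons[2] == "non-invertible"
    with pytest.raises(ValueError):
        classify_feasibility(predicted_times=[])
    with pytest.raises(ValueError):
        classify_feasibility()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(valid_lode)
def test_lode_predictions_always_feasible(params):
    """The LODE inverse is defined and increasing on the whole feasible
    intake range, so predicted bites are never non-feasible."""
    e = np.linspace(0.01, 0.999, 30) * params.emax
    t = lode_time(params, e)
    flags = classify_feasibility(predicted_times=t, predicted_intake=e)
    assert flags.n_nonfeasible == 0


# ---------------------------------------------------------------------------
# bite sequences and CSV
# ---------------------------------------------------------------------------


def test_bite_sequence_reports_first_bad_row():
    with pytest.raises(ValueError, match="bite 3"):
        BiteSequence("m1", [1.0, 2.0, 1.5], [10.0, 20.0, 30.0], meal_duration=5.0)
    with pytest.raises(ValueError, match="non-decreasing"):
        BiteSequence("m1", [1.0, 2.0, 3.0], [10.0, 5.0, 30.0], meal_duration=5.0)


def test_csv_round_trip(tmp_path):
    seqs = [
        BiteSequence("kid_a", [1.0, 2.5, 4.0], [10.0, 20.0, 30.0], meal_duration=4.0),
        BiteSequence("kid_b", [0.5, 1.0], [15.0, 30.0], meal_duration=1.0),
    ]
    path = tmp_path / "meals.csv"
    write_bite_csv(path, seqs)
    back = read_bite_csv(path)
    assert [s.case_id for s in back] == ["kid_a", "kid_b"]
    np.testing.assert_allclose(back[0].times, seqs[0].times)
    np.testing.assert_allclose(back[1].intake, seqs[1].intake)


def test_csv_missing_column(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("case_id,time_min\nx,1.0\n")
    with pytest.raises(ValueError, match="missing required columns"):
        read_bite_csv(p)
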