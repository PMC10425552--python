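"""Comparison statistics, correlations, orchestration and the CLI."""

import json
import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from bitecurve.cli import main as cli_main
from bitecurve.report import (
    StudyConfig,
    compare_distributions,
    compare_proportions,
    joint_parameter_table,
    parameter_correlations,
    run_study,
)


# ---------------------------------------------------------------------------
# Fisher exact vs brute-force hypergeometric enumeration
# ---------------------------------------------------------------------------


def _fisher_oracle(table):
    """Two-sided Fisher exact p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def test_fisher_against_enumeration_oracle(rng):
    for _ in range(25):
        a = rng.integers(0, 2, size=rng.integers(5, 25)).astype(bool)
        b = rng.integers(0, 2, size=rng.integers(5, 25)).astype(bool)
        _, p = compare_proportions(a, b)
        table = [[a.sum(), (~a).sum()], [b.sum(), (~b).sum()]]
        assert p == pytest.approx(_fisher_oracle(table), abs=1e-8)


def test_fisher_separated_and_identical_groups():
    _, p = compare_proportions([True] * 10, [False] * 10)
    assert p < 0.001
    assert p == pytest.approx(_fisher_oracle([[10, 0], [0, 10]]), abs=1e-12)
    _, p = compare_proportions([True, False] * 5, [True, False] * 5)
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compare_proportions([], [True])


def test_fisher_8_2_table():
    _, p = compare_proportions([True] * 8 + [False] * 2, [True] * 2 + [False] * 8)
    assert p == pytest.approx(_fisher_oracle([[8, 2], [2, 8]]), abs=1e-10)


# ---------------------------------------------------------------------------
# Mann-Whitney vs a rank-based oracle
# ---------------------------------------------------------------------------


def _mwu_oracle(a, b):
    """U statistic by direct pair counting and its tie-corrected normal p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var)  # continuity corrected
    from scipy.stats import norm
    return u, 2 * norm.sf(abs(z))


def test_mannwhitney_exact_u_values():
    u, _ = compare_distributions([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    u, p = compare_distributions([4, 5, 6], [1, 2, 3])
    assert u == 9.0


def test_mannwhitney_identical_groups_degenerate():
    u, p = compare_distributions([2.0, 2.0], [2.0, 2.0, 2.0])
    assert p == 1.0 and u == 3.0


def test_mannwhitney_against_rank_oracle(rng):
    for _ in range(20):
        a = rng.normal(0, 1, rng.integers(8, 30))
        b = rng.normal(rng.uniform(-1, 1), 1, rng.integers(8, 30))
        u, p = compare_distributions(a, b)
        u_o, p_o = _mwu_oracle(a, b)
        assert u == pytest.approx(u_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-8)


def test_mannwhitney_large_shift_significant(rng):
    a = rng.normal(0, 1, 200)
    b = rng.normal(2, 1, 200)
    _, p = compare_distributions(a, b)
    assert p < 0.001


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def test_parameter_correlations_identity_and_nan():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0], "z": [1.0, 1.0, 1.0]})
    corr = parameter_correlations(df)
    assert corr.loc["x", "x"] == 1.0
    assert corr.loc["x", "y"] == pytest.approx(1.0)
    assert np.isnan(corr.loc["x", "z"])


def test_cross_model_correlation_structure(small_profiles):
    """The quadratic and linear coefficients are strongly anticorrelated
    while the LODE parameters are much less coupled."""
    table = joint_parameter_table(small_profiles, seed=21)
    corr = parameter_correlations(table)
    assert corr.loc["a", "b"] < -0.7
    assert abs(corr.loc["theta", "r"]) < abs(corr.loc["a", "b"])


# ---------------------------------------------------------------------------
# config and orchestration
# ---------------------------------------------------------------------------

TINY = dict(n_cases=8, n_generating_cases=60)


def test_config_yaml_round_trip(tmp_path):
    p = tmp_path / "study.yaml"
    p.write_text(
        "n_cases: 17\n"
        "ci_level: 0.9\n"
        "models: [lode]\n"
        "ref:\n  means: {n_bites: 30, total_intake: 250, meal_duration: 12}\n"
    )
    cfg = StudyConfig.from_yaml(p)
    assert cfg.n_cases == 17 and cfg.ci_level == 0.9 and cfg.models == ("lode",)
    assert cfg.ref.means["n_bites"] == 30
    d = cfg.to_dict()
    assert d["ref"]["means"]["total_intake"] == 250


def test_config_validation():
    with pytest.raises(ValueError):
        StudyConfig(n_cases=0)
    with pytest.raises(ValueError):
        StudyConfig(ci_level=1.5)
    with pytest.raises(ValueError):
        StudyConfig(models=("cubic",))


@pytest.fixture(scope="module")
def tiny_study():
    return run_study(StudyConfig(**TINY), seed=5)


def test_run_study_emits_all_cells(tiny_study):
    assert set(tiny_study.results) == {
        (m, c)
        for m in ("quadratic", "lode")
        for c in ("constant", "variable", "measurement_error")
    }
    for res in tiny_study.results.values():
        assert len(res.fits) == 8
        assert set(res.coverage) == set(res.fits[0].free_names)
    assert not tiny_study.comparisons.empty
    assert {"a", "b", "theta", "r"} <= set(tiny_study.correlations.columns)


def test_run_study_deterministic(tiny_study):
    again = run_study(StudyConfig(**TINY), seed=5)
    assert json.dumps(tiny_study.summary, sort_keys=True) == json.dumps(
        again.summary, sort_keys=True
    )
    for key in tiny_study.results:
        pd.testing.assert_frame_equal(
            tiny_study.results[key].param_frame(), again.results[key].param_frame()
        )


def test_run_study_writes_output_tree(tiny_study, tmp_path):
    out = tmp_path / "study"
    tiny_study.write(out)
    expected = {
        "manifest.json",
        "summary.json",
        "comparisons.csv",
        "parameter_correlations.csv",
        "distribution_lode.json",
        "cases_lode_constant.csv",
        "recovery_params_quadratic_measurement_error.csv",
        "recovery_curve_lode_variable.csv",
    }
    present = {p.name for p in out.iterdir()}
    assert expected <= present
    manifest = json.loads((out / "manifest.json").read_text())
    assert manifest["seed"] == 5
    assert manifest["config"]["n_cases"] == 8


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def test_cli_generate_simulate_fit(tmp_path):
    runner = CliRunner()
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text("n_generating_cases: 60\n")
    r = runner.invoke(cli_main, [
        "generate", "--config", str(cfg), "--seed", "2", "--model", "lode",
        "--outdir", str(tmp_path),
    ])
    assert r.exit_code == 0, r.output
    dist_path = tmp_path / "distribution_lode.json"
    assert dist_path.exists()

    r = runner.invoke(cli_main, [
        "simulate", "--distribution", str(dist_path), "--condition", "constant",
        "--n-cases", "4", "--seed", "3", "--out", str(tmp_path / "meals.csv"),
    ])
    assert r.exit_code == 0, r.output
    assert (tmp_path / "meals.csv.truth.json").exists()

    r = runner.invoke(cli_main, [
        "fit", str(tmp_path / "meals.csv"), "--model", "lode",
        "--out", str(tmp_path / "fits.json"),
    ])
    assert r.exit_code == 0, r.output
    fits = json.loads((tmp_path / "fits.json").read_text())
    assert len(fits) == 4
    truth = json.loads((tmp_path / "meals.csv.truth.json").read_text())
    for case_id, fit in fits.items():
        true_theta = truth["cases"][case_id]["true_params"]["theta"]
        assert fit["estimates"]["theta"] == pytest.approx(true_theta, rel=1e-4)
        lo, hi = fit["ci"]["theta"]
        assert lo <= fit["estimates"]["theta"] <= hi
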