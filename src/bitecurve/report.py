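"""Study orchestration, comparison statistics and report tables.

:func:`run_study` executes the whole validation pipeline for a
:class:`StudyConfig` — generate microstructure, build feasible parameter
distributions, draw true parameters, simulate the three noise conditions,
fit with profile confidence intervals, run the recovery battery — and
returns an in-memory :class:`StudyResult` that can also be written to an
output directory as tidy CSV tables plus a JSON summary (medians and
25th/75th percentiles, the study's descriptive convention for its skewed
distributions) and a manifest that fully determines reproduction.

Comparison statistics follow the study's conventions: Fisher's exact test
for the binary distinct/not outcomes and Mann-Whitney U for the skewed
goodness-of-fit and error measures.  All pairwise contrasts are emitted
and labeled; no multiple-testing correction is applied (raw p-values).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .fitting import FitResult, fit_model, fit_with_intervals
from .generator import (
    GenerationError,
    MicrostructureProfile,
    ParameterDistribution,
    ReferenceStats,
    TrueCase,
    as_rng,
    build_parameter_distribution,
    generate_bite_timings,
    sample_microstructure,
    sample_true_parameters,
)
from .models import PARAM_NAMES, write_bite_csv
from .recovery import (
    CurveError,
    coverage,
    curve_error,
    distinguishability,
    gof_index,
)
from .simulate import (
    CONDITIONS,
    DEFAULT_PROCESS_SD_FRAC,
    DEFAULT_TIMING_JITTER_SD,
    NonFeasibleDraw,
    SimulatedCase,
    simulate_condition,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "ConditionResult",
    "compare_proportions",
    "compare_distributions",
    "parameter_correlations",
    "joint_parameter_table",
    "run_study",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Everything needed to reproduce a validation study."""

    n_cases: int = 100
    n_generating_cases: int = 500
    ref: ReferenceStats = field(default_factory=ReferenceStats)
    models: tuple[str, ...] = ("quadratic", "lode")
    conditions: tuple[str, ...] = CONDITIONS
    process_sd_frac: float = DEFAULT_PROCESS_SD_FRAC
    timing_jitter_sd: float = DEFAULT_TIMING_JITTER_SD
    gen_timing_jitter_frac: float = 0.02  # of meal duration
    ci_level: float = 0.95
    distinct_threshold_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_generating_cases < 1:
            raise ValueError("case counts must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        for m in self.models:
            if m not in PARAM_NAMES:
                raise ValueError(f"unknown model {m!r}")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ref" in raw:
            raw["ref"] = ReferenceStats.from_dict(raw["ref"])
        for key in ("models", "conditions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ref"] = self.ref.to_dict()
        d["models"] = list(self.models)
        d["conditions"] = list(self.conditions)
        return d


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------


def compare_proportions(flags_a, flags_b) -> tuple[float, float]:
    """Two-sided Fisher exact test on two binary vectors.

    Returns ``(odds_ratio, p)`` for the 2x2 table of distinct/not by group.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    table = [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]]
    res = sps.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_distributions(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    Degenerate input (every value identical across both groups) returns
    ``(n_a * n_b / 2, 1.0)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        log.info("Mann-Whitney input degenerate: all values tied")
        return len(a) * len(b) / 2.0, 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def parameter_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among model parameters and meal behaviors.

    ``table`` holds one row per case with any of the columns
    a, b, c, theta, r, n_bites, total_intake.  Zero-variance columns yield
    NaN entries and are logged.
    """
    for col in table.columns:
        if table[col].std(ddof=0) == 0:
            log.warning("zero-variance column %r: correlation undefined", col)
    return table.corr(method="pearson")


def joint_parameter_table(
    profiles: list[MicrostructureProfile],
    seed,
    jitter_frac: float | None = None,
) -> pd.DataFrame:
    """Fit both models to the *same* generated meals, one row per case.

    Used for the cross-model parameter correlation report; cases where
    either fit fails are dropped.
    """
    rng = as_rng(seed)
    rows = []
    for profile in profiles:
        jitter_sd = None if jitter_frac is None else jitter_frac * profile.meal_duration
        bites = generate_bite_timings(profile, jitter_sd=jitter_sd, seed=rng)
        try:
            fq = fit_model(bites, "quadratic")
            fl = fit_model(bites, "lode")
        except Exception:
            continue
        rows.append(
            {
                **fq.params.as_dict(),
                "theta": fl.params.theta,
                "r": fl.params.r,
                "n_bites": profile.n_bites,
                "total_intake": profile.total_intake,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study execution
# ---------------------------------------------------------------------------


@dataclass
class ConditionResult:
    """All per-case results for one (model, condition) cell."""

    model: str
    condition: str
    true_cases: list[TrueCase]
    sim_cases: list[SimulatedCase]
    fits: list[FitResult]
    coverage: dict[str, float]
    distinct: pd.DataFrame
    gof: pd.DataFrame  # columns: case, parameter, gof
    errors: list[CurveError]
    excluded: list[str]  # non-convergent case ids

    def error_frame(self) -> pd.DataFrame:
        rows = []
        for tc, err in zip(self.true_cases, self.errors):
            rows.append(
                {
                    "case_id": tc.case_id,
                    "timing_rmse": err.timing_rmse,
                    "timing_r2": err.timing_r2,
                    "intake_rmse": err.intake_rmse,
                    "intake_r2": err.intake_r2,
                    "n_nonfeasible": err.n_nonfeasible,
                    "n_bites": err.timing_flags.n_bites,
                    "convergent": err.convergent,
                }
            )
        return pd.DataFrame(rows)

    def param_frame(self) -> pd.DataFrame:
        rows = []
        names = PARAM_NAMES[self.model]
        gof_lookup = {
            (r.case, r.parameter): r.gof for r in self.gof.itertuples(index=False)
        }
        for i, (tc, fit) in enumerate(zip(self.true_cases, self.fits)):
            for name in names:
                lo, hi = fit.ci[name]
                sub = self.distinct
                row = sub[(sub["case"] == i) & (sub["parameter"] == name)].iloc[0]
                rows.append(
                    {
                        "case_id": tc.case_id,
                        "parameter": name,
                        "true": getattr(tc.params, name),
                        "estimate": fit.estimate(name),
                        "ci_lower": lo,
                        "ci_upper": hi,
                        "covered": lo <= getattr(tc.params, name) <= hi,
                        "overlap_count": row["overlap_count"],
                        "distinct": row["distinct"],
                        "any_distinct": row["any_distinct"],
                        "gof": gof_lookup[(i, name)],
                    }
                )
        return pd.DataFrame(rows)


def _med_iqr(x) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return {"median": float("nan"), "q25": float("nan"), "q75": float("nan")}
    return {
        "median": float(np.median(x)),
        "q25": float(np.percentile(x, 25)),
        "q75": float(np.percentile(x, 75)),
    }


def _summarize_cell(res: ConditionResult) -> dict:
    names = PARAM_NAMES[res.model]
    n = len(res.fits)
    pf = res.param_frame()
    ef = res.error_frame()
    ok = ef[ef["convergent"]]
    cell: dict = {
        "n_cases": n,
        "coverage": res.coverage,
        "pct_any_distinct": 100.0 * float(
            pf.drop_duplicates("case_id")["any_distinct"].mean()
        ),
        "pct_cases_with_nonfeasible": 100.0 * float((ef["n_nonfeasible"] > 0).mean()),
        "n_excluded": len(res.excluded),
        "parameters": {},
        "curve_error": {},
    }
    for name in names:
        sub = pf[pf["parameter"] == name]
        cell["parameters"][name] = {
            "pct_distinct": 100.0 * float(sub["distinct"].mean()),
            "overlap": _med_iqr(sub["overlap_count"]),
            "gof": _med_iqr(sub["gof"]),
        }
    for direction in ("timing", "intake"):
        cell["curve_error"][direction] = {
            "rmse": _med_iqr(ok[f"{direction}_rmse"]),
            "pseudo_r2": _med_iqr(ok[f"{direction}_r2"]),
        }
    return cell


def _comparisons(results: dict[tuple[str, str], ConditionResult]) -> pd.DataFrame:
    """All pairwise Fisher / Mann-Whitney contrasts, labeled."""
    rows = []

    def add(kind, measure, group_a, group_b, stat, p):
        rows.append(
            {"test": kind, "measure": measure, "group_a": group_a,
             "group_b": group_b, "statistic": stat, "p_value": p}
        )

    keys = list(results)
    models = sorted({m for m, _ in keys})
    conditions = [c for c in CONDITIONS if any(k[1] == c for k in keys)]

    # between models within condition: distinctness + curve error
    if len(models) == 2:
        for cond in conditions:
            ra, rb = results.get((models[0], cond)), results.get((models[1], cond))
            if ra is None or rb is None:
                continue
            fa = ra.param_frame().drop_duplicates("case_id")["any_distinct"]
            fb = rb.param_frame().drop_duplicates("case_id")["any_distinct"]
            orat, p = compare_proportions(fa, fb)
            add("fisher", "any_distinct", f"{models[0]}/{cond}", f"{models[1]}/{cond}", orat, p)
            ea = ra.error_frame().query("convergent")
            eb = rb.error_frame().query("convergent")
            for m in ("timing_rmse", "timing_r2", "intake_rmse", "intake_r2"):
                u, p = compare_distributions(ea[m].dropna(), eb[m].dropna())
                add("mannwhitney", m, f"{models[0]}/{cond}", f"{models[1]}/{cond}", u, p)

    # between conditions within model: distinctness, gof, error
    for model in models:
        cs = [c for c in conditions if (model, c) in results]
        for i in range(len(cs)):
            for j in range(i + 1, len(cs)):
                ra, rb = results[(model, cs[i])], results[(model, cs[j])]
                fa = ra.param_frame().drop_duplicates("case_id")["any_distinct"]
                fb = rb.param_frame().drop_duplicates("case_id")["any_distinct"]
                orat, p = compare_proportions(fa, fb)
                add("fisher", "any_distinct", f"{model}/{cs[i]}", f"{model}/{cs[j]}", orat, p)
                for name in PARAM_NAMES[model]:
                    ga = ra.gof[ra.gof["parameter"] == name]["gof"]
                    gb = rb.gof[rb.gof["parameter"] == name]["gof"]
                    u, p = compare_distributions(ga, gb)
                    add("mannwhitney", f"gof_{name}", f"{model}/{cs[i]}", f"{model}/{cs[j]}", u, p)
                ea = ra.error_frame().query("convergent")
                eb = rb.error_frame().query("convergent")
                for m in ("timing_rmse", "timing_r2", "intake_rmse", "intake_r2"):
                    u, p = compare_distributions(ea[m].dropna(), eb[m].dropna())
                    add("mannwhitney", m, f"{model}/{cs[i]}", f"{model}/{cs[j]}", u, p)
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Full output of one validation study run."""

    config: StudyConfig
    seed: int
    distributions: dict[str, ParameterDistribution]
    results: dict[tuple[str, str], ConditionResult]
    correlations: pd.DataFrame
    summary: dict
    comparisons: pd.DataFrame

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "package": "bitecurve",
            "version": __version__,
            "seed": self.seed,
            "config": self.config.to_dict(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for model, dist in self.distributions.items():
            dist.to_json(out / f"distribution_{model}.json")
        self.correlations.to_csv(out / "parameter_correlations.csv")
        for (model, cond), res in self.results.items():
            stem = f"{model}_{cond}"
            write_bite_csv(out / f"cases_{stem}.csv", [c.bites for c in res.sim_cases])
            res.param_frame().to_csv(out / f"recovery_params_{stem}.csv", index=False)
            res.error_frame().to_csv(out / f"recovery_curve_{stem}.csv", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2))
        self.comparisons.to_csv(out / "comparisons.csv", index=False)


def _simulate_with_retry(condition, case, config, rng, max_tries=50) -> SimulatedCase:
    avg = case.total_intake / case.n_bites
    for _ in range(max_tries):
        try:
            return simulate_condition(
                condition,
                case,
                process_sd=config.process_sd_frac * avg,
                timing_jitter_sd=config.timing_jitter_sd,
                seed=rng,
            )
        except NonFeasibleDraw:
            if condition == "constant":
                raise  # deterministic: retrying cannot help
            log.debug("%s/%s: noise produced a non-invertible meal; rejittering",
                      case.case_id, condition)
    raise GenerationError(f"{case.case_id}: no feasible {condition} simulation in {max_tries} tries")


def run_study(config: StudyConfig, seed: int) -> StudyResult:
    """Execute the full pipeline; deterministic for a given (config, seed)."""
    ss = np.random.SeedSequence(seed)
    s_gen, s_corr, *s_models = ss.spawn(2 + len(config.models))

    profiles = sample_microstructure(
        config.ref, config.n_generating_cases, np.random.default_rng(s_gen)
    )

    distributions: dict[str, ParameterDistribution] = {}
    results: dict[tuple[str, str], ConditionResult] = {}
    for model, s_model in zip(config.models, s_models):
        s_dist, s_true, *s_conds = s_model.spawn(2 + len(config.conditions))
        rng_dist = np.random.default_rng(s_dist)
        dist = build_parameter_distribution(
            profiles, model, rng_dist, jitter_frac=config.gen_timing_jitter_frac
        )
        dist.provenance = {"study_seed": seed, "model": model,
                           "n_generating_cases": config.n_generating_cases}
        distributions[model] = dist
        true_cases = sample_true_parameters(dist, config.n_cases, np.random.default_rng(s_true))
        truth = {
            name: np.array([getattr(tc.params, name) for tc in true_cases])
            for name in PARAM_NAMES[model]
        }
        for cond, s_cond in zip(config.conditions, s_conds):
            rng = np.random.default_rng(s_cond)
            sims = [_simulate_with_retry(cond, tc, config, rng) for tc in true_cases]
            # video-coded data carries a known timing resolution; declare it
            # to the likelihood for the measurement-error condition only
            timing_sd = config.timing_jitter_sd if cond == "measurement_error" else 0.0
            fits = [
                fit_with_intervals(
                    sc.bites, model, level=config.ci_level, timing_sd=timing_sd
                )
                for sc in sims
            ]
            cov = coverage(truth, fits)
            dis = distinguishability(fits, threshold_frac=config.distinct_threshold_frac)
            gof_rows = []
            errors = []
            excluded = []
            for i, (tc, fit) in enumerate(zip(true_cases, fits)):
                for name, g in gof_index(tc.params, fit.params, dist.medians).items():
                    gof_rows.append({"case": i, "parameter": name, "gof": g})
                err = curve_error(tc.params, fit.params, sims[i].bites)
                errors.append(err)
                if not err.convergent:
                    excluded.append(tc.case_id)
            results[(model, cond)] = ConditionResult(
                model=model,
                condition=cond,
                true_cases=true_cases,
                sim_cases=sims,
                fits=fits,
                coverage=cov,
                distinct=dis,
                gof=pd.DataFrame(gof_rows),
                errors=errors,
                excluded=excluded,
            )
            log.info("finished %s/%s: coverage %s", model, cond, cov)

    corr_table = joint_parameter_table(
        profiles, np.random.default_rng(s_corr),
        jitter_frac=config.gen_timing_jitter_frac,
    )
    correlations = parameter_correlations(corr_table)

    summary = {
        f"{model}/{cond}": _summarize_cell(res)
        for (model, cond), res in results.items()
    }
    comparisons = _comparisons(results)
    return StudyResult(
        config=config,
        seed=seed,
        distributions=distributions,
        results=results,
        correlations=correlations,
        summary=summary,
        comparisons=comparisons,
    )
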