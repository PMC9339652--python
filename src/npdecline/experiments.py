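"""Calibration and recovery experiments over the full pipeline.

Each function runs a self-contained simulation experiment and returns plain
numbers: parameter recovery for the norm regressions, z-score calibration
of the scoring stage on noise-only cohorts, coefficient recovery and CI
coverage for the Cox stage, type-I calibration of the conversion
chi-squared, and the directional behaviour of the default study simulation.
They are shared by the test suite and the acceptance script.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .evaluation import (
    apply_eligibility,
    build_survival_records,
    chi2_2x2,
    conversion_table,
    fit_cox,
    progression_curves,
)
from .model import Diagnosis, TestId
from .norms import fit_norm, fit_norm_table
from .scoring import NPStatus, score_cohort
from .simulate import (
    SimulationConfig,
    generate_reference_cohort,
    generate_study_cohort,
    simulate_survival_records,
)

STRATA = (Diagnosis.NORMAL, Diagnosis.IMPAIRED_NOT_MCI, Diagnosis.MCI)


def norm_recovery_experiment(
    seed: int,
    n_replicates: int = 200,
    n: int = 294,
    intercept: float = 6.883,
    slope: float = 0.595,
    resid_sd: float = 2.773,
    baseline_mean: float = 14.0,
    baseline_sd: float = 4.0,
) -> dict:
    """Recover known norm-regression parameters from reference-sized samples.

    Each replicate draws a baseline vector, generates follow-up scores from
    the true linear model, fits the norm, and checks that intercept, slope
    and the standard error of the estimate each land within 3 closed-form
    sampling standard errors of the truth.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    est_slopes = []
    for _ in range(n_replicates):
        x = rng.normal(baseline_mean, baseline_sd, n)
        y = intercept + slope * x + rng.normal(0.0, resid_sd, n)
        eq = fit_norm(TestId.LM_IMMEDIATE, x, y)
        sxx = float(np.sum((x - x.mean()) ** 2))
        se_slope = resid_sd / math.sqrt(sxx)
        se_intercept = resid_sd * math.sqrt(1.0 / n + x.mean() ** 2 / sxx)
        se_see = resid_sd / math.sqrt(2.0 * (n - 2))
        ok = (
            abs(eq.intercept - intercept) < 3 * se_intercept
            and abs(eq.slope - slope) < 3 * se_slope
            and abs(eq.see - resid_sd) < 3 * se_see
        )
        hits += ok
        est_slopes.append(eq.slope)
    return {
        "recovery_rate": hits / n_replicates,
        "mean_slope": float(np.mean(est_slopes)),
        "n_replicates": n_replicates,
        "n": n,
    }


def reference_calibration_experiment(
    seed: int, n_fit: int = 10000, n_eval: int = 10000
) -> dict:
    """Score a noise-only cohort with norms fitted on an independent one.

    When the scoring model is correctly specified, every subtest z should
    be standard-normal up to Monte-Carlo error: means near 0, SDs near 1.
    """
    fit_cohort = generate_reference_cohort(
        SimulationConfig(seed=seed, n_reference=n_fit)
    )
    norms = fit_norm_table(fit_cohort, label="independent reference fit")
    eval_cohort = generate_reference_cohort(
        SimulationConfig(seed=seed + 1_000_003, n_reference=n_eval)
    )
    results = [
        r for r in score_cohort(eval_cohort, norms) if r.composite_z is not None
    ]
    out = {"n_scored": len(results)}
    subtest_means, subtest_sds = [], []
    for test in TestId:
        z = np.array([r.subtest_z[test] for r in results])
        subtest_means.append(float(z.mean()))
        subtest_sds.append(float(z.std(ddof=1)))
    composite = np.array([r.composite_z for r in results])
    out.update(
        {
            "subtest_mean_min": min(subtest_means),
            "subtest_mean_max": max(subtest_means),
            "subtest_sd_min": min(subtest_sds),
            "subtest_sd_max": max(subtest_sds),
            "composite_mean": float(composite.mean()),
            "composite_sd": float(composite.std(ddof=1)),
        }
    )
    return out


def cox_recovery_experiment(
    seed: int,
    n_replicates: int = 100,
    n: int = 5000,
    true_hr: float = 2.0,
) -> dict:
    """Log-hazard-ratio recovery and CI coverage at a known true effect."""
    log_hr = math.log(true_hr)
    coefs, covered = [], 0
    for rep in range(n_replicates):
        records = simulate_survival_records(
            n=n, seed=seed + 7919 * rep, log_hr_per_decline_unit=log_hr
        )
        res = fit_cox(records, predictor="continuous_z")
        coefs.append(res.coef)
        lo = res.coef - 1.959963984540054 * res.se_coef
        hi = res.coef + 1.959963984540054 * res.se_coef
        covered += lo <= log_hr <= hi
    mean_coef = float(np.mean(coefs))
    return {
        "mean_log_hr": mean_coef,
        "mean_hr": float(np.exp(mean_coef)),
        "abs_log_hr_error": abs(mean_coef - log_hr),
        "ci_coverage": covered / n_replicates,
        "n_replicates": n_replicates,
        "n": n,
    }


def chi2_null_calibration_experiment(
    seed: int,
    n_replicates: int = 1000,
    n: int = 600,
    np_plus_fraction: float = 0.3,
    conversion_rate: float = 0.15,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the within-diagnosis 2x2 chi-squared under the null.

    Conversion is drawn independently of NP status, so the rejection rate
    at level alpha should match alpha up to binomial error.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        n_plus = rng.binomial(n, np_plus_fraction)
        n_minus = n - n_plus
        conv_plus = rng.binomial(n_plus, conversion_rate)
        conv_minus = rng.binomial(n_minus, conversion_rate)
        table = np.array(
            [[conv_plus, n_plus - conv_plus], [conv_minus, n_minus - conv_minus]]
        )
        _chi2, _dof, p = chi2_2x2(table)
        rejections += p < alpha
    return {
        "rejection_rate": rejections / n_replicates,
        "alpha": alpha,
        "n_replicates": n_replicates,
        "n": n,
    }


def study_evaluation_experiment(seed: int, n_study: int = 20000) -> dict:
    """Full pipeline on the default study simulation.

    Simulates a study cohort under default conditions, applies eligibility,
    fits norms on an independent reference cohort, scores NP decline,
    and summarizes stratified conversion, chi-squared contrasts, Cox models
    and progression-curve ordering.
    """
    cfg = replace(SimulationConfig(seed=seed), n_study=n_study)
    cohort = generate_study_cohort(cfg)
    eligible, ledger = apply_eligibility(cohort)
    ref = generate_reference_cohort(
        SimulationConfig(seed=seed + 2_000_003, n_reference=10000)
    )
    norms = fit_norm_table(ref, label="independent reference fit")
    results = score_cohort(eligible, norms)
    records = build_survival_records(eligible, results)
    stats = conversion_table(records)

    cells = stats.cells.set_index(["diagnosis_12m", "np_status"])
    conv = {
        (d.value, s.value): float(
            cells.loc[(d.value, s.value), "conversion_proportion"]
        )
        for d in STRATA
        for s in (NPStatus.NP_PLUS, NPStatus.NP_MINUS)
    }
    ratios = {
        d.value: conv[(d.value, "NP_PLUS")] / conv[(d.value, "NP_MINUS")]
        for d in STRATA
    }
    overall = {
        d.value: float(
            cells.loc[d.value].converters.sum() / cells.loc[d.value].n.sum()
        )
        for d in STRATA
    }

    curves = progression_curves(records)
    top = curves[(curves.diagnosis_12m == "MCI") & (curves.np_status == "NP_PLUS")]
    bottom = curves[
        (curves.diagnosis_12m == "NORMAL") & (curves.np_status == "NP_MINUS")
    ]
    merged = top.merge(
        bottom, on="time_months", suffixes=("_top", "_bottom")
    )
    curve_ordering_holds = bool(
        (
            merged.cumulative_progression_top
            >= merged.cumulative_progression_bottom
        ).all()
    )

    cox_all = fit_cox(records, predictor="continuous_z")
    cox_by_stratum = {
        d.value: fit_cox(records, predictor="continuous_z", stratum=d)
        for d in STRATA
    }
    np_plus = [r for r in results if r.np_status is NPStatus.NP_PLUS]
    determinate = [r for r in results if r.composite_z is not None]
    return {
        "ledger": ledger,
        "n_records": len(records),
        "np_plus_fraction": len(np_plus) / len(determinate),
        "conversion": conv,
        "np_ratio_by_stratum": ratios,
        "overall_conversion_by_stratum": overall,
        "chi2_by_stratum": {
            row.diagnosis_12m: float(row.chi2)
            for row in stats.contrasts.itertuples()
        },
        "curve_ordering_holds": curve_ordering_holds,
        "cox_all": cox_all,
        "cox_by_stratum": cox_by_stratum,
    }
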