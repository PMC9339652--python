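"""Eligibility, survival-record construction, and the prognostic models."""
import numpy as np
import pytest

from npdecline.evaluation import (
    EvaluationError,
    SurvivalRecord,
    ancova_factorial,
    apply_eligibility,
    build_survival_records,
    cdr_outcome,
    chi2_2x2,
    conversion_table,
    fit_cox,
    progression_curves,
)
from npdecline.model import Cohort, Diagnosis, Sex
from npdecline.scoring import NPStatus, score_cohort
from npdecline.simulate import simulate_survival_records

from conftest import make_battery, make_subject


def _visits(*specs):
    return [(m, d, c, make_battery()) for (m, d, c) in specs]


N, I, M, D = (
    Diagnosis.NORMAL,
    Diagnosis.IMPAIRED_NOT_MCI,
    Diagnosis.MCI,
    Diagnosis.DEMENTIA,
)


def eligibility_fixture():
    """Twelve hand-built subjects exercising every exclusion rule.

    Hand count: age 2, baseline diagnosis 1, exam count 2, follow-up
    duration 1, dementia by 12 months 3, eligible 3.
    """
    subjects = [
        # excluded: under 60 at baseline
        make_subject("X_AGE1", age0=59.0, visit_specs=_visits((0, N, 0), (12, N, 0), (24, N, 0))),
        # excluded: under 60 AND only 2 exams -> counted under age (first rule)
        make_subject("X_AGE2", age0=55.0, visit_specs=_visits((0, N, 0), (12, N, 0))),
        # excluded: demented at baseline
        make_subject("X_DX", age0=70.0, visit_specs=_visits((0, D, 1.0), (12, D, 1.0), (24, D, 1.0))),
        # excluded: 2 exams only
        make_subject("X_EXAMS1", age0=70.0, visit_specs=_visits((0, N, 0), (13, N, 0))),
        # excluded: 1 exam only
        make_subject("X_EXAMS2", age0=70.0, visit_specs=_visits((0, M, 0.5))),
        # excluded: 3 exams but total follow-up only 12 months
        make_subject("X_FU", age0=70.0, visit_specs=_visits((0, N, 0), (6, N, 0), (12, N, 0))),
        # excluded: demented at month 11
        make_subject("X_DEM11", age0=70.0, visit_specs=_visits((0, N, 0), (11, D, 1.0), (24, D, 1.0))),
        # excluded: demented at the 12-month exam
        make_subject("X_DEM12", age0=70.0, visit_specs=_visits((0, M, 0.5), (12, D, 1.0), (24, D, 1.0))),
        # excluded: demented at month 10 then still demented later
        make_subject("X_DEM10", age0=82.0, visit_specs=_visits((0, I, 0.5), (10, D, 1.0), (30, D, 1.0))),
        # eligible: converts at month 36
        make_subject("E_CONV", age0=70.0, visit_specs=_visits((0, N, 0), (12, N, 0), (24, N, 0), (36, D, 1.0))),
        # eligible: censored at month 60
        make_subject("E_CENS", age0=75.0, visit_specs=_visits((0, M, 0.5), (12, M, 0.5), (36, M, 0.5), (60, M, 0.5))),
        # eligible: exactly 3 exams, just over 12 months
        make_subject("E_MIN", age0=60.0, visit_specs=_visits((0, I, 0), (6, I, 0), (12.5, I, 0.5))),
    ]
    return Cohort(subjects=subjects, provenance="eligibility fixture")


EXPECTED_LEDGER = {
    "age": 2,
    "baseline_diagnosis": 1,
    "exam_count": 2,
    "followup_duration": 1,
    "dementia_by_12m": 3,
    "eligible": 3,
    "total": 12,
}


def test_eligibility_ledger_matches_hand_count():
    eligible, ledger = apply_eligibility(eligibility_fixture())
    assert ledger == EXPECTED_LEDGER
    assert {s.subject_id for s in eligible} == {"E_CONV", "E_CENS", "E_MIN"}


def test_eligibility_ledger_conservation():
    _, ledger = apply_eligibility(eligibility_fixture())
    excluded = sum(
        v for k, v in ledger.items() if k not in ("eligible", "total")
    )
    assert excluded + ledger["eligible"] == ledger["total"]


def _record(sid="R", time=24.0, event=True, z=-1.0, status=NPStatus.NP_PLUS,
            diag=Diagnosis.NORMAL, age=72.0, sex=Sex.FEMALE, edu=16.0):
    return SurvivalRecord(
        subject_id=sid, time_months=time, event=event, age_years=age,
        sex=sex, education_years=edu, np_decline_z=z, np_status=status,
        diagnosis_12m=diag,
    )


def test_survival_record_times(norms):
    cohort = Cohort(
        subjects=[
            make_subject("CONV", age0=70.0, visit_specs=_visits((0, N, 0), (12, N, 0), (24, N, 0), (36, D, 1.0))),
            make_subject("CENS", age0=70.0, visit_specs=_visits((0, N, 0), (12, N, 0), (60, N, 0))),
        ]
    )
    records = build_survival_records(cohort, score_cohort(cohort, norms))
    by_id = {r.subject_id: r for r in records}
    assert by_id["CONV"].time_months == 24.0 and by_id["CONV"].event
    assert by_id["CENS"].time_months == 48.0 and not by_id["CENS"].event
    assert by_id["CONV"].diagnosis_12m is Diagnosis.NORMAL


def test_indeterminate_subjects_dropped(norms):
    subj = make_subject("NOFU", visit_specs=_visits((0, N, 0), (30, N, 0), (42, N, 0)))
    cohort = Cohort(subjects=[subj])
    records = build_survival_records(cohort, score_cohort(cohort, norms))
    assert records == []


def test_chi2_hand_example():
    """[[30/100 converters NP+], [10/100 NP-]] -> expected counts 20/80 and
    chi2 = 12.5 with 1 df."""
    chi2, dof, _p = chi2_2x2(np.array([[30, 70], [10, 90]]))
    assert chi2 == pytest.approx(12.5)
    assert dof == 1


def test_conversion_table_counts_and_null_contrast():
    records = (
        [_record(f"a{i}", event=(i < 30), status=NPStatus.NP_PLUS) for i in range(100)]
        + [_record(f"b{i}", event=(i < 10), status=NPStatus.NP_MINUS) for i in range(100)]
        # identical conversion in NP+ and NP- within MCI -> chi2 = 0
        + [_record(f"c{i}", event=(i < 5), status=NPStatus.NP_PLUS, diag=M) for i in range(50)]
        + [_record(f"d{i}", event=(i < 5), status=NPStatus.NP_MINUS, diag=M) for i in range(50)]
    )
    stats = conversion_table(records)
    cells = stats.cells.set_index(["diagnosis_12m", "np_status"])
    assert cells.loc[("NORMAL", "NP_PLUS"), "converters"] == 30
    assert cells.loc[("NORMAL", "NP_MINUS"), "conversion_proportion"] == pytest.approx(0.1)
    contrasts = stats.contrasts.set_index("diagnosis_12m")
    assert contrasts.loc["NORMAL", "chi2"] == pytest.approx(12.5)
    assert contrasts.loc["MCI", "chi2"] == pytest.approx(0.0)
    assert np.isnan(contrasts.loc["IMPAIRED_NOT_MCI", "chi2"])  # empty cells


def test_conversion_table_cross_checks_with_records():
    rng = np.random.default_rng(5)
    records = [
        _record(
            f"s{i}",
            event=bool(rng.random() < 0.2),
            status=NPStatus.NP_PLUS if rng.random() < 0.4 else NPStatus.NP_MINUS,
            diag=[N, I, M][rng.integers(3)],
        )
        for i in range(500)
    ]
    stats = conversion_table(records)
    for row in stats.cells.itertuples():
        direct = [
            r.event
            for r in records
            if r.diagnosis_12m.value == row.diagnosis_12m
            and r.np_status.value == row.np_status
        ]
        assert row.n == len(direct)
        if direct:
            assert row.conversion_proportion == pytest.approx(np.mean(direct))


def test_cox_null_effect_recovery():
    records = simulate_survival_records(n=2000, seed=42, log_hr_per_decline_unit=0.0)
    res = fit_cox(records)
    assert abs(res.coef) < 3 * res.se_coef
    assert res.ci_low < 1.0 < res.ci_high


def test_cox_direction_agreement_continuous_vs_binary():
    records = simulate_survival_records(n=3000, seed=43)
    cont = fit_cox(records, predictor="continuous_z")
    binary = fit_cox(records, predictor="np_status")
    assert cont.hazard_ratio > 1.0
    assert binary.hazard_ratio > 1.0
    assert cont.p_value < 0.001


def test_cox_no_events_is_structured_error():
    records = [_record(f"s{i}", event=False) for i in range(50)]
    with pytest.raises(EvaluationError, match="events"):
        fit_cox(records)


def test_cox_reports_model_statistics():
    records = simulate_survival_records(n=2000, seed=44)
    res = fit_cox(records)
    assert res.hazard_ratio > 0
    assert res.ci_low < res.hazard_ratio < res.ci_high
    assert res.chi_square > 0
    assert res.minus2_loglik > 0
    assert res.n == 2000
    assert set(res.covariate_estimates) == {"age_years", "sex_male", "education_years"}


def _ancova_records(rng, shift=0.0, n=400):
    records = []
    for i in range(n):
        diag = [N, I, M][rng.integers(3)]
        event = bool(rng.random() < 0.3)
        z = rng.normal(0, 1) + (shift if event else 0.0)
        records.append(
            _record(
                f"s{i}", event=event, z=z,
                status=NPStatus.NP_PLUS if z <= -0.5808 else NPStatus.NP_MINUS,
                diag=diag,
                age=float(rng.normal(74, 7)),
                sex=Sex.MALE if rng.random() < 0.4 else Sex.FEMALE,
                edu=float(rng.normal(15, 3)),
            )
        )
    return records


def test_ancova_null_factors_not_significant(rng):
    res = ancova_factorial(_ancova_records(rng))
    assert res.anova.loc["C(outcome)", "PR(>F)"] > 0.001
    assert len(res.adjusted_means) == 6
    assert len(res.pairwise) == 15


def test_ancova_detects_converter_shift():
    rng = np.random.default_rng(7)
    res = ancova_factorial(_ancova_records(rng, shift=-0.5, n=3000))
    assert res.anova.loc["C(outcome)", "PR(>F)"] < 1e-6
    means = res.adjusted_means.set_index(["diagnosis", "outcome"])
    for diag in ("NORMAL", "IMPAIRED_NOT_MCI", "MCI"):
        assert (
            means.loc[(diag, "DEMENTIA"), "adjusted_mean"]
            < means.loc[(diag, "NO_DEMENTIA"), "adjusted_mean"]
        )


def test_ancova_reduces_to_anova_without_covariate_effects():
    """With no true covariate effects, adjusted means equal raw cell means
    up to estimation noise."""
    rng = np.random.default_rng(8)
    records = _ancova_records(rng, shift=-0.4, n=4000)
    res = ancova_factorial(records)
    raw = {}
    for r in records:
        key = (r.diagnosis_12m.value, "DEMENTIA" if r.event else "NO_DEMENTIA")
        raw.setdefault(key, []).append(r.np_decline_z)
    for row in res.adjusted_means.itertuples():
        assert row.adjusted_mean == pytest.approx(
            np.mean(raw[(row.diagnosis, row.outcome)]), abs=0.1
        )


def test_ancova_bonferroni_scales_p_values(rng):
    res = ancova_factorial(_ancova_records(rng, n=600))
    for row in res.pairwise.itertuples():
        assert row.p_bonferroni == pytest.approx(min(1.0, row.p_raw * 15))


def test_progression_no_events_flat_zero():
    records = [_record(f"s{i}", time=30.0 + i, event=False) for i in range(20)]
    curves = progression_curves(records)
    assert (curves.cumulative_progression == 0.0).all()


def test_progression_single_step_group():
    records = [_record(f"s{i}", time=24.0, event=True) for i in range(10)]
    curves = progression_curves(records)
    g = curves[(curves.diagnosis_12m == "NORMAL") & (curves.np_status == "NP_PLUS")]
    before = g[g.time_months < 24.0]
    after = g[g.time_months >= 24.0]
    assert (before.cumulative_progression == 0.0).all()
    assert np.allclose(after.cumulative_progression, 1.0)
    assert g[g.time_months == 24.0].events_interval.iloc[0] == 10


def test_cdr_outcome_event_and_exclusions(norms):
    cohort = Cohort(
        subjects=[
            # CDR 0 at the 12-month exam, rises to 0.5 at month 36
            make_subject("CDR_EVT", visit_specs=_visits((0, N, 0), (12, N, 0), (24, N, 0), (36, M, 0.5))),
            # CDR already 0.5 at the 12-month exam: excluded from this set
            make_subject("CDR_EXC", visit_specs=_visits((0, M, 0.5), (12, M, 0.5), (24, M, 0.5))),
            # CDR 0 throughout: censored at the last visit
            make_subject("CDR_CENS", visit_specs=_visits((0, N, 0), (12, N, 0), (48, N, 0))),
        ]
    )
    records = cdr_outcome(cohort, score_cohort(cohort, norms))
    by_id = {r.subject_id: r for r in records}
    assert set(by_id) == {"CDR_EVT", "CDR_CENS"}
    assert by_id["CDR_EVT"].event and by_id["CDR_EVT"].time_months == 24.0
    assert not by_id["CDR_CENS"].event
    assert by_id["CDR_CENS"].time_months == 36.0


def test_cdr_outcome_drops_missing_cdr(norms):
    subj = make_subject("NOCDR", visit_specs=_visits((0, N, None), (12, N, None), (24, N, None)))
    cohort = Cohort(subjects=[subj])
    assert cdr_outcome(cohort, score_cohort(cohort, norms)) == []
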