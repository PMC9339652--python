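"""Subtest and composite NP-decline z-scores, classification, and cutoffs."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npdecline.model import Diagnosis, TestId
from npdecline.scoring import (
    PUBLISHED_CUTOFF,
    CutoffSpec,
    NPStatus,
    ScoringPolicy,
    classify,
    percentile_of_cutoff,
    roc_optimal_cutoff,
    score_subject,
    subtest_z,
    subtest_z_from_raw,
)

from conftest import make_battery, make_subject


def test_subtest_z_zero_when_actual_equals_predicted():
    assert subtest_z(5.0, 5.0, 2.0) == 0.0


def test_subtest_z_rejects_nonpositive_see():
    with pytest.raises(ValueError, match="> 0"):
        subtest_z(1.0, 0.0, 0.0)


@pytest.mark.parametrize(
    "test,baseline,followup,expected",
    [
        # (10 - (6.883 + 0.595*10)) / 2.7730
        (TestId.LM_IMMEDIATE, 10.0, 10.0, (10.0 - 12.833) / 2.7730),
        # (-log10 25 + (0.589 + 0.598*log10 30)) / 0.1009
        (
            TestId.TRAILS_A,
            30.0,
            25.0,
            (-math.log10(25.0) + 0.589 + 0.598 * math.log10(30.0)) / 0.1009,
        ),
    ],
)
def test_subtest_z_worked_examples(norms, test, baseline, followup, expected):
    assert subtest_z_from_raw(norms[test], baseline, followup) == pytest.approx(
        expected, abs=1e-9
    )


@pytest.mark.parametrize(
    "z,expected",
    [
        (-0.5808, NPStatus.NP_PLUS),  # inclusive boundary
        (0.0, NPStatus.NP_MINUS),
        (-10.0, NPStatus.NP_PLUS),
        (-0.58079, NPStatus.NP_MINUS),
    ],
)
def test_classify_inclusive_boundary(z, expected):
    assert classify(z, PUBLISHED_CUTOFF) is expected


def _subject_with_z_pattern(norms, z_by_test):
    """Build a subject whose subtest z's equal the requested values by
    solving each norm equation for the follow-up raw score."""
    baseline = make_battery()
    followup = make_battery()
    from npdecline.norms import predict_followup

    for t, z in z_by_test.items():
        eq = norms[t]
        b = baseline.get(t)
        target_analysis = predict_followup(eq, b) + z * eq.see
        if t in (TestId.TRAILS_A, TestId.TRAILS_B):
            followup.set(t, 10.0 ** (-target_analysis))
        else:
            followup.set(t, target_analysis)
    return make_subject(
        visit_specs=[
            (0.0, Diagnosis.NORMAL, 0.0, baseline),
            (12.0, Diagnosis.NORMAL, 0.0, followup),
            (24.0, Diagnosis.NORMAL, 0.0, make_battery()),
        ]
    )


def test_composite_is_symmetric_mean(norms):
    zs = dict(zip(TestId, [0.5, -0.5, 0.25, -0.25, 1.0, -1.0]))
    subj = _subject_with_z_pattern(norms, zs)
    res = score_subject(subj, norms)
    assert res.n_subtests_used == 6
    assert res.composite_z == pytest.approx(0.0, abs=1e-9)
    assert res.np_status is NPStatus.NP_MINUS
    for t, z in zs.items():
        assert res.subtest_z[t] == pytest.approx(z, abs=1e-9)


def test_composite_equal_subtests_hits_cutoff(norms):
    subj = _subject_with_z_pattern(norms, {t: -0.6 for t in TestId})
    res = score_subject(subj, norms)
    assert res.composite_z == pytest.approx(-0.6, abs=1e-9)
    assert res.np_status is NPStatus.NP_PLUS


def test_missing_subtest_indeterminate_under_default_policy(norms):
    subj = _subject_with_z_pattern(norms, {t: 0.0 for t in TestId})
    subj.visits[1].scores.animals = None
    res = score_subject(subj, norms)
    assert res.np_status is NPStatus.INDETERMINATE
    assert res.composite_z is None
    assert res.n_subtests_used == 5
    assert "5 subtests" in res.reason


def test_relaxed_policy_averages_available_subtests(norms):
    subj = _subject_with_z_pattern(norms, {t: -1.0 for t in TestId})
    subj.visits[1].scores.animals = None
    res = score_subject(subj, norms, ScoringPolicy(min_subtests=4))
    assert res.n_subtests_used == 5
    assert res.composite_z == pytest.approx(-1.0, abs=1e-9)


def test_no_followup_visit_is_indeterminate(norms):
    subj = make_subject(
        visit_specs=[
            (0.0, Diagnosis.NORMAL, 0.0, make_battery()),
            (30.0, Diagnosis.NORMAL, 0.0, make_battery()),
        ]
    )
    res = score_subject(subj, norms)
    assert res.np_status is NPStatus.INDETERMINATE
    assert "window" in res.reason


def test_demented_at_followup_is_indeterminate(norms):
    subj = make_subject(
        visit_specs=[
            (0.0, Diagnosis.MCI, 0.5, make_battery()),
            (12.0, Diagnosis.DEMENTIA, 1.0, make_battery()),
        ]
    )
    res = score_subject(subj, norms)
    assert res.np_status is NPStatus.INDETERMINATE
    assert "demented" in res.reason


def test_followup_window_picks_closest_visit(norms):
    subj = make_subject(
        visit_specs=[
            (0.0, Diagnosis.NORMAL, 0.0, make_battery()),
            (7.0, Diagnosis.NORMAL, 0.0, make_battery(lm1=5.0)),
            (13.0, Diagnosis.NORMAL, 0.0, make_battery(lm1=20.0)),
        ]
    )
    res = score_subject(subj, norms)
    assert res.followup_visit_index == 2


@given(delta=st.floats(min_value=0.01, max_value=5.0))
@settings(deadline=None, derandomize=True)
def test_lower_followup_never_raises_z(norms, delta):
    """Monotonicity: a worse follow-up score (or a longer completion time)
    can only lower the subtest z."""
    eq_lm = norms[TestId.LM_IMMEDIATE]
    base = subtest_z_from_raw(eq_lm, 12.0, 12.0)
    worse = subtest_z_from_raw(eq_lm, 12.0, 12.0 - delta)
    assert worse < base
    eq_ta = norms[TestId.TRAILS_A]
    base_t = subtest_z_from_raw(eq_ta, 40.0, 40.0)
    slower = subtest_z_from_raw(eq_ta, 40.0, 40.0 + delta)
    assert slower < base_t


def test_roc_perfect_separation():
    z = np.array([-2.0, -1.8, -1.5, 0.5, 0.8, 1.0])
    y = np.array([1, 1, 1, 0, 0, 0])
    res = roc_optimal_cutoff(z, y)
    assert res.youden_j == pytest.approx(1.0)
    assert res.auc == pytest.approx(1.0)
    assert -1.5 <= res.cutoff.z_value < 0.5
    assert res.sensitivity == 1.0 and res.specificity == 1.0


def test_roc_null_labels_give_flat_curve(rng):
    z = rng.normal(0, 1, 10000)
    y = rng.random(10000) < 0.3  # independent of z
    res = roc_optimal_cutoff(z, y.astype(int))
    assert abs(res.auc - 0.5) < 0.02
    assert res.youden_j < 0.06


def test_roc_recovers_gaussian_crossing_point(rng):
    """Equal-prior Gaussians N(-1,1) for converters and N(1,1) for
    non-converters cross at 0, the analytic Youden optimum."""
    n = 20000
    z = np.concatenate([rng.normal(-1, 1, n // 2), rng.normal(1, 1, n // 2)])
    y = np.concatenate([np.ones(n // 2, int), np.zeros(n // 2, int)])
    res = roc_optimal_cutoff(z, y)
    assert abs(res.cutoff.z_value - 0.0) < 0.1


def test_roc_single_class_rejected():
    with pytest.raises(ValueError, match="class"):
        roc_optimal_cutoff([-1.0, 0.0, 1.0], [0, 0, 0])


def test_percentile_standard_normal_model():
    pct = percentile_of_cutoff(PUBLISHED_CUTOFF)
    assert pct == pytest.approx(28.07, abs=0.01)
    assert round(pct) == 28


def test_percentile_empirical():
    assert percentile_of_cutoff(CutoffSpec(z_value=0.0), [-1.0, 0.0, 1.0]) == pytest.approx(
        100 * 2 / 3
    )
    assert percentile_of_cutoff(CutoffSpec(z_value=-5.0), [-1.0, 0.0, 1.0]) == 0.0


def test_classify_percentile_coherence(rng):
    """Fraction NP+ equals the empirical percentile of the cutoff exactly:
    both use the inclusive boundary."""
    z = rng.normal(-0.2, 0.8, 5000)
    z[17] = PUBLISHED_CUTOFF.z_value  # force a boundary tie
    frac = np.mean([classify(v) is NPStatus.NP_PLUS for v in z])
    assert frac == percentile_of_cutoff(PUBLISHED_CUTOFF, z) / 100.0
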