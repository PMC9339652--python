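"""NP-decline scoring: per-subtest z-scores, the composite, and cutoffs.

For each test, the subtest z is the discrepancy between the actual
12-month score and the change-norm prediction, standardized by the norm's
standard error of the estimate:

    z = (actual - predicted) / see

Negative z means worse-than-expected follow-up performance. The composite
NP-decline z is the unweighted mean across the six subtests; subjects at or
below the cutoff (published value -0.5808, about the 28th percentile of a
standard-normal composite) are classified NP+, decline present.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _stdnorm

from .model import Diagnosis, Subject, TestId
from .norms import NormEquation, NormTable, predict_followup, to_analysis_scale

log = logging.getLogger(__name__)

#: published ROC-optimal composite cutoff
PUBLISHED_CUTOFF_Z = -0.5808


class NPStatus(Enum):
    NP_PLUS = "NP_PLUS"
    NP_MINUS = "NP_MINUS"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class CutoffSpec:
    z_value: float = PUBLISHED_CUTOFF_Z
    boundary: str = "inclusive"  # NP+ iff z <= z_value
    provenance: str = "published ROC-optimal cutoff"

    def __post_init__(self) -> None:
        if not math.isfinite(self.z_value):
            raise ValueError("cutoff must be finite")


PUBLISHED_CUTOFF = CutoffSpec()


@dataclass
class ScoringPolicy:
    """Tunables for turning a visit series into an NP-decline score."""

    followup_target_months: float = 12.0
    followup_window_months: float = 6.0
    min_subtests: int = 6  # composite requires all six by default
    cutoff: CutoffSpec = field(default_factory=CutoffSpec)


@dataclass
class NPDeclineResult:
    subject_id: str
    subtest_z: dict[TestId, Optional[float]]
    n_subtests_used: int
    composite_z: Optional[float]
    np_status: NPStatus
    cutoff_used: float
    baseline_visit_index: Optional[int] = None
    followup_visit_index: Optional[int] = None
    reason: Optional[str] = None  # populated when INDETERMINATE


def subtest_z(actual: float, predicted: float, see: float) -> float:
    """Standardized discrepancy between actual and predicted follow-up
    scores, both on the analysis scale."""
    if see <= 0:
        raise ValueError(f"standard error of the estimate must be > 0, got {see}")
    return (actual - predicted) / see


def classify(z: float, cutoff: CutoffSpec = PUBLISHED_CUTOFF) -> NPStatus:
    """NP+ iff z at or below the cutoff (inclusive boundary)."""
    if not math.isfinite(z):
        raise ValueError("composite z must be finite")
    return NPStatus.NP_PLUS if z <= cutoff.z_value else NPStatus.NP_MINUS


def subtest_z_from_raw(
    eq: NormEquation, baseline_raw: float, followup_raw: float
) -> float:
    """Subtest z from raw baseline and follow-up scores."""
    actual = to_analysis_scale(eq.test_id, followup_raw)
    predicted = predict_followup(eq, baseline_raw)
    return subtest_z(actual, predicted, eq.see)


def score_subject(
    subject: Subject,
    norms: NormTable,
    policy: Optional[ScoringPolicy] = None,
) -> NPDeclineResult:
    """Score one subject's 12-month NP decline against a norm table.

    Requires a baseline visit and a qualifying follow-up visit inside the
    policy window at which the subject is not demented; otherwise the result
    is INDETERMINATE with the reason recorded.
    """
    policy = policy or ScoringPolicy()
    zmap: dict[TestId, Optional[float]] = {t: None for t in TestId}

    def indeterminate(reason: str, fu_index: Optional[int] = None) -> NPDeclineResult:
        log.info("subject %s indeterminate: %s", subject.subject_id, reason)
        return NPDeclineResult(
            subject_id=subject.subject_id,
            subtest_z=zmap,
            n_subtests_used=0,
            composite_z=None,
            np_status=NPStatus.INDETERMINATE,
            cutoff_used=policy.cutoff.z_value,
            baseline_visit_index=subject.visits[0].visit_index if subject.visits else None,
            followup_visit_index=fu_index,
            reason=reason,
        )

    if not subject.visits:
        return indeterminate("no visits")
    baseline = subject.visits[0]
    followup = subject.followup_visit(
        policy.followup_target_months, policy.followup_window_months
    )
    if followup is None:
        return indeterminate("no follow-up visit inside the 12-month window")
    if followup.diagnosis is Diagnosis.DEMENTIA:
        return indeterminate(
            "demented at the follow-up visit", followup.visit_index
        )

    used = 0
    for test in TestId:
        b = baseline.scores.get(test)
        f = followup.scores.get(test)
        if b is None or f is None:
            continue
        zmap[test] = subtest_z_from_raw(norms[test], b, f)
        used += 1

    if used < policy.min_subtests:
        result = indeterminate(
            f"only {used} subtests available (policy minimum {policy.min_subtests})",
            followup.visit_index,
        )
        result.subtest_z = zmap
        result.n_subtests_used = used
        return result

    composite = float(np.mean([z for z in zmap.values() if z is not None]))
    return NPDeclineResult(
        subject_id=subject.subject_id,
        subtest_z=zmap,
        n_subtests_used=used,
        composite_z=composite,
        np_status=classify(composite, policy.cutoff),
        cutoff_used=policy.cutoff.z_value,
        baseline_visit_index=baseline.visit_index,
        followup_visit_index=followup.visit_index,
    )


def score_cohort(
    cohort, norms: NormTable, policy: Optional[ScoringPolicy] = None
) -> list[NPDeclineResult]:
    policy = policy or ScoringPolicy()
    return [score_subject(s, norms, policy) for s in cohort]


def results_to_frame(results: Sequence[NPDeclineResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "subject_id": r.subject_id,
            "n_subtests_used": r.n_subtests_used,
            "composite_z": r.composite_z,
            "np_status": r.np_status.value,
            "cutoff_used": r.cutoff_used,
            "baseline_visit_index": r.baseline_visit_index,
            "followup_visit_index": r.followup_visit_index,
        }
        for test in TestId:
            row[f"z_{test.value}"] = r.subtest_z.get(test)
        rows.append(row)
    return pd.DataFrame(rows)


# --- cutoff derivation and placement ---------------------------------------

@dataclass
class RocResult:
    cutoff: CutoffSpec
    youden_j: float
    sensitivity: float
    specificity: float
    auc: float
    n_events: int
    n_nonevents: int


def roc_optimal_cutoff(
    composite_z: Sequence[float], converted: Sequence[int]
) -> RocResult:
    """Youden-J-optimal NP-decline cutoff for predicting conversion.

    Candidate thresholds are the observed composite values; a subject tests
    positive when its z is at or below the threshold (decline is the
    low-score direction). Ties in J break toward the more negative
    threshold. AUC treats lower z as higher risk.
    """
    z = np.asarray(composite_z, dtype=float)
    y = np.asarray(converted, dtype=int)
    if z.shape != y.shape or z.ndim != 1:
        raise ValueError("composite_z and converted must be aligned 1-d vectors")
    n_event = int(y.sum())
    n_non = int((1 - y).sum())
    if n_event == 0 or n_non == 0:
        raise ValueError("both converter and non-converter classes required")

    candidates = np.unique(z)  # ascending, so ties resolve to most negative
    best_c, best_j, best_sens, best_spec = math.nan, -math.inf, math.nan, math.nan
    for c in candidates:
        positive = z <= c
        sens = float((positive & (y == 1)).sum()) / n_event
        spec = float((~positive & (y == 0)).sum()) / n_non
        j = sens + spec - 1.0
        if j > best_j:
            best_c, best_j, best_sens, best_spec = float(c), j, sens, spec

    from sklearn.metrics import roc_auc_score

    auc = float(roc_auc_score(y, -z))
    return RocResult(
        cutoff=CutoffSpec(
            z_value=best_c,
            boundary="inclusive",
            provenance=f"ROC Youden-J optimum (n={z.size})",
        ),
        youden_j=best_j,
        sensitivity=best_sens,
        specificity=best_spec,
        auc=auc,
        n_events=n_event,
        n_nonevents=n_non,
    )


def percentile_of_cutoff(
    cutoff: CutoffSpec, reference_z: Optional[Sequence[float]] = None
) -> float:
    """Percentile (0-100) of the cutoff within a reference distribution.

    With an empirical reference vector: 100 x fraction at or below the
    cutoff (inclusive, matching :func:`classify`). Without one, the
    standard-normal model: 100 x Phi(z*).
    """
    if reference_z is None:
        return 100.0 * float(_stdnorm.cdf(cutoff.z_value))
    ref = np.asarray(reference_z, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    return 100.0 * float(np.mean(ref <= cutoff.z_value))
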