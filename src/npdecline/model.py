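"""Canonical domain types for longitudinal neuropsychological cohorts.

A cohort is a collection of subjects, each an ordered series of visits.
Every visit carries the clinical diagnosis, the global CDR stage, and the
six-test battery (Logical Memory I/II, Trail Making A/B, Animals,
Vegetables) that the change-norm analysis consumes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional


class Diagnosis(Enum):
    NORMAL = "NORMAL"
    IMPAIRED_NOT_MCI = "IMPAIRED_NOT_MCI"
    MCI = "MCI"
    DEMENTIA = "DEMENTIA"


class Sex(Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"  # accepted on read, excluded from covariate models


class TestId(Enum):
    LM_IMMEDIATE = "lm_immediate"
    LM_DELAYED = "lm_delayed"
    TRAILS_A = "trails_a_seconds"
    TRAILS_B = "trails_b_seconds"
    ANIMALS = "animals"
    VEGETABLES = "vegetables"


#: raw-score validity bounds per test: (low, high, low_exclusive)
SCORE_BOUNDS: dict[TestId, tuple[float, float, bool]] = {
    TestId.LM_IMMEDIATE: (0.0, 25.0, False),
    TestId.LM_DELAYED: (0.0, 25.0, False),
    TestId.TRAILS_A: (0.0, 150.0, True),   # seconds, strictly positive
    TestId.TRAILS_B: (0.0, 300.0, True),
    TestId.ANIMALS: (0.0, math.inf, False),
    TestId.VEGETABLES: (0.0, math.inf, False),
}

#: tests where the raw score is a completion time (lower raw = better)
TIMED_TESTS = frozenset({TestId.TRAILS_A, TestId.TRAILS_B})

VALID_CDR = (0.0, 0.5, 1.0, 2.0, 3.0)


class ValidationError(ValueError):
    """Raised when a cohort table violates the documented schema."""


def check_score(test: TestId, value: float) -> None:
    """Raise ValidationError if ``value`` is outside the test's raw bounds."""
    low, high, low_excl = SCORE_BOUNDS[test]
    ok = (value > low if low_excl else value >= low) and value <= high
    if not ok:
        raise ValidationError(
            f"{test.value}={value!r} outside valid range "
            f"{'(' if low_excl else '['}{low}, {high}]"
        )


@dataclass
class TestBattery:
    """Raw scores from one testing occasion; ``None`` marks a missing score."""

    lm_immediate: Optional[float] = None
    lm_delayed: Optional[float] = None
    trails_a_seconds: Optional[float] = None
    trails_b_seconds: Optional[float] = None
    animals: Optional[float] = None
    vegetables: Optional[float] = None

    def get(self, test: TestId) -> Optional[float]:
        return getattr(self, test.value)

    def set(self, test: TestId, value: Optional[float]) -> None:
        setattr(self, test.value, value)

    def validate(self) -> None:
        for test in TestId:
            v = self.get(test)
            if v is not None:
                check_score(test, v)

    def complete(self) -> bool:
        return all(self.get(t) is not None for t in TestId)


@dataclass
class Visit:
    subject_id: str
    visit_index: int
    months_since_baseline: float
    age_years: float
    diagnosis: Diagnosis
    cdr_global: Optional[float] = None
    scores: TestBattery = field(default_factory=TestBattery)

    def validate(self) -> None:
        if self.visit_index < 0:
            raise ValidationError(f"visit_index {self.visit_index} < 0")
        if self.visit_index == 0 and self.months_since_baseline != 0:
            raise ValidationError(
                f"subject {self.subject_id}: baseline visit must have "
                f"months_since_baseline=0, got {self.months_since_baseline}"
            )
        if self.months_since_baseline < 0:
            raise ValidationError("months_since_baseline < 0")
        if self.cdr_global is not None and self.cdr_global not in VALID_CDR:
            raise ValidationError(
                f"cdr_global {self.cdr_global} not in {VALID_CDR}"
            )
        self.scores.validate()


@dataclass
class Subject:
    subject_id: str
    sex: Sex
    education_years: float
    visits: list[Visit] = field(default_factory=list)

    @property
    def baseline(self) -> Visit:
        return self.visits[0]

    def visit_at_index(self, idx: int) -> Optional[Visit]:
        for v in self.visits:
            if v.visit_index == idx:
                return v
        return None

    def followup_visit(
        self, target_months: float = 12.0, window_months: float = 6.0
    ) -> Optional[Visit]:
        """The non-baseline visit closest to ``target_months``, within
        ``±window_months``; ``None`` when no visit qualifies."""
        best, best_dist = None, window_months
        for v in self.visits[1:]:
            dist = abs(v.months_since_baseline - target_months)
            if dist <= best_dist:
                best, best_dist = v, dist
        return best

    def validate(self) -> None:
        if not self.visits:
            raise ValidationError(f"subject {self.subject_id} has no visits")
        if not 0 <= self.education_years <= 30:
            raise ValidationError(
                f"education_years {self.education_years} outside [0, 30]"
            )
        prev_m, prev_a, prev_i = -math.inf, -math.inf, -1
        for v in self.visits:
            v.validate()
            if v.subject_id != self.subject_id:
                raise ValidationError("visit subject_id mismatch")
            if v.visit_index <= prev_i:
                raise ValidationError(
                    f"subject {self.subject_id}: visit_index not increasing"
                )
            if v.months_since_baseline <= prev_m:
                raise ValidationError(
                    f"subject {self.subject_id}: months_since_baseline not "
                    f"strictly increasing at visit {v.visit_index}"
                )
            if v.age_years < prev_a:
                raise ValidationError(
                    f"subject {self.subject_id}: age_years decreasing at "
                    f"visit {v.visit_index}"
                )
            prev_m, prev_a, prev_i = (
                v.months_since_baseline, v.age_years, v.visit_index,
            )


@dataclass
class Cohort:
    subjects: list[Subject] = field(default_factory=list)
    provenance: str = ""
    schema_version: str = "1"

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def validate(self) -> None:
        seen: set[str] = set()
        for s in self.subjects:
            if s.subject_id in seen:
                raise ValidationError(f"duplicate subject_id {s.subject_id}")
            seen.add(s.subject_id)
            s.validate()
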