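"""Regression-based 12-month change norms.

Each test gets a linear equation mapping baseline performance to expected
12-month performance in a healthy reference sample, absorbing practice
effects and regression to the mean:

    predicted = intercept + slope * baseline        (analysis scale)

Timed tests (Trail Making A and B, recorded in seconds) are analyzed on a
transformed scale, -log10(seconds), so that scores are approximately normal
and higher always means better; their published equations carry a trailing
sign flip which is algebraically identical to regressing on the inverted
scale with a negated intercept. The standard error of the estimate (the
residual standard deviation, ``see``) standardizes the discrepancy between
the actual and predicted follow-up score into a z-score downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .model import TIMED_TESTS, TestId


class FittingError(ValueError):
    """Raised when a norm regression cannot be estimated."""


class TransformKind(Enum):
    IDENTITY = "IDENTITY"
    NEG_LOG10_SECONDS = "NEG_LOG10_SECONDS"


@dataclass(frozen=True)
class TransformSpec:
    kind: TransformKind

    def apply(self, raw: float) -> float:
        if self.kind is TransformKind.IDENTITY:
            return raw
        if raw <= 0:
            raise ValueError(f"non-positive time {raw} has no log transform")
        return -math.log10(raw)

    def invert(self, analysis: float) -> float:
        if self.kind is TransformKind.IDENTITY:
            return analysis
        return 10.0 ** (-analysis)


IDENTITY = TransformSpec(TransformKind.IDENTITY)
NEG_LOG10 = TransformSpec(TransformKind.NEG_LOG10_SECONDS)


def transform_for(test: TestId) -> TransformSpec:
    return NEG_LOG10 if test in TIMED_TESTS else IDENTITY


def to_analysis_scale(test: TestId, raw: float) -> float:
    """Map a raw score onto the higher-is-better analysis scale.

    Untimed tests pass through unchanged; timed tests become
    ``-log10(seconds)`` so a slower completion is a lower score.
    """
    return transform_for(test).apply(raw)


@dataclass(frozen=True)
class NormEquation:
    """One test's change norm: follow-up ~ intercept + slope * baseline."""

    test_id: TestId
    intercept: float
    slope: float
    see: float  # standard error of the estimate, analysis-scale units
    transform: TransformSpec
    n_fit: Optional[int] = None  # None for published constants

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if not self.see > 0:
            raise ValueError(f"see must be > 0, got {self.see}")


@dataclass
class NormTable:
    equations: dict[TestId, NormEquation]
    label: str = ""
    version: str = "1"

    def __post_init__(self) -> None:
        if set(self.equations) != set(TestId):
            missing = set(TestId) - set(self.equations)
            raise ValueError(f"norm table missing equations for {missing}")

    def __getitem__(self, test: TestId) -> NormEquation:
        return self.equations[test]


# Published reference-sample constants: intercept, slope, S_y.x per test.
# Fitted in a robustly normal reference cohort (n = 294); timed tests are on
# the -log10(seconds) scale.
_PUBLISHED = {
    TestId.LM_IMMEDIATE: (6.883, 0.595, 2.7730),
    TestId.LM_DELAYED: (4.810, 0.680, 3.1780),
    TestId.TRAILS_A: (0.589, 0.598, 0.1009),
    TestId.TRAILS_B: (0.656, 0.643, 0.1374),
    TestId.ANIMALS: (8.410, 0.623, 4.0650),
    TestId.VEGETABLES: (4.464, 0.687, 3.2700),
}


def published_norms() -> NormTable:
    """The published change-norm constants, verbatim."""
    eqs = {
        test: NormEquation(
            test_id=test,
            intercept=a,
            slope=b,
            see=s,
            transform=transform_for(test),
        )
        for test, (a, b, s) in _PUBLISHED.items()
    }
    return NormTable(equations=eqs, label="ADNI-robust-normal (published)")


def fit_norm(
    test_id: TestId,
    baseline: Sequence[float],
    followup: Sequence[float],
) -> NormEquation:
    """Ordinary least squares of 12-month score on baseline score.

    Both vectors must already be on the analysis scale and aligned; pairs
    with a missing value must be dropped by the caller (complete-case
    fitting). ``see = sqrt(RSS / (n - 2))``.

    For timed tests the intercept is stored in the same parameterization as
    the published equations — the positive-log regression with a trailing
    sign flip, ``predicted = -(intercept + slope * log10(seconds))`` — which
    is the analysis-scale fit with its intercept negated (the slope and the
    residuals are identical in the two parameterizations).
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(followup, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FittingError("baseline and followup must be aligned 1-d vectors")
    if np.isnan(x).any() or np.isnan(y).any():
        raise FittingError("complete cases only: NaN present")
    n = x.size
    if n < 3:
        raise FittingError(f"need at least 3 complete pairs, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise FittingError("zero baseline variance")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    rss = float(np.sum((y - intercept - slope * x) ** 2))
    see = math.sqrt(rss / (n - 2))
    if see == 0.0:
        # perfectly collinear data: keep the fit but flag the degenerate see
        raise FittingError(
            f"degenerate fit for {test_id.value}: zero residual variance "
            f"(intercept={intercept:.6g}, slope={slope:.6g})"
        )
    transform = transform_for(test_id)
    if transform.kind is TransformKind.NEG_LOG10_SECONDS:
        intercept = -intercept
    return NormEquation(
        test_id=test_id,
        intercept=intercept,
        slope=slope,
        see=see,
        transform=transform,
        n_fit=n,
    )


def predict_followup(eq: NormEquation, baseline_raw: float) -> float:
    """Predicted 12-month score on the analysis scale from a raw baseline.

    Untimed tests: ``intercept + slope * baseline_raw``. Timed tests:
    ``-(intercept + slope * log10(seconds))``, identical to applying the
    regression on the inverted scale with a negated intercept.
    """
    if eq.transform.kind is TransformKind.IDENTITY:
        return eq.intercept + eq.slope * baseline_raw
    if baseline_raw <= 0:
        raise ValueError(f"non-positive time {baseline_raw}")
    return -(eq.intercept + eq.slope * math.log10(baseline_raw))


def fit_norm_table(
    cohort,
    baseline_visit: int = 0,
    followup_target_months: float = 12.0,
    followup_window_months: float = 6.0,
    label: str = "",
) -> NormTable:
    """Fit all six change norms on a reference cohort (complete cases)."""
    equations: dict[TestId, NormEquation] = {}
    for test in TestId:
        baseline, followup = [], []
        for subject in cohort:
            b_visit = subject.visit_at_index(baseline_visit)
            f_visit = subject.followup_visit(
                followup_target_months, followup_window_months
            )
            if b_visit is None or f_visit is None:
                continue
            b, f = b_visit.scores.get(test), f_visit.scores.get(test)
            if b is None or f is None:
                continue
            baseline.append(to_analysis_scale(test, b))
            followup.append(to_analysis_scale(test, f))
        equations[test] = fit_norm(test, baseline, followup)
    return NormTable(equations=equations, label=label or "locally fitted")


# --- plain-text serialization (versioned key-value format) -----------------

def write_norm_table(table: NormTable, path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = [
        "# npdecline norm table",
        f"version: {table.version}",
        f"label: {table.label}",
    ]
    for test in TestId:
        eq = table[test]
        nfit = "" if eq.n_fit is None else str(eq.n_fit)
        lines.append(
            f"{test.value}: intercept={eq.intercept!r} slope={eq.slope!r} "
            f"see={eq.see!r} transform={eq.transform.kind.value} n_fit={nfit}"
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_norm_table(path: Union[str, Path]) -> NormTable:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    version, label = "1", ""
    eqs: dict[TestId, NormEquation] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, rest = line.partition(":")
        key, rest = key.strip(), rest.strip()
        if key == "version":
            version = rest
        elif key == "label":
            label = rest
        else:
            test = TestId(key)
            fields = dict(tok.split("=", 1) for tok in rest.split())
            eqs[test] = NormEquation(
                test_id=test,
                intercept=float(fields["intercept"]),
                slope=float(fields["slope"]),
                see=float(fields["see"]),
                transform=TransformSpec(TransformKind(fields["transform"])),
                n_fit=int(fields["n_fit"]) if fields.get("n_fit") else None,
            )
    return NormTable(equations=eqs, label=label, version=version)
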