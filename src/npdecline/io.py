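"""Cohort table reader/writer and configuration loading.

The on-disk format is one comma-separated UTF-8 row per visit, in NACC-like
long format, with the exact column order below and empty cells for missing
values. Reals are written with ``repr`` so a write/read cycle is exact.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .model import (
    Cohort,
    Diagnosis,
    Sex,
    Subject,
    TestBattery,
    TestId,
    ValidationError,
    Visit,
    check_score,
)

log = logging.getLogger(__name__)

COLUMNS = [
    "subject_id",
    "visit_index",
    "months_since_baseline",
    "age_years",
    "sex",
    "education_years",
    "diagnosis",
    "cdr_global",
    "lm_immediate",
    "lm_delayed",
    "trails_a_seconds",
    "trails_b_seconds",
    "animals",
    "vegetables",
]

_SCORE_COLUMNS = [t.value for t in TestId]


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
        return repr(value)
    return repr(value) if isinstance(value, float) else str(value)


def read_cohort(path: Union[str, Path], strict: bool = True) -> Cohort:
    """Read a visit-per-row cohort table.

    In strict mode any malformed cell raises :class:`ValidationError` naming
    the row and field; otherwise out-of-bounds scores are logged and demoted
    to missing. Rows are grouped by ``subject_id`` and sorted by
    ``visit_index`` within subject.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != COLUMNS:
        unknown = [c for c in df.columns if c not in COLUMNS]
        missing = [c for c in COLUMNS if c not in df.columns]
        raise ValidationError(
            f"header mismatch in {path.name}: unknown columns {unknown}, "
            f"missing columns {missing}"
        )

    subjects: dict[str, Subject] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.subject_id
        try:
            sex = Sex(row.sex)
            diagnosis = Diagnosis(row.diagnosis)
        except ValueError as exc:
            raise ValidationError(f"row {row_no}: {exc}") from exc
        battery = TestBattery()
        for test in TestId:
            raw = getattr(row, test.value)
            if raw == "":
                continue
            try:
                value = float(raw)
                check_score(test, value)
            except ValidationError as exc:
                if strict:
                    raise ValidationError(f"row {row_no}: {exc}") from exc
                log.warning("row %d: %s -> treated as missing", row_no, exc)
                continue
            except ValueError as exc:
                raise ValidationError(
                    f"row {row_no}: unparseable {test.value}={raw!r}"
                ) from exc
            battery.set(test, value)
        try:
            visit = Visit(
                subject_id=sid,
                visit_index=int(row.visit_index),
                months_since_baseline=float(row.months_since_baseline),
                age_years=float(row.age_years),
                diagnosis=diagnosis,
                cdr_global=float(row.cdr_global) if row.cdr_global != "" else None,
                scores=battery,
            )
        except ValueError as exc:
            raise ValidationError(f"row {row_no}: {exc}") from exc
        if sid not in subjects:
            subjects[sid] = Subject(
                subject_id=sid,
                sex=sex,
                education_years=float(row.education_years),
                visits=[],
            )
        subjects[sid].visits.append(visit)

    for subj in subjects.values():
        subj.visits.sort(key=lambda v: v.visit_index)
    cohort = Cohort(subjects=list(subjects.values()), provenance=str(path))
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> Path:
    """Write ``cohort`` so that :func:`read_cohort` reproduces it exactly."""
    path = Path(path)
    rows = []
    for subj in cohort:
        for v in subj.visits:
            row = {
                "subject_id": subj.subject_id,
                "visit_index": str(v.visit_index),
                "months_since_baseline": _cell(float(v.months_since_baseline)),
                "age_years": _cell(float(v.age_years)),
                "sex": subj.sex.value,
                "education_years": _cell(float(subj.education_years)),
                "diagnosis": v.diagnosis.value,
                "cdr_global": _cell(v.cdr_global),
            }
            for test in TestId:
                val = v.scores.get(test)
                row[test.value] = _cell(float(val)) if val is not None else ""
            rows.append(row)
    df = pd.DataFrame(rows, columns=COLUMNS)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML (or JSON, a YAML subset) key-value configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} is not a key-value mapping")
    return cfg
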