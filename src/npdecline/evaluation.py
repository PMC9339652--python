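"""Prognostic evaluation of NP decline against dementia conversion.

Applies the cohort eligibility rules, builds survival records with the
12-month exam as time origin, and evaluates NP decline as a predictor of
all-cause dementia: stratified conversion contrasts (chi-squared),
factorial ANCOVA on the composite z, Cox proportional-hazards models
controlling for age, sex and education, and Kaplan-Meier-style cumulative
progression curves. A CDR-based outcome (progression from global CDR 0 to
0.5 or higher) is available as a sensitivity analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Cohort, Diagnosis, Sex, Subject
from .scoring import NPDeclineResult, NPStatus

log = logging.getLogger(__name__)

EXCLUSION_RULES = (
    "age",
    "baseline_diagnosis",
    "exam_count",
    "followup_duration",
    "dementia_by_12m",
)


class EvaluationError(ValueError):
    """Raised for structured fitting failures."""


@dataclass
class EligibilityConfig:
    min_age_years: float = 60.0
    min_exams: int = 3
    min_total_followup_months: float = 12.0  # strictly more than this required
    require_nondemented_at_followup: bool = True
    followup_target_months: float = 12.0
    followup_window_months: float = 6.0


def _first_failing_rule(subject: Subject, cfg: EligibilityConfig) -> Optional[str]:
    baseline = subject.visits[0]
    if baseline.age_years < cfg.min_age_years:
        return "age"
    if baseline.diagnosis is Diagnosis.DEMENTIA:
        return "baseline_diagnosis"
    if len(subject.visits) < cfg.min_exams:
        return "exam_count"
    if subject.visits[-1].months_since_baseline <= cfg.min_total_followup_months:
        return "followup_duration"
    demented_early = any(
        v.diagnosis is Diagnosis.DEMENTIA
        and v.months_since_baseline <= cfg.followup_target_months
        for v in subject.visits
    )
    fu = subject.followup_visit(
        cfg.followup_target_months, cfg.followup_window_months
    )
    demented_at_fu = (
        cfg.require_nondemented_at_followup
        and fu is not None
        and fu.diagnosis is Diagnosis.DEMENTIA
    )
    if demented_early or demented_at_fu:
        return "dementia_by_12m"
    return None


def apply_eligibility(
    cohort: Cohort, cfg: Optional[EligibilityConfig] = None
) -> tuple[Cohort, dict[str, int]]:
    """Retain subjects meeting every inclusion rule.

    The exclusion ledger counts subjects by the *first* failing rule, in
    fixed order: age, baseline diagnosis, exam count, follow-up duration,
    dementia by 12 months. Excluded + eligible always equals the input
    count.
    """
    cfg = cfg or EligibilityConfig()
    ledger = {rule: 0 for rule in EXCLUSION_RULES}
    kept = []
    for subject in cohort:
        rule = _first_failing_rule(subject, cfg)
        if rule is None:
            kept.append(subject)
        else:
            ledger[rule] += 1
    ledger["eligible"] = len(kept)
    ledger["total"] = len(cohort)
    eligible = Cohort(
        subjects=kept,
        provenance=f"{cohort.provenance} [eligible]",
        schema_version=cohort.schema_version,
    )
    return eligible, ledger


@dataclass
class SurvivalRecord:
    subject_id: str
    time_months: float  # from the 12-month exam
    event: bool  # dementia (or CDR >= 0.5 under the sensitivity outcome)
    age_years: float  # at the time origin
    sex: Sex
    education_years: float
    np_decline_z: float
    np_status: NPStatus
    diagnosis_12m: Diagnosis


def build_survival_records(
    cohort: Cohort,
    scores: Sequence[NPDeclineResult],
    cfg: Optional[EligibilityConfig] = None,
) -> list[SurvivalRecord]:
    """Survival records with the 12-month exam as time origin.

    Event time is months from the origin to the first visit with a dementia
    diagnosis; censoring time is months to the last dementia-free visit.
    INDETERMINATE-scored subjects and subjects with no follow-up beyond the
    origin are dropped with a logged count.
    """
    cfg = cfg or EligibilityConfig()
    by_id = {s.subject_id: s for s in cohort}
    records = []
    n_indeterminate = n_no_followup = 0
    for res in scores:
        if res.np_status is NPStatus.INDETERMINATE or res.composite_z is None:
            n_indeterminate += 1
            continue
        subject = by_id.get(res.subject_id)
        if subject is None:
            continue
        fu = subject.followup_visit(
            cfg.followup_target_months, cfg.followup_window_months
        )
        if fu is None:
            n_indeterminate += 1
            continue
        origin = fu.months_since_baseline
        onset = next(
            (
                v.months_since_baseline
                for v in subject.visits
                if v.diagnosis is Diagnosis.DEMENTIA
            ),
            None,
        )
        if onset is not None:
            time, event = onset - origin, True
        else:
            last_free = max(
                v.months_since_baseline
                for v in subject.visits
                if v.diagnosis is not Diagnosis.DEMENTIA
            )
            time, event = last_free - origin, False
        if time <= 0:
            n_no_followup += 1
            continue
        records.append(
            SurvivalRecord(
                subject_id=subject.subject_id,
                time_months=float(time),
                event=event,
                age_years=float(fu.age_years),
                sex=subject.sex,
                education_years=float(subject.education_years),
                np_decline_z=float(res.composite_z),
                np_status=res.np_status,
                diagnosis_12m=fu.diagnosis,
            )
        )
    if n_indeterminate:
        log.info("dropped %d indeterminate-scored subjects", n_indeterminate)
    if n_no_followup:
        log.info("dropped %d subjects with no follow-up past the origin", n_no_followup)
    return records


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "time_months": [r.time_months for r in records],
            "event": [int(r.event) for r in records],
            "age_years": [r.age_years for r in records],
            "sex": [r.sex.value for r in records],
            "sex_male": [int(r.sex is Sex.MALE) for r in records],
            "education_years": [r.education_years for r in records],
            "np_decline_z": [r.np_decline_z for r in records],
            "np_status": [r.np_status.value for r in records],
            "diagnosis_12m": [r.diagnosis_12m.value for r in records],
        }
    )


# --- conversion contrasts ---------------------------------------------------

def chi2_2x2(table: np.ndarray, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction by
    default (large-sample usage)."""
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), int(dof), float(p)


@dataclass
class GroupStats:
    cells: pd.DataFrame  # one row per diagnosis x NP status
    contrasts: pd.DataFrame  # per-diagnosis 2x2 chi-squared


def conversion_table(records: Sequence[SurvivalRecord]) -> GroupStats:
    """Six-cell conversion summary (3 diagnoses x NP+/-) with per-diagnosis
    chi-squared contrasts (1 df, no continuity correction)."""
    if not records:
        raise EvaluationError("no survival records")
    df = records_to_frame(records)
    cells = []
    contrasts = []
    for diag in (Diagnosis.NORMAL, Diagnosis.IMPAIRED_NOT_MCI, Diagnosis.MCI):
        sub = df[df.diagnosis_12m == diag.value]
        table = np.zeros((2, 2))
        for i, status in enumerate((NPStatus.NP_PLUS, NPStatus.NP_MINUS)):
            grp = sub[sub.np_status == status.value]
            n, conv = len(grp), int(grp.event.sum())
            table[i] = [conv, n - conv]
            cells.append(
                {
                    "diagnosis_12m": diag.value,
                    "np_status": status.value,
                    "n": n,
                    "converters": conv,
                    "conversion_proportion": conv / n if n else np.nan,
                }
            )
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            log.warning("empty margin for %s: chi-squared undefined", diag.value)
            chi2, dof, p = np.nan, 1, np.nan
        else:
            chi2, dof, p = chi2_2x2(table)
        contrasts.append(
            {
                "diagnosis_12m": diag.value,
                "chi2": chi2,
                "df": dof,
                "p_value": p,
                "n": int(sub.shape[0]),
            }
        )
    return GroupStats(cells=pd.DataFrame(cells), contrasts=pd.DataFrame(contrasts))


# --- Cox proportional hazards ----------------------------------------------

@dataclass
class CoxResult:
    predictor: str  # "continuous_z" or "np_status"
    hazard_ratio: float  # per unit of decline (z negated on entry)
    ci_low: float
    ci_high: float
    coef: float  # log hazard ratio on the decline scale
    se_coef: float
    chi_square: float  # LR statistic vs covariates-only null, 1 df
    minus2_loglik: float
    p_value: float
    n: int
    n_events: int
    covariate_estimates: dict[str, float] = field(default_factory=dict)


def fit_cox(
    records: Sequence[SurvivalRecord],
    predictor: str = "continuous_z",
    stratum: Optional[Diagnosis] = None,
    adjust_covariates: bool = True,
) -> CoxResult:
    """Cox model of time to dementia on NP decline.

    ``predictor="continuous_z"`` enters the negated composite z (one unit =
    one standard-error-of-estimate of 12-month decline), so a hazard ratio
    above 1 means decline is harmful; ``predictor="np_status"`` enters the
    binary NP+ indicator. Efron tie handling; age, sex, and years of
    education are adjusted for unless disabled. The likelihood-ratio
    chi-square contrasts the full model with the covariates-only null.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = records_to_frame(records)
    if stratum is not None:
        df = df[df.diagnosis_12m == stratum.value]
    n_unknown = int((df.sex == Sex.UNKNOWN.value).sum())
    if n_unknown:
        log.info("excluding %d subjects with unknown sex from Cox model", n_unknown)
        df = df[df.sex != Sex.UNKNOWN.value]
    if predictor == "continuous_z":
        df = df.assign(decline=-df.np_decline_z)
    elif predictor == "np_status":
        df = df.assign(decline=(df.np_status == NPStatus.NP_PLUS.value).astype(int))
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    n_events = int(df.event.sum())
    if n_events < 2:
        raise EvaluationError(
            f"need at least 2 events, got {n_events} "
            f"(stratum={stratum.value if stratum else 'all'})"
        )
    covars = ["age_years", "sex_male", "education_years"] if adjust_covariates else []
    cols = ["time_months", "event", "decline", *covars]

    def _fit(columns):
        cph = CoxPHFitter()
        cph.fit(df[columns], duration_col="time_months", event_col="event")
        return cph

    try:
        full = _fit(cols)
        if covars:
            null = _fit(["time_months", "event", *covars])
            null_llf = null.log_likelihood_
        else:
            # covariate-free null: partial likelihood of the empty model
            null_llf = full.log_likelihood_ - full.log_likelihood_ratio_test().test_statistic / 2.0
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise EvaluationError(f"Cox fit failed: {exc}") from exc

    coef = float(full.params_["decline"])
    se = float(full.standard_errors_["decline"])
    chi2 = 2.0 * (full.log_likelihood_ - null_llf)
    p = float(stats.chi2.sf(chi2, df=1))
    return CoxResult(
        predictor=predictor,
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        coef=coef,
        se_coef=se,
        chi_square=float(chi2),
        minus2_loglik=float(-2.0 * full.log_likelihood_),
        p_value=p,
        n=int(df.shape[0]),
        n_events=n_events,
        covariate_estimates={c: float(full.params_[c]) for c in covars},
    )


# --- factorial ANCOVA -------------------------------------------------------

@dataclass
class AncovaResult:
    anova: pd.DataFrame  # F tests for factors, interaction, covariates
    adjusted_means: pd.DataFrame  # covariate-at-mean cell means
    pairwise: pd.DataFrame  # Bonferroni-adjusted cell contrasts


def ancova_factorial(
    records: Sequence[SurvivalRecord],
    outcome_factor: str = "event",
    adjust_covariates: bool = True,
) -> AncovaResult:
    """Factorial ANCOVA of the composite z on diagnosis x dementia outcome.

    Models composite z on the two factors, their interaction, and the
    age/sex/education covariates; reports covariate-at-mean adjusted cell
    means and all pairwise cell contrasts with Bonferroni-adjusted p-values.
    ``outcome_factor="np_status"`` swaps in the alternative factor pair
    (diagnosis x NP status).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records_to_frame(records)
    df = df[df.sex != Sex.UNKNOWN.value].copy()
    if outcome_factor == "event":
        df["outcome"] = np.where(df.event == 1, "DEMENTIA", "NO_DEMENTIA")
    elif outcome_factor == "np_status":
        df["outcome"] = df.np_status
    else:
        raise ValueError(f"unknown outcome_factor {outcome_factor!r}")
    df["diagnosis"] = df.diagnosis_12m

    cell_counts = df.groupby(["diagnosis", "outcome"]).size()
    if (cell_counts > 0).sum() < 2:
        raise EvaluationError("need at least 2 nonempty cells")

    covars = "+ age_years + sex_male + education_years" if adjust_covariates else ""
    formula = f"np_decline_z ~ C(diagnosis) * C(outcome) {covars}"
    try:
        fit = smf.ols(formula, data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
    except np.linalg.LinAlgError as exc:
        raise EvaluationError(f"rank-deficient ANCOVA design: {exc}") from exc

    # adjusted means: predict each observed cell at the grand covariate means
    pred_rows = []
    for (diag, out), _n in cell_counts.items():
        if _n == 0:
            continue
        pred_rows.append(
            {
                "diagnosis": diag,
                "outcome": out,
                "age_years": df.age_years.mean(),
                "sex_male": df.sex_male.mean(),
                "education_years": df.education_years.mean(),
            }
        )
    grid = pd.DataFrame(pred_rows)
    pred = fit.get_prediction(grid)
    adjusted = grid[["diagnosis", "outcome"]].copy()
    adjusted["adjusted_mean"] = pred.predicted_mean
    adjusted["se"] = pred.se_mean
    adjusted["n"] = [cell_counts[(r.diagnosis, r.outcome)] for r in adjusted.itertuples()]

    # pairwise cell contrasts via linear combinations of the design
    from patsy import dmatrix

    design_info = fit.model.data.design_info
    design_rows = {}
    for row in grid.itertuples(index=False):
        d = pd.DataFrame([row._asdict()])
        design_rows[(row.diagnosis, row.outcome)] = np.asarray(
            dmatrix(design_info, d, return_type="dataframe")
        )[0]
    keys = list(design_rows)
    pair_rows = []
    n_pairs = len(keys) * (len(keys) - 1) // 2
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            contrast = design_rows[keys[i]] - design_rows[keys[j]]
            tt = fit.t_test(contrast)
            p_raw = float(tt.pvalue)
            pair_rows.append(
                {
                    "cell_a": "/".join(keys[i]),
                    "cell_b": "/".join(keys[j]),
                    "difference": float(np.ravel(tt.effect)[0]),
                    "t": float(np.ravel(tt.tvalue)[0]),
                    "p_raw": p_raw,
                    "p_bonferroni": min(1.0, p_raw * n_pairs),
                }
            )
    return AncovaResult(
        anova=anova,
        adjusted_means=adjusted,
        pairwise=pd.DataFrame(pair_rows),
    )


# --- stratified progression curves ------------------------------------------

def progression_curves(
    records: Sequence[SurvivalRecord], grid_interval_months: float = 12.0
) -> pd.DataFrame:
    """Kaplan-Meier-style cumulative progression per diagnosis x NP group.

    Returns a long table with one row per group and 12-month grid point:
    cumulative incidence (1 - S(t)), the number still at risk, and events in
    the preceding interval.
    """
    from lifelines import KaplanMeierFitter

    if not records:
        raise EvaluationError("no survival records")
    df = records_to_frame(records)
    max_t = df.time_months.max()
    grid = np.arange(0.0, max_t + grid_interval_months, grid_interval_months)
    rows = []
    for (diag, status), grp in df.groupby(["diagnosis_12m", "np_status"]):
        km = KaplanMeierFitter()
        km.fit(grp.time_months, grp.event)
        surv = km.survival_function_at_times(grid).to_numpy()
        prev_events = 0
        for t, s in zip(grid, surv):
            at_risk = int((grp.time_months >= t).sum())
            events_so_far = int(((grp.time_months <= t) & (grp.event == 1)).sum())
            rows.append(
                {
                    "diagnosis_12m": diag,
                    "np_status": status,
                    "time_months": float(t),
                    "cumulative_progression": float(1.0 - s),
                    "n_at_risk": at_risk,
                    "events_interval": events_so_far - prev_events,
                    "events_cumulative": events_so_far,
                }
            )
            prev_events = events_so_far
    return pd.DataFrame(rows)


# --- CDR-based sensitivity outcome ------------------------------------------

def cdr_outcome(
    cohort: Cohort,
    scores: Sequence[NPDeclineResult],
    cfg: Optional[EligibilityConfig] = None,
) -> list[SurvivalRecord]:
    """Rebuild survival records with CDR progression as the outcome.

    Event = first visit with global CDR >= 0.5, among subjects with CDR 0 at
    the 12-month exam; subjects already at CDR >= 0.5 there are excluded,
    and subjects missing CDR are dropped with a logged count. All downstream
    operations run unchanged on the returned records.
    """
    cfg = cfg or EligibilityConfig()
    by_id = {s.subject_id: s for s in cohort}
    records = []
    n_missing = n_not_zero = n_dropped = 0
    for res in scores:
        if res.np_status is NPStatus.INDETERMINATE or res.composite_z is None:
            n_dropped += 1
            continue
        subject = by_id.get(res.subject_id)
        if subject is None:
            continue
        fu = subject.followup_visit(
            cfg.followup_target_months, cfg.followup_window_months
        )
        if fu is None:
            n_dropped += 1
            continue
        if fu.cdr_global is None or any(
            v.cdr_global is None for v in subject.visits
        ):
            n_missing += 1
            continue
        if fu.cdr_global >= 0.5:
            n_not_zero += 1
            continue
        origin = fu.months_since_baseline
        onset = next(
            (
                v.months_since_baseline
                for v in subject.visits
                if v.months_since_baseline > origin and v.cdr_global >= 0.5
            ),
            None,
        )
        if onset is not None:
            time, event = onset - origin, True
        else:
            last = max(v.months_since_baseline for v in subject.visits)
            time, event = last - origin, False
        if time <= 0:
            n_dropped += 1
            continue
        records.append(
            SurvivalRecord(
                subject_id=subject.subject_id,
                time_months=float(time),
                event=event,
                age_years=float(fu.age_years),
                sex=subject.sex,
                education_years=float(subject.education_years),
                np_decline_z=float(res.composite_z),
                np_status=res.np_status,
                diagnosis_12m=fu.diagnosis,
            )
        )
    if n_missing:
        log.info("CDR outcome: dropped %d subjects with missing CDR", n_missing)
    if n_not_zero:
        log.info("CDR outcome: excluded %d subjects with CDR >= 0.5 at the 12-month exam", n_not_zero)
    if n_dropped:
        log.info("CDR outcome: dropped %d unscoreable subjects", n_dropped)
    return records
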