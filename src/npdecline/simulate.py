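"""Synthetic longitudinal cohorts with the structure the analysis assumes.

Two generators are provided. ``generate_reference_cohort`` emulates a
robustly normal reference sample: subjects stay cognitively normal, attend a
baseline and a ~12-month retest, and their follow-up scores follow a linear
baseline->follow-up relation with practice effects and regression to the
mean. ``generate_study_cohort`` emulates a heterogeneous study cohort with
three diagnostic strata, a latent decline process shared across the six
tests, dementia onset from a proportional-hazards model linked to that
decline, annual visits with jitter, dropout, and CDR staging consistent with
diagnosis.

Generative model per test, on the analysis scale (timed tests live on
-log10(seconds) and are back-transformed to seconds for storage):

    obs_0  = L_0 + e_0
    L_12   = mu + retest_slope * (L_0 - mu) + u
    obs_12 = L_12 + practice_gain + e_12 - decline * loading * see_gen

with latent ability L_0 ~ N(mu, sd^2), measurement noise e chosen so the
test's reliability is the stated share of observed variance, and u keeping
the latent variance stationary. The implied regression of obs_12 on obs_0
has slope reliability * retest_slope (attenuation), the quantity the
norming stage estimates. ``decline`` is a per-subject latent 12-month
decrement in composite-z units; scaling by the test's generative residual
standard deviation (``see_gen``) makes one unit of latent decline pull each
subtest z down by about one loading.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .model import TIMED_TESTS, Cohort, Diagnosis, Sex, Subject, TestBattery, TestId, Visit

STRATA = (Diagnosis.NORMAL, Diagnosis.IMPAIRED_NOT_MCI, Diagnosis.MCI)


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass(frozen=True)
class TestModelSpec:
    """Generative parameters for one test, on its analysis scale."""

    test_id: TestId
    true_score_mean: float
    true_score_sd: float
    reliability: float  # share of observed variance from latent ability
    practice_gain: float  # expected retest gain for stable subjects
    retest_slope: float  # regression-to-the-mean strength, (0, 1]
    score_floor: float  # raw-scale bounds
    score_ceiling: float
    decline_loading: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.reliability <= 1:
            raise ConfigError(f"reliability must be in (0,1], got {self.reliability}")
        if not 0 < self.retest_slope <= 1:
            raise ConfigError(f"retest_slope must be in (0,1], got {self.retest_slope}")
        if not self.score_floor < self.score_ceiling:
            raise ConfigError("score_floor must be below score_ceiling")

    @property
    def noise_sd(self) -> float:
        """Measurement-noise SD implied by the reliability."""
        rel = self.reliability
        return self.true_score_sd * math.sqrt((1 - rel) / rel)

    @property
    def observed_sd(self) -> float:
        return self.true_score_sd / math.sqrt(self.reliability)

    @property
    def attenuation_slope(self) -> float:
        """Closed-form slope of the obs_12 ~ obs_0 regression."""
        return self.reliability * self.retest_slope

    @property
    def see_gen(self) -> float:
        """Closed-form residual SD of the obs_12 ~ obs_0 regression."""
        return self.observed_sd * math.sqrt(1 - self.attenuation_slope**2)


def default_test_models() -> dict[TestId, TestModelSpec]:
    """Plausible test-range generative defaults.

    These are synthetic values chosen to sit in realistic score ranges for
    older adults; they are not estimates from any real reference sample.
    """
    mk = TestModelSpec
    return {
        TestId.LM_IMMEDIATE: mk(TestId.LM_IMMEDIATE, 14.0, 3.5, 0.75, 1.2, 0.85, 0.0, 25.0),
        TestId.LM_DELAYED: mk(TestId.LM_DELAYED, 13.0, 3.8, 0.75, 1.0, 0.85, 0.0, 25.0),
        # timed tests: analysis scale is -log10(seconds); 35 s and 90 s typical
        TestId.TRAILS_A: mk(TestId.TRAILS_A, -math.log10(35.0), 0.12, 0.70, 0.02, 0.85, 5.0, 150.0),
        TestId.TRAILS_B: mk(TestId.TRAILS_B, -math.log10(90.0), 0.15, 0.70, 0.025, 0.85, 10.0, 300.0),
        TestId.ANIMALS: mk(TestId.ANIMALS, 20.0, 4.5, 0.80, 0.5, 0.85, 0.0, 60.0),
        TestId.VEGETABLES: mk(TestId.VEGETABLES, 14.0, 3.5, 0.80, 0.4, 0.85, 0.0, 50.0),
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts."""

    n_reference: int = 294
    n_study: int = 6794
    stratum_fractions: dict[Diagnosis, float] = field(
        default_factory=lambda: {
            Diagnosis.NORMAL: 0.691,
            Diagnosis.IMPAIRED_NOT_MCI: 0.069,
            Diagnosis.MCI: 0.240,
        }
    )
    decline_fraction: dict[Diagnosis, float] = field(
        default_factory=lambda: {
            Diagnosis.NORMAL: 0.20,
            Diagnosis.IMPAIRED_NOT_MCI: 0.35,
            Diagnosis.MCI: 0.60,
        }
    )
    decline_rate_mean: float = 1.0  # composite-z units per 12 months
    decline_rate_sd: float = 0.5
    baseline_hazard: float = 0.0008  # dementia events per person-month
    log_hazard_per_decline_unit: float = math.log(2.2)
    stratum_hazard_multiplier: dict[Diagnosis, float] = field(
        default_factory=lambda: {
            Diagnosis.NORMAL: 1.0,
            Diagnosis.IMPAIRED_NOT_MCI: 1.8,
            Diagnosis.MCI: 3.5,
        }
    )
    max_followup_months: float = 156.0
    visit_interval_months: float = 12.0
    visit_jitter_months: float = 2.0
    censoring_rate: float = 1.0 / 70.0  # dropout hazard per person-month
    age_mean: float = 74.0
    age_sd: float = 7.8
    age_min: float = 60.0
    age_max: float = 104.0
    male_fraction: float = 0.385
    education_mean: float = 15.52
    education_sd: float = 3.21
    seed: int = 0
    test_models: dict[TestId, TestModelSpec] = field(default_factory=default_test_models)

    def validate(self) -> None:
        if self.n_reference < 0 or self.n_study < 0:
            raise ConfigError("cohort sizes must be >= 0")
        tot = sum(self.stratum_fractions.get(s, 0.0) for s in STRATA)
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ConfigError(f"stratum_fractions must sum to 1, got {tot}")
        for s in STRATA:
            f = self.decline_fraction.get(s, 0.0)
            if not 0 <= f <= 1:
                raise ConfigError(f"decline_fraction[{s}] outside [0,1]")
        if self.baseline_hazard < 0 or self.censoring_rate < 0:
            raise ConfigError("rates must be >= 0")
        if self.visit_interval_months <= 2 * self.visit_jitter_months:
            raise ConfigError("jitter must be below half the visit interval")


def _to_raw(spec: TestModelSpec, analysis: np.ndarray) -> np.ndarray:
    """Back-transform analysis-scale scores to clamped raw scores."""
    if spec.test_id in TIMED_TESTS:
        raw = 10.0 ** (-np.asarray(analysis, dtype=float))
    else:
        raw = np.asarray(analysis, dtype=float)
    return np.clip(raw, spec.score_floor, spec.score_ceiling)


def _sample_demographics(cfg: SimulationConfig, n: int, rng: np.random.Generator):
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), cfg.age_min, cfg.age_max)
    sex = np.where(rng.random(n) < cfg.male_fraction, Sex.MALE.value, Sex.FEMALE.value)
    edu = np.clip(rng.normal(cfg.education_mean, cfg.education_sd, n), 0.0, 30.0)
    return age, sex, edu


def _score_panel(
    cfg: SimulationConfig,
    months: np.ndarray,  # (n, k) visit months, NaN-padded
    decline: np.ndarray,  # (n,) latent 12-month decrement, composite-z units
    rng: np.random.Generator,
) -> dict[TestId, np.ndarray]:
    """Raw scores for every subject x visit x test, NaN where no visit.

    Latent ability follows an AR(1) across visit waves with the retest slope
    as autocorrelation; practice applies from the first retest onward; the
    latent decline grows linearly in time.
    """
    n, kmax = months.shape
    out: dict[TestId, np.ndarray] = {}
    for test, spec in cfg.test_models.items():
        latent = rng.normal(spec.true_score_mean, spec.true_score_sd, n)
        scores = np.full((n, kmax), np.nan)
        for k in range(kmax):
            active = ~np.isnan(months[:, k])
            noise = rng.normal(0.0, spec.noise_sd, n)
            practice = spec.practice_gain if k > 0 else 0.0
            decrement = decline * spec.decline_loading * spec.see_gen * (
                np.where(active, months[:, k], 0.0) / 12.0
            )
            obs = latent + practice + noise - decrement
            obs_raw = _to_raw(spec, obs)
            scores[active, k] = obs_raw[active]
            if k + 1 < kmax:
                innov = rng.normal(
                    0.0,
                    spec.true_score_sd * math.sqrt(1 - spec.retest_slope**2),
                    n,
                )
                latent = (
                    spec.true_score_mean
                    + spec.retest_slope * (latent - spec.true_score_mean)
                    + innov
                )
        out[test] = scores
    return out


def _assemble(
    cfg: SimulationConfig,
    ids: list[str],
    months: np.ndarray,
    panel: dict[TestId, np.ndarray],
    age0: np.ndarray,
    sex: np.ndarray,
    edu: np.ndarray,
    diagnosis_fn,
    cdr_fn,
    provenance: str,
) -> Cohort:
    subjects = []
    for i, sid in enumerate(ids):
        visits = []
        for k in range(months.shape[1]):
            m = months[i, k]
            if np.isnan(m):
                break
            battery = TestBattery()
            for test in TestId:
                battery.set(test, float(panel[test][i, k]))
            visits.append(
                Visit(
                    subject_id=sid,
                    visit_index=k,
                    months_since_baseline=float(m),
                    age_years=float(age0[i] + m / 12.0),
                    diagnosis=diagnosis_fn(i, k, m),
                    cdr_global=cdr_fn(i, k, m),
                    scores=battery,
                )
            )
        subjects.append(
            Subject(
                subject_id=sid,
                sex=Sex(sex[i]),
                education_years=float(edu[i]),
                visits=visits,
            )
        )
    cohort = Cohort(subjects=subjects, provenance=provenance)
    cohort.validate()
    return cohort


def generate_reference_cohort(config: Optional[SimulationConfig] = None) -> Cohort:
    """A robustly normal reference cohort: baseline plus ~12-month retest,
    everyone cognitively normal throughout, no decline, no dementia."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reference
    if n == 0:
        return Cohort(subjects=[], provenance="synthetic reference (empty)")
    age0, sex, edu = _sample_demographics(cfg, n, rng)
    jitter = rng.uniform(-cfg.visit_jitter_months, cfg.visit_jitter_months, n)
    months = np.column_stack(
        [np.zeros(n), cfg.visit_interval_months + jitter]
    )
    panel = _score_panel(cfg, months, np.zeros(n), rng)
    ids = [f"REF{i:05d}" for i in range(n)]
    return _assemble(
        cfg, ids, months, panel, age0, sex, edu,
        diagnosis_fn=lambda i, k, m: Diagnosis.NORMAL,
        cdr_fn=lambda i, k, m: 0.0,
        provenance="synthetic robustly-normal reference",
    )


def generate_study_cohort(
    config: Optional[SimulationConfig] = None, return_truth: bool = False
):
    """A heterogeneous study cohort with decline-linked dementia hazards.

    Subjects are assigned a diagnostic stratum, optionally a latent decline
    process, and a continuous-time dementia onset from a proportional-
    hazards model (log-hazard linear in the latent decline); onset is
    snapped to the next scheduled visit, mirroring adjudication at visits.
    With ``return_truth`` the latent per-subject state is returned alongside
    the cohort as a DataFrame for calibration checks.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_study
    if n == 0:
        cohort = Cohort(subjects=[], provenance="synthetic study (empty)")
        return (cohort, pd.DataFrame()) if return_truth else cohort

    strata = rng.choice(
        len(STRATA), size=n, p=[cfg.stratum_fractions[s] for s in STRATA]
    )
    decline_flag = np.array(
        [rng.random() < cfg.decline_fraction[STRATA[s]] for s in strata]
    )
    decline = np.where(
        decline_flag,
        np.maximum(0.0, rng.normal(cfg.decline_rate_mean, cfg.decline_rate_sd, n)),
        0.0,
    )

    # follow-up termination: dropout (exponential) or administrative cutoff
    if cfg.censoring_rate > 0:
        dropout = rng.exponential(1.0 / cfg.censoring_rate, n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(dropout, cfg.max_followup_months)

    # continuous-time dementia onset under proportional hazards
    mult = np.array([cfg.stratum_hazard_multiplier[STRATA[s]] for s in strata])
    rate = cfg.baseline_hazard * mult * np.exp(
        cfg.log_hazard_per_decline_unit * decline
    )
    with np.errstate(divide="ignore"):
        onset = np.where(rate > 0, rng.exponential(1.0, n) / np.where(rate > 0, rate, 1.0), np.inf)

    # visit schedule: annual grid with jitter, truncated at the censor time
    kmax = int(cfg.max_followup_months // cfg.visit_interval_months) + 1
    months = np.full((n, kmax), np.nan)
    months[:, 0] = 0.0
    for k in range(1, kmax):
        sched = k * cfg.visit_interval_months
        jit = rng.uniform(-cfg.visit_jitter_months, cfg.visit_jitter_months, n)
        t = sched + jit
        months[:, k] = np.where(sched <= censor, t, np.nan)

    # snap onset to the first visit at/after the continuous onset time
    onset_visit = np.full(n, -1)
    onset_month = np.full(n, np.nan)
    for i in range(n):
        for k in range(kmax):
            m = months[i, k]
            if np.isnan(m):
                break
            if m >= onset[i]:
                onset_visit[i] = k
                onset_month[i] = m
                break

    panel = _score_panel(cfg, months, decline, rng)
    age0, sex, edu = _sample_demographics(cfg, n, rng)

    # CDR machinery: 0 while NORMAL; impaired/MCI may sit at 0.5 before
    # onset (persistent once raised); >= 1 from the dementia-onset visit
    base_cdr_elevated = np.zeros(n, dtype=bool)
    for i in range(n):
        s = STRATA[strata[i]]
        if s is Diagnosis.IMPAIRED_NOT_MCI:
            base_cdr_elevated[i] = rng.random() < 0.4
        elif s is Diagnosis.MCI:
            base_cdr_elevated[i] = rng.random() < 0.6
    rise_visit = np.full(n, np.inf)  # visit index at which CDR first hits 0.5
    for i in range(n):
        if STRATA[strata[i]] is Diagnosis.NORMAL:
            continue
        if base_cdr_elevated[i]:
            rise_visit[i] = 0
            continue
        for k in range(1, kmax):
            if np.isnan(months[i, k]):
                break
            if onset_visit[i] != -1 and k >= onset_visit[i]:
                break
            if rng.random() < 0.05:
                rise_visit[i] = k
                break

    def diagnosis_fn(i: int, k: int, m: float) -> Diagnosis:
        if onset_visit[i] != -1 and k >= onset_visit[i]:
            return Diagnosis.DEMENTIA
        return STRATA[strata[i]]

    def cdr_fn(i: int, k: int, m: float) -> float:
        if onset_visit[i] != -1 and k >= onset_visit[i]:
            return 1.0
        if STRATA[strata[i]] is Diagnosis.NORMAL:
            return 0.0
        return 0.5 if k >= rise_visit[i] else 0.0

    ids = [f"S{i:06d}" for i in range(n)]
    cohort = _assemble(
        cfg, ids, months, panel, age0, sex, edu,
        diagnosis_fn, cdr_fn, provenance="synthetic study cohort",
    )
    if not return_truth:
        return cohort
    truth = pd.DataFrame(
        {
            "subject_id": ids,
            "stratum": [STRATA[s].value for s in strata],
            "is_decliner": decline_flag,
            "decline_rate": decline,
            "onset_month": onset_month,
            "censor_month": censor,
            "converted": onset_visit != -1,
        }
    )
    return cohort, truth


def reference_config(n: int, seed: int, **overrides) -> SimulationConfig:
    """Convenience constructor for a reference-cohort configuration."""
    return replace(SimulationConfig(seed=seed, n_reference=n), **overrides)


def simulate_survival_records(
    n: int,
    seed: int,
    log_hr_per_decline_unit: float = math.log(2.0),
    baseline_hazard: float = 0.005,
    followup_min_months: float = 24.0,
    followup_max_months: float = 120.0,
    age_coef: float = 0.0,
    education_coef: float = 0.0,
    sex_coef: float = 0.0,
):
    """Survival records drawn directly from a proportional-hazards model.

    The hazard is linked to the *same* decline covariate the Cox model will
    see (one unit = one composite-z unit of decline), so the fitted log
    hazard ratio is a consistent estimate of ``log_hr_per_decline_unit``.
    This is the clean oracle for coefficient-recovery and CI-coverage
    checks; the full cohort generator links the hazard to the latent decline
    instead, whose measured composite carries measurement error.
    """
    from .evaluation import SurvivalRecord
    from .scoring import NPStatus, PUBLISHED_CUTOFF_Z

    rng = np.random.default_rng(seed)
    decline = rng.normal(0.0, 1.0, n)  # decline units; higher = more decline
    age = np.clip(rng.normal(74.0, 7.8, n), 60.0, 104.0)
    edu = np.clip(rng.normal(15.5, 3.2, n), 0.0, 30.0)
    male = (rng.random(n) < 0.385).astype(int)
    lin = (
        log_hr_per_decline_unit * decline
        + age_coef * (age - age.mean())
        + education_coef * (edu - edu.mean())
        + sex_coef * male
    )
    rate = baseline_hazard * np.exp(lin)
    event_time = rng.exponential(1.0, n) / rate
    censor_time = rng.uniform(followup_min_months, followup_max_months, n)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    z = -decline  # stored on the composite-z scale (negative = decline)
    records = [
        SurvivalRecord(
            subject_id=f"R{i:06d}",
            time_months=float(time[i]),
            event=bool(event[i]),
            age_years=float(age[i]),
            sex=Sex.MALE if male[i] else Sex.FEMALE,
            education_years=float(edu[i]),
            np_decline_z=float(z[i]),
            np_status=(
                NPStatus.NP_PLUS if z[i] <= PUBLISHED_CUTOFF_Z else NPStatus.NP_MINUS
            ),
            diagnosis_12m=Diagnosis.NORMAL,
        )
        for i in range(n)
    ]
    return records
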