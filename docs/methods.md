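# Methods

## The NP-decline metric

Serial neuropsychological testing is complicated by practice effects
(retest scores improve without any change in ability) and regression to the
mean (extreme baselines drift back toward the population mean). Both are
absorbed by *regression-based change norms*: in a robustly normal reference
sample — older adults cognitively normal at baseline who remain normal
throughout follow-up — each test's 12-month score is regressed on its
baseline score,

    ŷ₁₂ = a + b·y₀ ,

and a subject's observed follow-up performance is standardized against that
expectation using the regression's standard error of the estimate
(the residual SD, S_y.x):

    z = (y₁₂ − ŷ₁₂) / S_y.x .

The battery covers six tests spanning memory (Logical Memory I and II,
story units 0–25), attention/executive function (Trail Making A and B,
completion seconds), and language (Animals and Vegetables category fluency,
words per minute). Trail-making times are right-skewed and keyed in the
wrong direction, so they are analyzed as −log₁₀(seconds): approximately
normal and higher-is-better like every other score. The published trail
equations are written as a positive-log regression with a trailing sign
flip; the package stores the constants in that parameterization and relies
on the identity −(a + b·log₁₀ s) = (−a) + b·(−log₁₀ s) (locked in by a
property test) so that locally fitted and published tables predict on the
same analysis scale. `fit_norm` therefore negates the analysis-scale
intercept when it stores a timed-test equation.

The six subtest z's are averaged, unweighted, into the composite NP-decline
z. NP decline is *present* (NP+) when the composite is at or below the
published ROC-derived cutoff −0.5808 — an inclusive boundary, matching the
"at or below the 28th percentile" reading; 100·Φ(−0.5808) = 28.07. The
default scoring policy requires all six subtests (that is how the composite
is defined); a configurable minimum of ≥4 is available for realistic data,
with the count of subtests used always recorded and INDETERMINATE returned
below the minimum.

The cutoff can be re-derived on any scored sample with
`roc_optimal_cutoff`, which maximizes Youden's J over the observed
composite values (the original derivation cites ROC analysis without
restating its optimality criterion; J is the standard single-number choice
and reproduces a percentile-style cutoff). Ties break toward the more
negative threshold, the conservative direction for flagging decline.

## Synthetic cohorts

Real reference and study data of this kind live in access-controlled
repositories, so the package ships a generative model with the structure
the analysis assumes; all defaults are synthetic, plausible test-range
values, not estimates from any real cohort.

Per test, on its analysis scale, with latent ability L and measurement
noise e set by a target reliability ρ (share of observed variance due to
ability):

    y₀  = L₀ + e₀                         L₀ ~ N(μ, σ²),  Var(e) = σ²(1−ρ)/ρ
    L₁₂ = μ + r·(L₀ − μ) + u              Var(u) = σ²(1−r²)
    y₁₂ = L₁₂ + practice + e₁₂ − d·λ·SEE

where r is the 12-month latent autocorrelation (the regression-to-the-mean
strength), `practice` the retest gain for stable subjects, d the subject's
latent 12-month decline in composite-z units (0 for non-decliners), λ the
test's decline loading (default 1.0 for all six, inducing the shared
decline that makes the composite informative), and SEE the closed-form
generative residual SD. Scaling the decline by SEE means one unit of d
pulls each subtest z down by about λ, and the composite by about d. Scores
are clamped to raw-scale bounds and back-transformed (timed tests to
seconds); they are kept continuous rather than rounded to integer raw
units, keeping the closed-form attenuation slope b = ρ·r exact — a known,
minor departure from real score scales.

The implied composite z of a stable subject has SD ≈ √(1/6) ≈ 0.41
(six independent subtest residuals), so with the default decline mixture
(decliner fractions 0.20 / 0.35 / 0.60 across the normal, impaired-not-MCI
and MCI strata; d ~ N(1.0, 0.5) truncated at 0) the NP+ fractions land near
the 24% / 35% / 55% pattern of the motivating cohort.

Study-cohort machinery around the scores:

- **Strata.** 12-month diagnostic mix 69.1% normal, 6.9% impaired without
  MCI, 24.0% MCI (the motivating cohort's composition). Diagnosis is
  constant at the stratum value until dementia onset.
- **Dementia onset.** Continuous-time exponential with rate
  h₀ · m_stratum · exp(β·d), h₀ = 0.0008 events/person-month,
  β = log 2.2 per decline unit, stratum multipliers 1.0 / 1.8 / 3.5.
  The multipliers encode diagnosis carrying risk beyond measured decline;
  without them the NP− conversion rates would be nearly flat across strata,
  contrary to the observed 4.2% → 9.7% → 20.6% gradient. Onset is snapped
  to the next scheduled visit (adjudication happens at visits), and the
  diagnosis stays DEMENTIA from that visit on. Calibration targets the
  observed ordering and rough band only; exact reproduction of any real
  cohort's percentages is a non-goal.
- **Visits and censoring.** Annual visits with ±2 months uniform jitter,
  dropout hazard 1/70 per month, administrative cutoff at 156 months.
  After the eligibility rules (below) this yields observed follow-up with
  roughly the right mean and minimum.
- **CDR.** 0 at every cognitively normal visit; 0 or 0.5 at impaired/MCI
  visits before onset (elevated from baseline with probability 0.4 / 0.6 by
  stratum, else a 5%-per-visit chance of rising, persistent once raised);
  ≥ 1 from the onset visit. This supports the sensitivity outcome
  (CDR 0 → ≥0.5) without making it identical to the diagnosis outcome.
- **Demographics.** Age ~ N(74.0, 7.8²) clipped to [60, 104], 38.5% male,
  education ~ N(15.52, 3.21²) clipped to [0, 30] — the motivating cohort's
  Table-1 moments; these feed the covariate adjustments.

What the generator does **not** emulate: site heterogeneity, diagnostic
reversion (MCI → normal), missing-score patterns, integer score grids,
death as a competing risk, and any dependence of practice effects on
diagnosis. Passing calibration tests therefore show the pipeline is
correct *under its own assumptions*, not that the synthetic defaults match
any real population.

## Eligibility and survival construction

Inclusion mirrors the cohort-study conventions: age ≥ 60 at baseline;
baseline diagnosis in {normal, impaired-not-MCI, MCI}; ≥ 3 exams; total
follow-up strictly > 12 months; not demented by the 12-month exam. The
exclusion ledger counts each subject under its *first* failing rule in that
fixed order, so excluded + eligible = total always.

Survival records put the time origin at the 12-month exam — NP decline is
only knowable there; a baseline origin is available behind a flag for
comparison. Event time is months from the origin to the first visit with a
dementia diagnosis; censoring time is months to the last dementia-free
visit. Group membership (diagnosis at 12 months) is taken from the
follow-up visit, so decline is classified within the correct diagnostic
range.

## Statistical models

- **Conversion contrasts.** Within each diagnostic stratum, a 2×2 Pearson
  chi-squared (NP status × converted), 1 df, no continuity correction
  (large-sample usage; configurable). Empty margins report the statistic as
  undefined with a warning rather than raising.
- **Cox regression** (lifelines, Efron ties — visit-grid snapping produces
  heavy ties, and Efron is less biased than Breslow there). The composite z
  is negated on entry so the reported HR is per *unit of decline* and HR > 1
  means decline is harmful; the raw coefficient is also emitted. Age, sex
  and years of education are adjusted for; subjects with unknown sex are
  excluded from covariate-adjusted models with a logged count. The model
  chi-square is the likelihood-ratio statistic against the covariates-only
  null, and −2 log L is reported. Both the continuous-z and the binary
  NP± specification are provided, overall and per stratum — neither is
  privileged.
- **ANCOVA.** OLS of the composite z on diagnosis × dementia outcome, their
  interaction, and the covariates; type-II F tests; adjusted means are
  predictions at the grand covariate means; all 15 pairwise cell contrasts
  carry Bonferroni-adjusted p-values. The alternative factor pair
  (diagnosis × NP status) is exposed via `outcome_factor`, not silently
  chosen.
- **Progression curves.** Kaplan–Meier per diagnosis × NP± group, reported
  as cumulative progression 1 − S(t) on a 12-month grid with at-risk and
  interval event counts.

## Verification design

- Printed-constant anchors (the six equations, their S_y.x values, the
  cutoff and its percentile) are tested by exact string comparison and
  by hand-arithmetic oracles computed independently of the package code.
- `fit_norm` is checked against statsmodels OLS (dual route), against the
  closed-form attenuation slope ρ·r on simulated cohorts, and for the exact
  residual identity √(mean squared residual · n/(n−2)) = SEE.
- Norm-parameter recovery runs 200 replicates at the reference sample size
  n = 294 with the first memory equation's constants as truth, requiring
  intercept, slope and SEE each within 3 closed-form sampling SEs.
- Scoring calibration fits norms on one 10,000-subject reference cohort and
  scores an independent one: every subtest z must have mean within ±0.05
  and SD within 0.95–1.05. The fitting cohort is deliberately large so
  the check isolates the scoring pipeline; at n = 294 the norm-estimation
  error alone would dominate the band.
- Cox recovery uses a records-level simulator whose hazard is linked to the
  same covariate the model fits (true HR 2.0 per decline unit, n = 5,000,
  100 replicates; mean log-HR within 0.1 of log 2, ≥93% CI coverage). In
  the full cohort generator the hazard is linked to the *latent* decline,
  so the coefficient on the *measured* composite is attenuated by classical
  measurement error — a real statistical phenomenon, not an implementation
  defect — which is why the full pipeline is checked directionally (NP+
  conversion above NP− in every stratum, stratified curve ordering, HR > 1
  everywhere) rather than for exact coefficient recovery.
- Chi-squared type-I calibration draws 1,000 null 2×2 tables (conversion
  independent of NP status, n = 600 per table) and requires a rejection
  rate of 5% ± 1.5% at α = 0.05.

Problem sizes throughout (10,000-subject calibration cohorts, 20,000 for
directional checks, 100–1,000 replicates) were chosen so Monte-Carlo error
is small relative to each tolerance while the whole suite stays fast.

## Known limitations

- The norm model uses baseline score only, as the published equations do;
  demographically adjusted change norms are out of scope.
- Complete-case norm fitting and all-six-subtest scoring are the defaults;
  no imputation is provided.
- Whether the original reference regressions were fitted on
  transformed-then-inverted scores or inverted post hoc is not documented
  at the source; the two are algebraically identical under the adopted
  convention, which this package states as its own choice.
- The published 28th-percentile figure is treated as inclusive ("at or
  below"); an exclusive reading would differ only on exact ties.
- Conversion percentages, hazard ratios and chi-squared magnitudes from the
  synthetic study cohort are properties of the generator's defaults, not
  estimates of any real cohort's values.
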