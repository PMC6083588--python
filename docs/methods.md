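# Methods

## Problem and estimands

A population-based volunteer cohort study is linked to whole-of-
population health records. Everyone aged ≥45 diagnosed with bowel
(C18–C20) or non-small-cell lung cancer (C34, small-cell morphologies
M8041–M8045/M8246 excluded) in the study window forms the source
population; the cohort members among them (recruited *before*
diagnosis) form a nested subsample. Two questions are asked:

1. **Representativeness** — are demographic, tumour and
   health-service-use characteristics of the subsample proportionally
   those of the population? Measured per category by the ratio of
   relative frequency, RRF = p_sub / p_pop.
2. **Association bias** — do risk-factor associations (remoteness,
   area-SES, country of birth, comorbidity) with resection, long
   hospital stay (> 4 weeks), frequent ED use (> 2 attendances) and
   one-year survival differ between subsample and population? Measured
   per factor level by the relative odds ratio, ROR = OR_sub / OR_pop,
   from identically specified multivariable logistic models.

## Nested-sample confidence limits

Both ratios compare a subsample with a population that *contains* it,
so the two estimates are positively correlated and independent-samples
variances are too wide. Under the working assumption that the
subsample is a simple random sample of the population:

- var(ln RRF) = (1 − p_sub)/x_sub − (1 − p_pop)/x_pop;
- var(ln ROR) = se²(ln OR_sub) − se²(ln OR_pop), because for MLEs from
  nested samples cov(b_sub, b_pop) = var(b_pop).

The difference form is validated two ways: it reproduces published
confidence-limit pairs exactly at 2 dp where the printed counts allow
recomputation (the independent form fails those checks on the lower
limits), and it attains 95.2% empirical coverage under a hypergeometric
nested-subsampling oracle at the study's sizes (population 27,013,
subsample 1,837; `analysis/06_calibration.py`). The subsample is *not*
in fact a random sample — that is the point of the study — but coverage
is adequate, consistent with the formula's originating literature.
Degenerate cases: a non-positive RRF variance difference falls back to
the independent-samples variance with a warning; a non-positive ROR
variance difference is floored at 1e-12 and flagged (`se_floored`).
Zero cells yield status-flagged results, never silent NaNs. The
z-quantile is the exact normal value 1.959964; at 2 dp this is
indistinguishable from 1.96.

## Eligibility cascade

Index cancer = a person's earliest registry record with an in-scope
site code. Exclusions, one reason per person in fixed precedence
(out-of-window → age < 45 → site/histology → unknown date or residence
→ death-certificate-only → prior cancer since Jan 2000 → another
primary within 91 days): the precedence makes the flow ledger
deterministic; the source describes the rules but no order. "Three
months" is implemented as 91 days (calendar-month arithmetic is
ambiguous; configurable). A second primary within the window excludes
the person entirely; a later cancer outside it leaves the index intact.
Participants are roster members recruited strictly before diagnosis;
the population always retains them (nesting is never broken).

## Outcome derivation

All windows use a 365-day year (configurable; no leap handling, for
determinism). Prior window [diagnosis − 365 d, diagnosis), post window
[diagnosis, diagnosis + 365 d) — half-open, so no event is double
counted. An admission belongs to a window by its admission date;
bed-days are the union of stay intervals clipped at window edges, so
transfers and nested stays are not double counted (union-of-days is our
stated choice; the source is silent). Overnight ⇔ separation date >
admission date. Bands follow the published category sets (e.g. post-
diagnosis weeks: zero / ≤2 / >2–4 / >4). Hospital-type shares are
computed over admissions, not persons. The Charlson score uses a
five-year lookback over all hospital-recorded diagnoses, classical
17-condition weights, each condition counted once; the condition →
ICD-10-prefix map ships as data (Quan-style prefixes) and is swappable.
People with no admission in the lookback get a distinct `no_admission`
band. Major resection = any post-window admission carrying a code from
the packaged (sentinel) resection-code list; licensing prevents
shipping real intervention codes, so real analyses supply their own
list. Post-operative survival anchors at the resection admission date
(procedure date is not modelled). Survival at 1/3 years is a plain
binary, valid because the generator guarantees (and the derivation
asserts) a censor date ≥ 3 years after every diagnosis.

## Logistic fits

Fits are binomial GLMs on covariate-pattern-aggregated data (identical
likelihood to person-level logistic regression), dummy-coded against
declared reference levels (major city, least-disadvantaged quintile,
Australia-born, Charlson 0, male, 65–74, localised). Age enters as the
published 10-year bands; "unknown" country of birth and extent are
explicit levels. Separation is detected (|coef| > 15 or SE > 50) and
flagged, not penalised away; models whose smaller outcome class yields
fewer than 10 events per parameter (configurable) are refused with
`too_few_events` — echoing the precision caveats sparse subsamples
carry — rather than reported. Univariable fits are emitted alongside
the multivariable panel for comparison.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes;
it is a study-conditions model, not a re-creation of any real dataset.

- **Covariates** are drawn from an explicit joint table: product of
  configured marginals (NSW-like bowel+lung mix: 56% male; age bands
  8.9/21.3/30.8/28.5/10.5%; remoteness 66.4/24.6/9.0%; SES quintiles
  14.4–26.3%; country-of-birth 67/9.4/20/3.6%) times exp(θ) log-linear
  association terms, making the pairwise odds ratio between flagged
  categories exactly exp(θ). Extent of disease is drawn per cancer
  type (bowel and lung extent distributions differ strongly) and is
  therefore outside the dependence machinery.
- **Latent health** is a per-person standard normal entering
  participation and outcomes linearly on the log-odds/log-rate scale —
  the minimal collider mechanism (shared cause of participation and
  outcome). Higher = healthier.
- **Participation**: probability = cap(logistic(baseline + category
  offsets + dependence·latent) × design multiplier, 1). Default design
  multipliers are the documented oversampling — ×2 for ages 85+ and
  both non-metropolitan remoteness levels — with `inf` available for a
  take-everyone stratum; capping at 1 (not renormalising) is the
  simplest faithful reading of a certainty design. Multipliers and
  self-selection offsets are treated as separable factors (their
  interaction with the cohort's ~18% response rate is not documented
  anywhere). Baseline ≈ 7% yields the observed few-percent participant
  share among cancer patients.
- **Outcomes**: binary models (resection, 1-year survival, 3-year
  survival conditional on the first year) and Poisson log-rate models
  (admissions, ED attendances, background admissions for the Charlson
  lookback) with per-cancer intercepts chosen to imply the published
  population marginals (e.g. 1-year survival ~83% bowel / ~42% lung,
  resection ~79% / ~17%, ~20% of post-diagnosis totals above four
  weeks in hospital), plus extent/age/SES effects and latent loadings
  for realistic structure. ED events are generated in full and thinned
  by a remoteness-specific coverage probability (default 1.0 / 0.85 /
  0.70), emulating incomplete non-metropolitan ED capture; thinning
  uses its own random stream so datasets differing only in coverage
  share events. Deaths truncate later admissions/ED events and clip
  separation dates, so no event follows a death.
- **Determinism**: one root seed splits into per-stage streams;
  identical specs + seed give byte-identical CSVs. The generating
  `truth.json` is serialised beside the data and round-trips into the
  three spec objects.

What the generator does *not* emulate: record-linkage error, the
recruitment questionnaire, a non-cancer background population (every
analysis conditions on diagnosis), within-band age–participation
gradients, cause-specific survival, or real registry noise (DCO
records, unknown dates) — the cascade's exclusion arms are exercised by
handcrafted fixtures instead. Passing tests therefore show the
estimators are correct and calibrated under the assumed structure, not
that any particular real-world cohort is unbiased.

## Scales used in the shipped analyses

The numbered analysis scripts run 60,000 simulated patients
(≈3,300 participants), large enough that all four outcome models clear
the events-per-parameter rule for the bowel cohort while the whole
pipeline runs in seconds. Calibration uses 10,000 hypergeometric
coverage replicates, 500–1,000 ROR null replicates and 250–500 collider
replicates. The collider design defaults (participation loadings 0.8 on
the factor and 1.2 on latent health, outcome loading 1.2) give a mean
ln ROR ≈ −0.13, detectable at these replicate counts.

## Known limitations

- The RRF/ROR variance formulas assume random nested subsampling;
  under strong self-selection the limits are approximate (their
  published origin reports adequate coverage in a comparable setting).
- Survival is binary at fixed horizons, not time-to-event; no
  competing risks.
- The ROR panel inherits logistic-regression caveats: sparse-data bias
  is flagged rather than corrected (no Firth fallback by default).
- Only two remoteness-based ED coverage regimes are modelled; the
  private-hospital ED undercount is not.
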