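# cohortbias

Assessing self-selection in population-based cohort studies with linked
administrative health data.

Volunteer cohort studies enrol people who are, on average, healthier and
more advantaged than their source population. That is well understood
for aetiological associations, but much less is known about whether
**health-service-use** outcomes and their risk-factor associations
generalise from a self-selected cohort. When cohort records can be
linked to whole-of-population registries (cancer registry, hospital
admissions, emergency department attendances, deaths), the cohort
members diagnosed with a disease form a *nested subsample* of everyone
diagnosed, and the two can be compared directly. This package implements
that comparison for bowel and lung cancer cohorts, with a seeded
synthetic generator standing in for the confidential linked data.

## The statistics

**Representativeness.** For a category of a covariate or outcome with
`x_sub / n_sub` prevalence among cohort participants and `x_pop / n_pop`
in the source population, the **ratio of relative frequency** is

```
RRF = (x_sub / n_sub) / (x_pop / n_pop)
```

with RRF > 1 meaning over-representation among participants. Because
the subsample is contained in the population, the usual two-independent-
proportions variance overstates the uncertainty of this ratio; the
nested-subsample log-scale variance is the *difference*

```
var(ln RRF) = (1 − p_sub) / x_sub − (1 − p_pop) / x_pop
```

and 95% limits are `RRF · exp(±1.96 · SE)`.

**Association bias.** The same multivariable logistic model (risk
factors: remoteness, area-SES quintile, country-of-birth group, Charlson
comorbidity band; prognostic adjusters: sex, age band, extent of
disease, plus resection status for non-resection outcomes) is fitted
separately among participants and in the population. For each factor
level the **relative odds ratio**

```
ROR = OR_subsample / OR_population,   se(ln ROR) = sqrt(se_sub² − se_pop²)
```

measures distortion of the association; departure from 1 flags selection
bias. The variance difference again reflects nesting (for maximum-
likelihood estimates from a subsample versus the full sample,
cov(b_sub, b_pop) = var(b_pop)).

## Layout

- `src/cohortbias/` — the library: `synthetic_data` (linked-data
  generator), `eligibility` (inclusion/exclusion cascade),
  `outcomes` (bands, Charlson score, resection, survival),
  `representativeness` (RRF), `association_bias` (OR/ROR),
  `report` (tables + end-to-end run), `calibration` (known-truth
  simulation oracles), `cli`.
- `analysis/01_simulate.py … 06_calibration.py` — numbered drivers
  running the full study on synthetic data; outputs under `results/`.
- `scripts/acceptance.py` — recomputes the headline published numbers.

## Worked example

Published tables print the underlying counts, so any RRF row can be
recomputed exactly. Among bowel-cancer patients, 1,009 of 1,837 cohort
participants and 14,585 of 27,013 population members were male:

```python
>>> from cohortbias.representativeness import rrf
>>> rrf(1009, 1837, 14585, 27013).rounded()
(1.02, 0.98, 1.06)
```

— men are represented almost proportionally (RRF 1.02), and the nested
limits (0.98, 1.06) match the published interval; the independent-
samples formula would give (0.97, 1.06) and is detectably wrong.

End to end on synthetic data:

```python
>>> from cohortbias.report import RunConfig, run_all
>>> s = run_all(RunConfig(out_dir="out", scenario="selection",
...                       n_persons=12_000, seed=7))
>>> s["n_eligible"], s["n_participants"]
(12000, 661)
```

The `selection` scenario plants volunteer-cohort self-selection (plus
the documented rural/oldest-age oversampling design), and the pipeline
recovers it: bowel-cancer patients born in non-English-speaking
countries come out under-represented (RRF 0.51, CL 0.39, 0.68) and
inner-regional residents over-represented (RRF 1.62, CL 1.46, 1.81) in
this run's `table1.csv`.

The same can be driven from the shell:

```
cohortbias simulate --scenario selection --n-persons 30000 --out sim --seed 1
cohortbias run --config run.yaml
```

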