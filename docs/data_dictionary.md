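# Data dictionary

All files are plain CSV with ISO-8601 dates. A simulated dataset
directory holds the five linked tables plus `truth.json` (the
generating parameter values, sufficient to re-instantiate the
population/participation/outcome specs).

## registry.csv — one row per cancer diagnosis

| column | type | notes |
|---|---|---|
| person_id | str | links all tables |
| cancer_site_code | str | ICD-10 C-code (C18/C19/C20 bowel, C34 lung) |
| histology_code | str | morphology m-code; M8041–M8045/M8246 = small cell |
| diagnosis_date | date | |
| age_at_diagnosis | int | years |
| sex | str | male / female |
| remoteness | str | major_city / inner_regional / outer_regional_remote |
| ses_quintile | str | 1–5, 5 = most disadvantaged |
| cob_group | str | australia / other_english / non_english / unknown |
| extent | str | localised / regional / distant / unknown |
| dco_flag | bool | death-certificate-only registration |
| residence_known | bool | |
| diagnosis_date_known | bool | |

## admissions.csv — one row per hospital admission

| column | type | notes |
|---|---|---|
| person_id | str | |
| admission_date / separation_date | date | separation ≥ admission; overnight ⇔ separation > admission |
| hospital_type | str | public / private |
| urgency | str | emergency / planned_other |
| acute_flag | bool | false for sub-/non-acute facilities (excluded from use measures) |
| procedure_codes | str | `;`-separated; resection codes per `data/resection_codes.csv` |
| diagnosis_codes | str | `;`-separated; Charlson prefixes per `data/charlson_map.csv` |

## ed.csv — one row per emergency department attendance

person_id, attendance_date.

## deaths.csv — one row per death

person_id, death_date. No event for a person postdates their death.

## roster.csv — cohort-study membership

person_id, recruitment_date. Participants in an analysis are roster
members recruited strictly before their diagnosis.

## Derived analysis rows (`analysis_rows.csv`)

One row per eligible person: identifiers (person_id, cohort =
bowel/lung, participant flag), covariates (sex, age_group, remoteness,
ses_quintile, cob_group, extent, charlson_band ∈ {0, 1, 2+,
no_admission}), outcome bands (adm_prior_band 0/1/2+, adm_post_band
0/1/2/3+, weeks_prior_band zero/1_week/gt1_week, weeks_post_band
zero/up_to_2_weeks/gt2_to_4_weeks/gt4_weeks, ed_prior_band, ed_post_band),
admission-level hospital-type counts (n_adm_private/public_prior/post),
resection flag + resection_urgency (defined only with a resection), and
survival_1y / survival_3y / survival_1y_postop (the last defined only
with a resection).
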