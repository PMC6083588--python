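"""Category sets and orderings shared across the pipeline.

Every categorical variable used by the representativeness and
association-bias machinery has a declared, fixed ordering so that tables
and model design matrices are deterministic.
"""

from __future__ import annotations

SEX = ("male", "female")
AGE_GROUPS = ("45-54", "55-64", "65-74", "75-84", "85+")
REMOTENESS = ("major_city", "inner_regional", "outer_regional_remote")
SES_QUINTILES = ("1", "2", "3", "4", "5")  # 5 = most disadvantaged
COB_GROUPS = ("australia", "other_english", "non_english", "unknown")
EXTENT = ("localised", "regional", "distant", "unknown")
CANCERS = ("bowel", "lung")

CHARLSON_BANDS = ("0", "1", "2+", "no_admission")

# outcome band label sets (window-specific, mirroring the published tables)
ADM_PRIOR_BANDS = ("0", "1", "2+")
ADM_POST_BANDS = ("0", "1", "2", "3+")
WEEKS_PRIOR_BANDS = ("zero", "1_week", "gt1_week")
WEEKS_POST_BANDS = ("zero", "up_to_2_weeks", "gt2_to_4_weeks", "gt4_weeks")
ED_PRIOR_BANDS = ("0", "1", "2+")
ED_POST_BANDS = ("0", "1", "2", "3+")
URGENCY = ("planned_other", "emergency")
HOSPITAL_TYPES = ("public", "private")

COVARIATES: dict[str, tuple[str, ...]] = {
    "sex": SEX,
    "age_group": AGE_GROUPS,
    "remoteness": REMOTENESS,
    "ses_quintile": SES_QUINTILES,
    "cob_group": COB_GROUPS,
    "extent": EXTENT,
}

#: declared ordering for every categorical column an RRF table may use
ORDERINGS: dict[str, tuple[str, ...]] = {
    **COVARIATES,
    "cancer": CANCERS,
    "charlson_band": CHARLSON_BANDS,
    "adm_prior_band": ADM_PRIOR_BANDS,
    "adm_post_band": ADM_POST_BANDS,
    "weeks_prior_band": WEEKS_PRIOR_BANDS,
    "weeks_post_band": WEEKS_POST_BANDS,
    "ed_prior_band": ED_PRIOR_BANDS,
    "ed_post_band": ED_POST_BANDS,
    "resection_urgency": URGENCY,
}

_AGE_EDGES = ((45, 54), (55, 64), (65, 74), (75, 84), (85, 200))


def age_to_group(age: int) -> str:
    """Map an age at diagnosis (years, >=45) to its 10-year analysis band."""
    for (lo, hi), label in zip(_AGE_EDGES, AGE_GROUPS):
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside the supported bands (>=45)")
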