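"""Inclusion/exclusion cascade building the analysis cohorts.

Eligible: people aged >= 45 whose index cancer — the earliest registry
record with an in-scope site code — is bowel (C18-C20) or lung (C34,
excluding small-cell morphologies M8041-M8045 and M8246) diagnosed inside
the study window.  Excluded: prior cancer since the lookback start,
another cancer within the multiple-primary window of the index, records
known only from a death certificate, unknown diagnosis date or residence,
and configured uncommon histologies.

Exactly one exclusion reason is recorded per excluded person, in a fixed
precedence order, so the resulting flow ledger is deterministic:
out_of_window -> age -> site_histology -> unknown_date_or_residence ->
dco -> prior_cancer -> multiple_primary.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import age_to_group
from ._util import as_date

EXCLUSION_ORDER = (
    "out_of_window",
    "age",
    "site_histology",
    "unknown_date_or_residence",
    "dco",
    "prior_cancer",
    "multiple_primary",
)


@dataclass
class EligibilityConfig:
    window: tuple[dt.date, dt.date] = (dt.date(2006, 2, 1), dt.date(2012, 12, 31))
    min_age: int = 45
    bowel_codes: frozenset[str] = frozenset({"C18", "C19", "C20"})
    lung_codes: frozenset[str] = frozenset({"C34"})
    lung_excluded_morphology: frozenset[str] = frozenset(
        {"M8041", "M8042", "M8043", "M8044", "M8045", "M8246"})
    prior_cancer_lookback_start: dt.date = dt.date(2000, 1, 1)
    multiple_primary_window_days: int = 91  # "three months", calendar-agnostic
    uncommon_histology_exclusion_set: frozenset[str] = frozenset()
    max_date_errors: int = 0

    def __post_init__(self) -> None:
        self.window = tuple(as_date(d) for d in self.window)
        self.prior_cancer_lookback_start = as_date(self.prior_cancer_lookback_start)
        if self.min_age < 0:
            raise ValueError("min_age must be >= 0")
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede end")

    def site_cohort(self, code: str) -> str | None:
        code = str(code).upper()
        if any(code.startswith(c) for c in self.bowel_codes):
            return "bowel"
        if any(code.startswith(c) for c in self.lung_codes):
            return "lung"
        return None


class DateParseError(ValueError):
    pass


def _parse_dates(registry: pd.DataFrame, max_errors: int) -> pd.Series:
    parsed = pd.to_datetime(registry["diagnosis_date"], errors="coerce")
    known = registry.get("diagnosis_date_known",
                         pd.Series(True, index=registry.index)).astype(bool)
    bad = parsed.isna() & known & registry["diagnosis_date"].notna()
    if bad.sum() > max_errors:
        raise DateParseError(
            f"{int(bad.sum())} unparseable diagnosis dates "
            f"(threshold {max_errors}); first offending person_id: "
            f"{registry.loc[bad, 'person_id'].iloc[0]}")
    return parsed


def select_index_cases(registry: pd.DataFrame,
                       config: EligibilityConfig | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility cascade; return (cohort stubs, exclusion ledger).

    The cohort frame has one row per eligible person (person_id, cohort
    label, diagnosis date, covariates); the ledger has one row per
    excluded person with its single precedence-ordered reason, plus a
    summary usable as a recruitment-flow table.
    """
    config = config or EligibilityConfig()
    cols = ["person_id", "cohort", "diagnosis_date", "age_at_diagnosis",
            "age_group", "sex", "remoteness", "ses_quintile", "cob_group", "extent"]
    if len(registry) == 0:
        return (pd.DataFrame(columns=cols),
                pd.DataFrame(columns=["person_id", "reason"]))

    reg = registry.copy()
    reg["diagnosis_date"] = _parse_dates(reg, config.max_date_errors)
    w0, w1 = (pd.Timestamp(d) for d in config.window)
    lb0 = pd.Timestamp(config.prior_cancer_lookback_start)
    mp_days = pd.Timedelta(days=config.multiple_primary_window_days)

    # fast path: persons with a single registry record need no record
    # interplay (no prior-cancer or multiple-primary rule can fire)
    n_records = reg["person_id"].map(reg["person_id"].value_counts())
    singles = reg[n_records == 1]
    multi = reg[n_records > 1]
    eligible_frames: list[pd.DataFrame] = []
    excluded_frames: list[pd.DataFrame] = []
    if len(singles):
        e_df, x_df = _cascade_single_records(singles, config, w0, w1)
        eligible_frames.append(e_df)
        excluded_frames.append(x_df)

    eligible_rows = []
    excluded = []
    for pid, grp in multi.groupby("person_id", sort=True):
        grp = grp.sort_values("diagnosis_date", kind="mergesort", na_position="last")
        in_scope = grp[grp["cancer_site_code"].map(
            lambda c: config.site_cohort(c) is not None)]
        if len(in_scope) == 0:
            excluded.append((pid, "site_histology"))
            continue
        index = in_scope.iloc[0]
        cohort = config.site_cohort(index["cancer_site_code"])
        d = index["diagnosis_date"]
        hist = str(index.get("histology_code", "")).upper()

        reason = None
        date_known = bool(index.get("diagnosis_date_known", True)) and not pd.isna(d)
        if date_known and not (w0 <= d <= w1):
            reason = "out_of_window"
        elif int(index["age_at_diagnosis"]) < config.min_age:
            reason = "age"
        elif ((cohort == "lung" and hist in config.lung_excluded_morphology)
              or hist in config.uncommon_histology_exclusion_set):
            reason = "site_histology"
        elif not date_known or not bool(index.get("residence_known", True)):
            reason = "unknown_date_or_residence"
        elif bool(index.get("dco_flag", False)):
            reason = "dco"
        else:
            others = grp.drop(index=index.name)
            od = others["diagnosis_date"]
            if ((od >= lb0) & (od < d)).any():
                reason = "prior_cancer"
            elif ((od > d) & (od <= d + mp_days)).any():
                reason = "multiple_primary"

        if reason is not None:
            excluded.append((pid, reason))
            continue
        eligible_rows.append({
            "person_id": pid,
            "cohort": cohort,
            "diagnosis_date": d,
            "age_at_diagnosis": int(index["age_at_diagnosis"]),
            "age_group": age_to_group(int(index["age_at_diagnosis"])),
            "sex": index["sex"],
            "remoteness": index["remoteness"],
            "ses_quintile": str(index["ses_quintile"]),
            "cob_group": index["cob_group"],
            "extent": index["extent"],
        })

    eligible_frames.append(pd.DataFrame(eligible_rows, columns=cols))
    excluded_frames.append(pd.DataFrame(excluded, columns=["person_id", "reason"]))
    cohort_df = (pd.concat([f for f in eligible_frames if len(f)], ignore_index=True)
                 if any(len(f) for f in eligible_frames)
                 else pd.DataFrame(columns=cols))
    ledger = (pd.concat([f for f in excluded_frames if len(f)], ignore_index=True)
              if any(len(f) for f in excluded_frames)
              else pd.DataFrame(columns=["person_id", "reason"]))
    cohort_df = cohort_df.sort_values("person_id", kind="mergesort").reset_index(drop=True)
    ledger = ledger.sort_values("person_id", kind="mergesort").reset_index(drop=True)
    return cohort_df, ledger


def _cascade_single_records(reg: pd.DataFrame, config: EligibilityConfig,
                            w0: pd.Timestamp, w1: pd.Timestamp
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised cascade for persons holding exactly one registry record."""
    site = reg["cancer_site_code"].astype(str).str.upper()
    cohort = pd.Series(np.where(
        site.str[:3].isin(config.bowel_codes), "bowel",
        np.where(site.str[:3].isin(config.lung_codes), "lung", "")),
        index=reg.index)
    hist = reg.get("histology_code", pd.Series("", index=reg.index)) \
        .fillna("").astype(str).str.upper()
    d = reg["diagnosis_date"]
    date_known = reg.get("diagnosis_date_known",
                         pd.Series(True, index=reg.index)).astype(bool) & d.notna()
    res_known = reg.get("residence_known",
                        pd.Series(True, index=reg.index)).astype(bool)
    dco = reg.get("dco_flag", pd.Series(False, index=reg.index)).astype(bool)

    no_scope = cohort == ""
    oow = date_known & ~((d >= w0) & (d <= w1))
    young = reg["age_at_diagnosis"].astype(float) < config.min_age
    bad_hist = ((cohort == "lung") & hist.isin(config.lung_excluded_morphology)) \
        | hist.isin(config.uncommon_histology_exclusion_set)
    unknown = ~date_known | ~res_known

    reason = np.select(
        [no_scope, oow, young, bad_hist, unknown, dco],
        ["site_histology", "out_of_window", "age", "site_histology",
         "unknown_date_or_residence", "dco"],
        default="")
    excluded = pd.DataFrame({"person_id": reg.loc[reason != "", "person_id"],
                             "reason": reason[reason != ""]})
    ok = reg[reason == ""]
    eligible = pd.DataFrame({
        "person_id": ok["person_id"],
        "cohort": cohort[reason == ""],
        "diagnosis_date": ok["diagnosis_date"],
        "age_at_diagnosis": ok["age_at_diagnosis"].astype(int),
        "age_group": ok["age_at_diagnosis"].astype(int).map(age_to_group),
        "sex": ok["sex"],
        "remoteness": ok["remoteness"],
        "ses_quintile": ok["ses_quintile"].astype(str),
        "cob_group": ok["cob_group"],
        "extent": ok["extent"],
    })
    return eligible.reset_index(drop=True), excluded.reset_index(drop=True)


def flow_table(registry: pd.DataFrame, cohort: pd.DataFrame,
               ledger: pd.DataFrame) -> pd.DataFrame:
    """Recruitment-flow summary: persons assessed, then one row per
    exclusion reason in precedence order, then the eligible count."""
    n_persons = registry["person_id"].nunique() if len(registry) else 0
    rows = [{"stage": "persons_assessed", "n": n_persons}]
    counts = ledger["reason"].value_counts() if len(ledger) else {}
    for reason in EXCLUSION_ORDER:
        rows.append({"stage": f"excluded_{reason}", "n": int(counts.get(reason, 0))})
    rows.append({"stage": "eligible", "n": len(cohort)})
    return pd.DataFrame(rows)


def split_by_membership(cohort: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """Flag each eligible person as participant or population-only.

    A person is a participant iff they appear on the cohort-study roster
    with a recruitment date strictly before their cancer diagnosis.  The
    population is everyone eligible; participants stay nested inside it.
    """
    if roster["person_id"].duplicated().any():
        dup = roster.loc[roster["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValueError(f"duplicate person_id on roster: {dup}")
    out = cohort.merge(roster[["person_id", "recruitment_date"]],
                       on="person_id", how="left")
    rec = pd.to_datetime(out["recruitment_date"])
    out["participant"] = rec.notna() & (rec < pd.to_datetime(out["diagnosis_date"]))
    return out
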