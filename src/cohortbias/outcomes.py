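"""Per-person derivation of health-service-use and survival outcomes.

Conventions (documented, configurable where noted):

* a "year" is 365 days; the prior window is ``[diagnosis-365d, diagnosis)``
  and the post window ``[diagnosis, diagnosis+365d)`` — half-open, so no
  event can fall in both;
* an admission belongs to a window by its admission date; bed-days are the
  union of stay intervals clipped at the window edges (transfers and
  nested stays are not double-counted);
* an admission is overnight iff separation date > admission date;
* the comorbidity lookback is ``[diagnosis-5x365d, diagnosis)`` over all
  hospital-recorded diagnoses; people with no admission at all in that
  window get the distinct ``no_admission`` band rather than a zero score;
* survival at k years is a plain binary (death before anchor + k x 365
  days), which requires every person's censor date to be at least three
  years after diagnosis — asserted, not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import categories as cat

logger = logging.getLogger(__name__)

YEAR_DAYS = 365


class DataError(ValueError):
    """Raised for impossible input data (e.g. death before diagnosis)."""


# --------------------------------------------------------------------------
# packaged lookups
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CharlsonCondition:
    condition: str
    weight: int
    prefixes: tuple[str, ...]


def load_charlson_map(path: str | Path | None = None) -> list[CharlsonCondition]:
    """Load the condition -> (weight, diagnosis-code prefixes) lookup.

    Ships with the classical 17-condition weighting over Quan-style
    ICD-10 prefixes; the table is data, not code, so an alternative
    mapping can be supplied via ``path``.
    """
    if path is None:
        src = resources.files("cohortbias.data") / "charlson_map.csv"
        df = pd.read_csv(src)
    else:
        df = pd.read_csv(path)
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        weights = grp["weight"].unique()
        if len(weights) != 1 or weights[0] <= 0:
            raise ValueError(f"condition {cond!r} must have one positive weight")
        prefixes = tuple(grp["prefix"].astype(str))
        if len(set(prefixes)) != len(prefixes):
            raise ValueError(f"condition {cond!r} has duplicate code prefixes")
        out.append(CharlsonCondition(cond, int(weights[0]), prefixes))
    all_prefixes = [p for c in out for p in c.prefixes]
    if len(set(all_prefixes)) != len(all_prefixes):
        raise ValueError("code prefixes must be unique across conditions")
    return out


def load_resection_codes(path: str | Path | None = None) -> dict[str, set[str]]:
    """Major-resection procedure-code sets per cancer (sentinel codes by
    default; swap in a licensed intervention-classification list via
    ``path``)."""
    if path is None:
        src = resources.files("cohortbias.data") / "resection_codes.csv"
        df = pd.read_csv(src)
    else:
        df = pd.read_csv(path)
    return {cancer: set(grp["code"].astype(str)) for cancer, grp in df.groupby("cancer")}


# --------------------------------------------------------------------------
# elementary operations (single person's events)
# --------------------------------------------------------------------------

def window_events(events: pd.DataFrame, diagnosis_date, which: str,
                  date_col: str = "admission_date",
                  year_days: int = YEAR_DAYS) -> pd.DataFrame:
    """Select events in the prior or post one-year window around diagnosis.

    prior = [diagnosis - year_days, diagnosis); post = [diagnosis,
    diagnosis + year_days).  Both half-open, so the two windows partition
    the +/- one-year band.
    """
    d = pd.Timestamp(diagnosis_date)
    t = pd.to_datetime(events[date_col])
    if which == "prior":
        mask = (t >= d - pd.Timedelta(days=year_days)) & (t < d)
    elif which == "post":
        mask = (t >= d) & (t < d + pd.Timedelta(days=year_days))
    else:
        raise ValueError("which must be 'prior' or 'post'")
    return events[mask]


def _band(count: int, labels: tuple[str, ...]) -> str:
    """Map a count to banded labels like ('0','1','2+')."""
    top = len(labels) - 1
    return labels[min(count, top)]


def count_overnight_admissions(admissions: pd.DataFrame, which: str) -> str:
    """Band the number of overnight acute admissions in a window."""
    overnight = (pd.to_datetime(admissions["separation_date"]) >
                 pd.to_datetime(admissions["admission_date"]))
    labels = cat.ADM_PRIOR_BANDS if which == "prior" else cat.ADM_POST_BANDS
    return _band(int(overnight.sum()), labels)


def _union_days(starts: np.ndarray, stops: np.ndarray) -> int:
    """Total days covered by the union of [start, stop) intervals."""
    order = np.argsort(starts, kind="mergesort")
    total = 0
    cur_lo = cur_hi = None
    for s, e in zip(starts[order], stops[order]):
        if e <= s:
            continue
        if cur_lo is None or s > cur_hi:
            if cur_lo is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = s, e
        else:
            cur_hi = max(cur_hi, e)
    if cur_lo is not None:
        total += cur_hi - cur_lo
    return int(total)


def weeks_in_hospital(admissions: pd.DataFrame, diagnosis_date, which: str,
                      year_days: int = YEAR_DAYS) -> str:
    """Band total bed-days (union of stays, clipped to the window).

    Bands: prior {zero, 1_week (1-7d), gt1_week}; post {zero, up_to_2_weeks
    (1-14d), gt2_to_4_weeks (15-28d), gt4_weeks (>28d)}.
    """
    d = pd.Timestamp(diagnosis_date)
    w0 = d - pd.Timedelta(days=year_days) if which == "prior" else d
    w1 = d if which == "prior" else d + pd.Timedelta(days=year_days)
    adm = pd.to_datetime(admissions["admission_date"])
    sep = pd.to_datetime(admissions["separation_date"])
    if (sep < adm).any():
        raise DataError("separation_date before admission_date")
    starts = np.maximum(adm.to_numpy(), np.datetime64(w0)).astype("datetime64[D]")
    stops = np.minimum(sep.to_numpy(), np.datetime64(w1)).astype("datetime64[D]")
    days = _union_days(starts.astype(int), stops.astype(int))
    days = min(days, year_days)
    if which == "prior":
        if days == 0:
            return "zero"
        return "1_week" if days <= 7 else "gt1_week"
    if days == 0:
        return "zero"
    if days <= 14:
        return "up_to_2_weeks"
    return "gt2_to_4_weeks" if days <= 28 else "gt4_weeks"


def detect_resection(admissions: pd.DataFrame, codes: set[str]
                     ) -> tuple[bool, str | None, pd.Timestamp | None]:
    """Find a major resection among (post-window) admissions.

    Returns (flag, urgency of the first resection admission, its
    admission date).
    """
    if len(admissions) == 0:
        return False, None, None
    has = admissions["procedure_codes"].fillna("").astype(str).map(
        lambda s: bool(codes.intersection(s.split(";"))) if s else False)
    hits = admissions[has]
    if len(hits) == 0:
        return False, None, None
    first = hits.sort_values("admission_date", kind="mergesort").iloc[0]
    return True, str(first["urgency"]), pd.Timestamp(first["admission_date"])


def charlson_score(admissions: pd.DataFrame,
                   cmap: list[CharlsonCondition]) -> str:
    """Charlson band from a 5-year lookback's hospital diagnosis codes.

    Each condition counts once regardless of repeat codes; codes matching
    no prefix are ignored (logged at debug level).  No admissions at all
    -> the distinct ``no_admission`` band.
    """
    if len(admissions) == 0:
        return "no_admission"
    codes: set[str] = set()
    for s in admissions["diagnosis_codes"].fillna("").astype(str):
        codes.update(c for c in s.split(";") if c)
    score = 0
    matched: set[str] = set()
    for cond in cmap:
        if any(code.startswith(p) for code in codes for p in cond.prefixes):
            score += cond.weight
            matched.update(c for c in codes
                           if any(c.startswith(p) for p in cond.prefixes))
    unknown = codes - matched
    if unknown:
        logger.debug("ignoring %d non-index diagnosis codes", len(unknown))
    if score >= 2:
        return "2+"
    return str(score)


def survival_outcomes(diagnosis_date, resection_date, death_date, censor_date,
                      year_days: int = YEAR_DAYS
                      ) -> tuple[bool, bool, bool | None]:
    """(survival_1y, survival_3y, survival_1y_postop) as plain binaries.

    Requires censor_date >= diagnosis + 3 years so three-year status is
    always ascertainable; survival_1y_postop is None without a resection.
    """
    d = pd.Timestamp(diagnosis_date)
    if pd.Timestamp(censor_date) < d + pd.Timedelta(days=3 * year_days):
        raise DataError("censor date closer than 3 years to a diagnosis; "
                        "three-year survival not ascertainable")
    death = None if pd.isna(death_date) else pd.Timestamp(death_date)
    if death is not None and death < d:
        raise DataError("death date precedes diagnosis date")

    def alive_at(anchor: pd.Timestamp, k_years: int) -> bool:
        if death is None:
            return True
        return death >= anchor + pd.Timedelta(days=k_years * year_days)

    s1 = alive_at(d, 1)
    s3 = alive_at(d, 3)
    s1_post = None
    if resection_date is not None and not pd.isna(resection_date):
        s1_post = alive_at(pd.Timestamp(resection_date), 1)
    return s1, s3, s1_post


def count_ed(ed_events: pd.DataFrame, which: str) -> str:
    """Band the number of ED attendances in a window."""
    labels = cat.ED_PRIOR_BANDS if which == "prior" else cat.ED_POST_BANDS
    return _band(len(ed_events), labels)


# --------------------------------------------------------------------------
# cohort-level derivation
# --------------------------------------------------------------------------

def derive_analysis_rows(cohort: pd.DataFrame,
                         admissions: pd.DataFrame,
                         ed: pd.DataFrame,
                         deaths: pd.DataFrame,
                         censor_date,
                         charlson_map: list[CharlsonCondition] | None = None,
                         resection_codes: dict[str, set[str]] | None = None,
                         year_days: int = YEAR_DAYS) -> pd.DataFrame:
    """Derive one analysis row per eligible person.

    ``cohort`` is the eligibility module's output (person_id, cohort,
    participant, diagnosis_date plus covariates); the admission/ED/death
    tables are record-level.  Returns the AnalysisRow table every
    estimator consumes.
    """
    cmap = charlson_map if charlson_map is not None else load_charlson_map()
    rcodes = resection_codes if resection_codes is not None else load_resection_codes()

    out_cols = [
        "person_id", "cohort", "participant", "sex", "age_group",
        "remoteness", "ses_quintile", "cob_group", "extent",
        "charlson_band", "adm_prior_band", "adm_post_band",
        "weeks_prior_band", "weeks_post_band", "ed_prior_band",
        "ed_post_band", "n_adm_private_prior", "n_adm_public_prior",
        "n_adm_private_post", "n_adm_public_post", "resection",
        "resection_urgency", "survival_1y", "survival_3y",
        "survival_1y_postop"]
    if len(cohort) == 0:
        return pd.DataFrame(columns=out_cols)

    if deaths["person_id"].duplicated().any():
        raise DataError("duplicate person_id in deaths table")

    out = cohort[["person_id", "cohort", "participant", "sex", "age_group",
                  "remoteness", "ses_quintile", "cob_group",
                  "extent"]].copy().reset_index(drop=True)
    out["participant"] = out["participant"].astype(bool)
    out["ses_quintile"] = out["ses_quintile"].astype(str)
    diag = pd.to_datetime(cohort["diagnosis_date"]).reset_index(drop=True)
    pid_index = pd.Index(out["person_id"])
    if pid_index.duplicated().any():
        raise DataError("duplicate person_id in cohort")

    # ---- survival ---------------------------------------------------------
    death = out["person_id"].map(
        dict(zip(deaths["person_id"], pd.to_datetime(deaths["death_date"]))))
    if (death < diag).any():
        raise DataError("death date precedes diagnosis date")
    if pd.Timestamp(censor_date) < diag.max() + pd.Timedelta(days=3 * year_days):
        raise DataError("censor date closer than 3 years to a diagnosis; "
                        "three-year survival not ascertainable")
    out["survival_1y"] = death.isna() | (death >= diag + pd.Timedelta(days=year_days))
    out["survival_3y"] = death.isna() | (death >= diag + pd.Timedelta(days=3 * year_days))

    # ---- admissions: window tagging ---------------------------------------
    adm = admissions.merge(
        pd.DataFrame({"person_id": out["person_id"], "diagnosis_date_x": diag,
                      "cohort_x": out["cohort"]}),
        on="person_id", how="inner")
    adm["admission_date"] = pd.to_datetime(adm["admission_date"])
    adm["separation_date"] = pd.to_datetime(adm["separation_date"])
    if (adm["separation_date"] < adm["admission_date"]).any():
        raise DataError("separation_date before admission_date in admissions")
    delta = (adm["admission_date"] - adm["diagnosis_date_x"]).dt.days
    adm["window"] = np.select(
        [(delta >= -year_days) & (delta < 0), (delta >= 0) & (delta < year_days)],
        ["prior", "post"], default="")
    adm["in_lookback"] = (delta >= -5 * year_days) & (delta < 0)
    acute = adm[adm["acute_flag"].astype(bool) & (adm["window"] != "")]

    def _per_person(series_groupby, default=0):
        return pid_index.map(series_groupby).fillna(default)

    # overnight admission counts and banding
    overnight = acute[acute["separation_date"] > acute["admission_date"]]
    for window, labels in (("prior", cat.ADM_PRIOR_BANDS),
                           ("post", cat.ADM_POST_BANDS)):
        n = _per_person(overnight[overnight["window"] == window]
                        .groupby("person_id").size()).astype(int)
        out[f"adm_{window}_band"] = np.asarray(labels, dtype=object)[
            np.minimum(n, len(labels) - 1)]

    # admission-level hospital-type counts
    for window in ("prior", "post"):
        w = acute[acute["window"] == window]
        for htype in ("private", "public"):
            out[f"n_adm_{htype}_{window}"] = _per_person(
                w[w["hospital_type"] == htype].groupby("person_id").size()
            ).astype(int)

    # ---- weeks in hospital: per person-window interval union --------------
    start_day = acute["admission_date"].to_numpy("datetime64[D]").astype(int)
    stop_day = acute["separation_date"].to_numpy("datetime64[D]").astype(int)
    d_day = acute["diagnosis_date_x"].to_numpy("datetime64[D]").astype(int)
    is_post = (acute["window"] == "post").to_numpy()
    w_lo = np.where(is_post, d_day, d_day - year_days)
    w_hi = np.where(is_post, d_day + year_days, d_day)
    lo = np.maximum(start_day, w_lo)
    hi = np.minimum(stop_day, w_hi)
    order = np.lexsort((lo, is_post, acute["person_id"].to_numpy()))
    bed_days: dict[tuple[str, bool], int] = {}
    keys = list(zip(acute["person_id"].to_numpy()[order], is_post[order]))
    lo_s, hi_s = lo[order], hi[order]
    cur_key, cur_lo, cur_hi = None, 0, 0
    for k, s, e in zip(keys, lo_s, hi_s):
        if e <= s:
            continue
        if k != cur_key:
            if cur_key is not None:
                bed_days[cur_key] = bed_days.get(cur_key, 0) + (cur_hi - cur_lo)
            cur_key, cur_lo, cur_hi = k, s, e
        elif s > cur_hi:
            bed_days[cur_key] = bed_days.get(cur_key, 0) + (cur_hi - cur_lo)
            cur_lo, cur_hi = s, e
        else:
            cur_hi = max(cur_hi, e)
    if cur_key is not None:
        bed_days[cur_key] = bed_days.get(cur_key, 0) + (cur_hi - cur_lo)

    def _week_band(pid: str, post: bool) -> str:
        d = min(bed_days.get((pid, post), 0), year_days)
        if not post:
            if d == 0:
                return "zero"
            return "1_week" if d <= 7 else "gt1_week"
        if d == 0:
            return "zero"
        if d <= 14:
            return "up_to_2_weeks"
        return "gt2_to_4_weeks" if d <= 28 else "gt4_weeks"

    out["weeks_prior_band"] = [_week_band(p, False) for p in out["person_id"]]
    out["weeks_post_band"] = [_week_band(p, True) for p in out["person_id"]]

    # ---- Charlson (5-year lookback, all admissions) ------------------------
    lb = adm[adm["in_lookback"]]
    has_adm = set(lb["person_id"])
    code_strings = lb["diagnosis_codes"].fillna("").astype(str)
    cond_weight = {c.condition: c.weight for c in cmap}
    prefix_list = [(p, c.condition) for c in cmap for p in c.prefixes]

    def _conds(s: str) -> tuple[str, ...]:
        found = {cond for code in s.split(";") if code
                 for p, cond in prefix_list if code.startswith(p)}
        return tuple(sorted(found))

    str_to_conds = {s: _conds(s) for s in code_strings.unique()}
    pairs = pd.DataFrame({
        "person_id": lb["person_id"].to_numpy(),
        "conds": code_strings.map(str_to_conds).to_numpy(),
    }).explode("conds").dropna().drop_duplicates()
    pairs["weight"] = pairs["conds"].map(cond_weight)
    score = pid_index.map(pairs.groupby("person_id")["weight"].sum()).fillna(0).astype(int)
    band = np.where(score >= 2, "2+", score.astype(str))
    band = np.where(out["person_id"].isin(has_adm), band, "no_admission")
    out["charlson_band"] = band

    # ---- resection ---------------------------------------------------------
    post_adm = acute[acute["window"] == "post"].copy()
    proc = post_adm["procedure_codes"].fillna("").astype(str)
    code_set_by_cancer = {k: frozenset(v) for k, v in rcodes.items()}

    def _is_res(codes: str, cancer: str) -> bool:
        return bool(codes) and bool(
            code_set_by_cancer[cancer].intersection(codes.split(";")))

    hit = np.fromiter((_is_res(c, k) for c, k in zip(proc, post_adm["cohort_x"])),
                      dtype=bool, count=len(post_adm))
    res_adm = (post_adm[hit].sort_values(["person_id", "admission_date"],
                                         kind="mergesort")
               .drop_duplicates("person_id", keep="first")
               .set_index("person_id"))
    out["resection"] = out["person_id"].isin(res_adm.index)
    out["resection_urgency"] = pid_index.map(res_adm["urgency"])
    out["resection_urgency"] = out["resection_urgency"].where(out["resection"], None)
    res_date = pid_index.map(res_adm["admission_date"])
    s1_post = death.isna() | (death >= res_date + pd.Timedelta(days=year_days))
    out["survival_1y_postop"] = s1_post.where(out["resection"], None)

    # ---- ED attendance ------------------------------------------------------
    edt = ed.merge(pd.DataFrame({"person_id": out["person_id"],
                                 "diagnosis_date_x": diag}),
                   on="person_id", how="inner")
    edt["attendance_date"] = pd.to_datetime(edt["attendance_date"])
    ed_delta = (edt["attendance_date"] - edt["diagnosis_date_x"]).dt.days
    for window, labels, mask in (
            ("prior", cat.ED_PRIOR_BANDS, (ed_delta >= -year_days) & (ed_delta < 0)),
            ("post", cat.ED_POST_BANDS, (ed_delta >= 0) & (ed_delta < year_days))):
        n = _per_person(edt[mask].groupby("person_id").size()).astype(int)
        out[f"ed_{window}_band"] = np.asarray(labels, dtype=object)[
            np.minimum(n, len(labels) - 1)]

    return out[out_cols]
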