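import numpy as np
import pandas as pd
import pytest

from cohortbias import outcomes
from cohortbias.outcomes import (DataError, charlson_score,
                                 count_ed, count_overnight_admissions,
                                 detect_resection, load_charlson_map,
                                 load_resection_codes, survival_outcomes,
                                 weeks_in_hospital, window_events)

DX = pd.Timestamp("2010-06-01")


def _adm(dates_stays, urgency="planned_other", hospital="public",
         proc="", codes="", acute=True):
    rows = []
    for start, stay in dates_stays:
        start = pd.Timestamp(start)
        rows.append({"admission_date": start,
                     "separation_date": start + pd.Timedelta(days=stay),
                     "hospital_type": hospital, "urgency": urgency,
                     "acute_flag": acute, "procedure_codes": proc,
                     "diagnosis_codes": codes})
    return pd.DataFrame(rows, columns=["admission_date", "separation_date",
                                       "hospital_type", "urgency", "acute_flag",
                                       "procedure_codes", "diagnosis_codes"])


class TestWindows:
    @pytest.mark.parametrize("offset,expected", [
        (0, "post"), (364, "post"), (365, None),
        (-1, "prior"), (-365, "prior"), (-366, None),
    ])
    def test_half_open_boundaries(self, offset, expected):
        ev = _adm([(DX + pd.Timedelta(days=offset), 1)])
        got = None
        for which in ("prior", "post"):
            if len(window_events(ev, DX, which)):
                got = which
        assert got == expected

    def test_windows_partition_the_band(self):
        rng = np.random.default_rng(0)
        offsets = rng.integers(-400, 400, size=60)
        ev = _adm([(DX + pd.Timedelta(days=int(o)), 1) for o in offsets])
        prior = window_events(ev, DX, "prior")
        post = window_events(ev, DX, "post")
        assert len(prior) + len(post) == int(((offsets >= -365) & (offsets < 365)).sum())
        assert not set(prior.index) & set(post.index)


class TestAdmissionBands:
    def test_sameday_only_is_zero(self):
        assert count_overnight_admissions(_adm([(DX, 0)]), "post") == "0"

    def test_two_overnight_prior_is_two_plus(self):
        adm = _adm([(DX - pd.Timedelta(days=100), 2),
                    (DX - pd.Timedelta(days=50), 1)])
        assert count_overnight_admissions(adm, "prior") == "2+"

    def test_five_overnight_post_is_three_plus(self):
        adm = _adm([(DX + pd.Timedelta(days=10 * k), 1) for k in range(1, 6)])
        assert count_overnight_admissions(adm, "post") == "3+"


class TestWeeksInHospital:
    def test_no_admissions_zero(self):
        assert weeks_in_hospital(_adm([]), DX, "post") == "zero"

    def test_thirty_bed_days_exceeds_four_weeks(self):
        adm = _adm([(DX + pd.Timedelta(days=5), 30)])
        assert weeks_in_hospital(adm, DX, "post") == "gt4_weeks"

    def test_overlapping_stays_union_not_sum(self):
        """Stays over days 1-10 and 5-12 cover 11 distinct days, not 17."""
        adm = _adm([(DX + pd.Timedelta(days=1), 9),
                    (DX + pd.Timedelta(days=5), 7)])
        # 11 bed-days -> up to 2 weeks; the naive sum (16) would also band
        # there, so check the union length directly too
        from cohortbias.outcomes import _union_days

        starts = np.array([1, 5])
        stops = np.array([10, 12])
        assert _union_days(starts, stops) == 11
        assert weeks_in_hospital(adm, DX, "post") == "up_to_2_weeks"

    def test_clipped_at_window_edge(self):
        """A stay crossing the window end contributes only in-window days,
        so total bed-days never exceed the window length."""
        adm = _adm([(DX + pd.Timedelta(days=360), 40)])
        assert weeks_in_hospital(adm, DX, "post") == "up_to_2_weeks"  # 5 days

    def test_separation_before_admission_rejected(self):
        adm = _adm([(DX, 3)])
        adm.loc[0, "separation_date"] = adm.loc[0, "admission_date"] - \
            pd.Timedelta(days=1)
        with pytest.raises(DataError):
            weeks_in_hospital(adm, DX, "post")


class TestResection:
    CODES = {"RES-B01", "RES-B02"}

    def test_emergency_resection_detected(self):
        adm = _adm([(DX + pd.Timedelta(days=10), 7)], urgency="emergency",
                   proc="RES-B01")
        flag, urgency, date = detect_resection(adm, self.CODES)
        assert flag and urgency == "emergency"
        assert date == DX + pd.Timedelta(days=10)

    def test_no_codes_no_resection(self):
        flag, urgency, date = detect_resection(_adm([(DX, 3)]), self.CODES)
        assert not flag and urgency is None and date is None

    def test_first_resection_sets_urgency(self):
        adm = pd.concat([
            _adm([(DX + pd.Timedelta(days=5), 7)], urgency="planned_other",
                 proc="RES-B01"),
            _adm([(DX + pd.Timedelta(days=40), 7)], urgency="emergency",
                 proc="RES-B02"),
        ], ignore_index=True)
        flag, urgency, _ = detect_resection(adm, self.CODES)
        assert flag and urgency == "planned_other"


class TestCharlson:
    CMAP = load_charlson_map()

    def test_no_admissions_distinct_band(self):
        assert charlson_score(_adm([]), self.CMAP) == "no_admission"

    def test_admission_without_conditions_scores_zero(self):
        adm = _adm([(DX - pd.Timedelta(days=400), 2)], codes="R69")
        assert charlson_score(adm, self.CMAP) == "0"

    def test_repeat_codes_count_once(self):
        """Diabetes (weight 1) coded three times plus a tumour code
        (weight 2) gives score 3, band 2+."""
        adm = _adm([(DX - pd.Timedelta(days=300 + 30 * k), 1) for k in range(3)])
        adm["diagnosis_codes"] = ["E119", "E119;C50", "E119"]
        assert charlson_score(adm, self.CMAP) == "2+"

    def test_single_condition_band_one(self):
        adm = _adm([(DX - pd.Timedelta(days=200), 1)], codes="J44")
        assert charlson_score(adm, self.CMAP) == "1"

    def test_adding_condition_never_lowers_band(self):
        order = {"0": 0, "1": 1, "2+": 2}
        adm1 = _adm([(DX - pd.Timedelta(days=200), 1)], codes="I50")
        adm2 = adm1.copy()
        adm2["diagnosis_codes"] = "I50;N18"
        assert order[charlson_score(adm2, self.CMAP)] >= \
            order[charlson_score(adm1, self.CMAP)]


class TestSurvival:
    CENSOR = DX + pd.Timedelta(days=4 * 365)

    @pytest.mark.parametrize("death_day,s1,s3", [
        (200, False, False), (400, True, False), (None, True, True),
        (365, True, False), (1095, True, True),
    ])
    def test_binary_horizons(self, death_day, s1, s3):
        death = None if death_day is None else DX + pd.Timedelta(days=death_day)
        got1, got3, _ = survival_outcomes(DX, None, death, self.CENSOR)
        assert (got1, got3) == (s1, s3)
        assert got1 or not got3  # 3-year survival implies 1-year survival

    def test_postop_anchor(self):
        res = DX + pd.Timedelta(days=30)
        death = DX + pd.Timedelta(days=380)  # >1y post-dx, <1y post-op
        s1, _, s1_post = survival_outcomes(DX, res, death, self.CENSOR)
        assert s1 and s1_post is False

    def test_death_before_diagnosis_rejected(self):
        with pytest.raises(DataError):
            survival_outcomes(DX, None, DX - pd.Timedelta(days=1), self.CENSOR)

    def test_censor_too_close_rejected(self):
        with pytest.raises(DataError):
            survival_outcomes(DX, None, None, DX + pd.Timedelta(days=600))


class TestEd:
    def _ed(self, offsets):
        return pd.DataFrame({"attendance_date":
                             [DX + pd.Timedelta(days=o) for o in offsets]})

    def test_zero_band(self):
        assert count_ed(self._ed([]), "post") == "0"

    def test_four_events_top_band(self):
        assert count_ed(self._ed([1, 2, 3, 4]), "post") == "3+"

    def test_prior_bands_cap_at_two_plus(self):
        assert count_ed(self._ed([]), "prior") == "0"
        assert count_ed(self._ed([1, 2, 3]), "prior") == "2+"


class TestDeriveAnalysisRows:
    def test_band_partition_and_consistency(self, sim_rows):
        """Every person lands in exactly one valid band per outcome, and
        the cross-outcome logical invariants hold."""
        from cohortbias import categories as cat

        rows = sim_rows
        assert rows["adm_prior_band"].isin(cat.ADM_PRIOR_BANDS).all()
        assert rows["adm_post_band"].isin(cat.ADM_POST_BANDS).all()
        assert rows["weeks_prior_band"].isin(cat.WEEKS_PRIOR_BANDS).all()
        assert rows["weeks_post_band"].isin(cat.WEEKS_POST_BANDS).all()
        assert rows["charlson_band"].isin(cat.CHARLSON_BANDS).all()
        # 3-year survival implies 1-year survival
        assert not (rows["survival_3y"] & ~rows["survival_1y"]).any()
        # urgency and post-operative survival defined iff resection
        has_res = rows["resection"]
        assert rows.loc[has_res, "resection_urgency"].notna().all()
        assert rows.loc[~has_res, "resection_urgency"].isna().all()
        assert rows.loc[has_res, "survival_1y_postop"].notna().all()
        assert rows.loc[~has_res, "survival_1y_postop"].isna().all()

    def test_matches_elementary_operations(self, sim_dataset):
        """The vectorised derivation agrees with the per-person elementary
        operations on a subsample of people."""
        from cohortbias import eligibility

        ds = sim_dataset
        cohort, _ = eligibility.select_index_cases(ds.registry)
        cohort = eligibility.split_by_membership(cohort, ds.roster)
        cohort = cohort.head(150)
        rows = outcomes.derive_analysis_rows(
            cohort, ds.admissions, ds.ed, ds.deaths, ds.censor_date)
        cmap = load_charlson_map()
        rcodes = load_resection_codes()
        adm_all = ds.admissions.set_index("person_id", drop=False)
        ed_all = ds.ed.set_index("person_id", drop=False)
        dmap = dict(zip(ds.deaths["person_id"], ds.deaths["death_date"]))
        for rec in rows.head(60).itertuples(index=False):
            d = cohort.set_index("person_id").loc[rec.person_id, "diagnosis_date"]
            pa = adm_all.loc[[rec.person_id]] if rec.person_id in adm_all.index \
                else ds.admissions.iloc[0:0]
            pe = ed_all.loc[[rec.person_id]] if rec.person_id in ed_all.index \
                else ds.ed.iloc[0:0]
            acute = pa[pa["acute_flag"].astype(bool)]
            prior = window_events(acute, d, "prior")
            post = window_events(acute, d, "post")
            assert rec.adm_prior_band == count_overnight_admissions(prior, "prior")
            assert rec.adm_post_band == count_overnight_admissions(post, "post")
            assert rec.weeks_prior_band == weeks_in_hospital(prior, d, "prior")
            assert rec.weeks_post_band == weeks_in_hospital(post, d, "post")
            lb = pa[(pa["admission_date"] >= d - pd.Timedelta(days=5 * 365))
                    & (pa["admission_date"] < d)]
            assert rec.charlson_band == charlson_score(lb, cmap)
            flag, urgency, res_date = detect_resection(post, rcodes[rec.cohort])
            assert rec.resection == flag
            s1, s3, s1p = survival_outcomes(d, res_date, dmap.get(rec.person_id),
                                            ds.censor_date)
            assert (rec.survival_1y, rec.survival_3y) == (s1, s3)
            ed_post = window_events(pe, d, "post", date_col="attendance_date")
            assert rec.ed_post_band == count_ed(ed_post, "post")

    def test_empty_cohort(self, sim_dataset):
        ds = sim_dataset
        empty = pd.DataFrame(columns=["person_id", "cohort", "participant",
                                      "diagnosis_date", "sex", "age_group",
                                      "remoteness", "ses_quintile", "cob_group",
                                      "extent"])
        rows = outcomes.derive_analysis_rows(empty, ds.admissions, ds.ed,
                                             ds.deaths, ds.censor_date)
        assert len(rows) == 0
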