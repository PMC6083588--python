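import math

import numpy as np
import pandas as pd
import pytest

from cohortbias.association_bias import (ModelSpec, bias_panel,
                                         default_model_specs, fit_logistic,
                                         ror)
from cohortbias.calibration import logistic_recovery


def _two_by_two(a, b, c, d):
    """Person rows for a 2x2 table: exposed yes/no x outcome yes/no."""
    rows = ([{"exposed": "yes", "survival_1y": True}] * a +
            [{"exposed": "yes", "survival_1y": False}] * b +
            [{"exposed": "no", "survival_1y": True}] * c +
            [{"exposed": "no", "survival_1y": False}] * d)
    df = pd.DataFrame(rows)
    df["participant"] = True
    return df


BINARY_SPEC = ModelSpec("survival_1y", risk_factors=("exposed",), adjusters=(),
                        references={"exposed": "no"})


class TestFitLogistic:
    def test_matches_cross_product_oracle(self):
        """An unadjusted single-factor fit equals the closed-form 2x2 odds
        ratio ad/bc with SE sqrt(1/a+1/b+1/c+1/d), across random tables."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            a, b, c, d = rng.integers(3, 80, size=4)
            fit = fit_logistic(_two_by_two(a, b, c, d), BINARY_SPEC,
                               "population", min_events_per_param=0)
            term = fit.term("exposed", "yes")
            expected_or = (a * d) / (b * c)
            expected_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert math.exp(term.coef) == pytest.approx(expected_or, rel=1e-6)
            assert term.se == pytest.approx(expected_se, rel=1e-6)

    def test_degenerate_outcome_flagged(self):
        df = _two_by_two(5, 0, 7, 0)  # everyone has the outcome
        fit = fit_logistic(df, BINARY_SPEC, "population", min_events_per_param=0)
        assert fit.status == "degenerate_outcome"

    def test_sparse_flag(self):
        fit = fit_logistic(_two_by_two(4, 4, 4, 4), BINARY_SPEC, "population",
                           min_events_per_param=10)
        assert fit.sparse

    def test_parameter_recovery_from_generator(self):
        """A known quintile-5 log-odds is recovered from the package's own
        population generator (modest n here; the full-scale check runs in
        the acceptance suite)."""
        coef = logistic_recovery(n=20_000, target_logodds=0.5, seed=11)
        assert coef == pytest.approx(0.5, abs=0.1)


class TestRor:
    def test_identical_fits_give_unit_ror(self):
        df = _two_by_two(20, 30, 40, 25)
        sub = fit_logistic(df, BINARY_SPEC, "subsample", min_events_per_param=0)
        pop = fit_logistic(df, BINARY_SPEC, "population", min_events_per_param=0)
        with pytest.warns(UserWarning, match="floored"):
            res = ror(sub, pop)
        assert res[0].ror == pytest.approx(1.0)
        assert res[0].status == "se_floored"

    def test_nested_subsample_ror(self):
        rng = np.random.default_rng(5)
        df = _two_by_two(60, 70, 80, 90)
        df["participant"] = rng.random(len(df)) < 0.4
        sub = fit_logistic(df, BINARY_SPEC, "subsample", min_events_per_param=0)
        pop = fit_logistic(df, BINARY_SPEC, "population", min_events_per_param=0)
        res = ror(sub, pop)[0]
        assert res.ror == pytest.approx(res.or_sub / res.or_pop)
        assert res.cl_lower <= res.ror <= res.cl_upper
        assert res.se_ln_or_sub > res.se_ln_or_pop

    def test_reference_relabelling_reciprocal(self):
        """Swapping the reference level inverts the OR and the ROR."""
        rng = np.random.default_rng(9)
        df = _two_by_two(60, 70, 80, 90)
        df["participant"] = rng.random(len(df)) < 0.4
        spec_rev = ModelSpec("survival_1y", risk_factors=("exposed",),
                             adjusters=(), references={"exposed": "yes"})
        res_fwd = ror(fit_logistic(df, BINARY_SPEC, "subsample", 0),
                      fit_logistic(df, BINARY_SPEC, "population", 0))[0]
        res_rev = ror(fit_logistic(df, spec_rev, "subsample", 0),
                      fit_logistic(df, spec_rev, "population", 0))[0]
        assert res_rev.or_pop == pytest.approx(1 / res_fwd.or_pop, rel=1e-6)
        assert res_rev.ror == pytest.approx(1 / res_fwd.ror, rel=1e-6)

    def test_mismatched_outcomes_rejected(self):
        df = _two_by_two(20, 30, 40, 25)
        df["resection"] = df["survival_1y"]
        df["weeks_post_band"] = "zero"
        fit_a = fit_logistic(df, BINARY_SPEC, "population", 0)
        spec_b = ModelSpec("resection", risk_factors=("exposed",), adjusters=(),
                           references={"exposed": "no"})
        fit_b = fit_logistic(df, spec_b, "population", 0)
        with pytest.raises(ValueError, match="different outcomes"):
            ror(fit_a, fit_b)


class TestBiasPanel:
    def test_panel_on_simulated_cohort(self, sim_rows):
        """The four-outcome panel runs end-to-end on simulated data and
        reports RORs (or explicit refusals) for every risk factor."""
        panel = bias_panel(sim_rows[sim_rows["cohort"] == "bowel"],
                           min_events_per_param=2)
        assert set(panel["outcome"]) == {"resection", "gt4_weeks", "gt2_ed",
                                         "survival_1y"}
        ok = panel[panel["status"] == "ok"]
        assert len(ok) > 0
        assert (ok["cl_lower"] <= ok["cl_upper"]).all()
        assert set(ok["factor"]) <= {"remoteness", "ses_quintile", "cob_group",
                                     "charlson_band"}
        assert {"multivariable", "univariable"} == set(panel["model"])

    def test_tiny_cohort_refused_with_smallness_flag(self, toy_registry):
        """A handful of people cannot support the multivariable models; the
        panel refuses with an explicit flag instead of fitting."""
        from cohortbias.eligibility import select_index_cases, split_by_membership

        cohort, _ = select_index_cases(toy_registry)
        roster = pd.DataFrame({"person_id": ["P01"],
                               "recruitment_date": ["2005-01-01"]})
        cohort = split_by_membership(cohort, roster)
        rows = cohort.copy()
        rows["resection"] = [True, False, True, False, True]
        rows["weeks_post_band"] = "zero"
        rows["ed_post_band"] = "0"
        rows["survival_1y"] = True
        rows["charlson_band"] = "0"
        panel = bias_panel(rows, [ModelSpec("resection")],
                           include_univariable=False)
        assert (panel["status"] != "ok").all()
        assert panel["status"].isin(["too_few_events",
                                     "degenerate_outcome"]).all()
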