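import math

import numpy as np
import pandas as pd
import pytest

from cohortbias.calibration import latent_participation_gap
from cohortbias.synthetic_data import (BinaryModel, DependenceTerm,
                                       OutcomeSpec, ParticipationSpec,
                                       PopulationSpec, assign_participation,
                                       default_covariate_distributions,
                                       generate_events, generate_population,
                                       simulate, specs_from_truth)
from cohortbias.scenarios import selection_scenario


def _pop_spec(n, seed=1, **kw):
    return PopulationSpec(n_persons=n, seed=seed, **kw)


class TestGeneratePopulation:
    def test_marginal_convergence(self):
        dists = default_covariate_distributions()
        dists["sex"] = {"male": 0.54, "female": 0.46}
        pop = generate_population(_pop_spec(100_000, covariate_distributions=dists))
        assert abs((pop["sex"] == "male").mean() - 0.54) < 0.01

    def test_degenerate_distribution(self):
        dists = default_covariate_distributions()
        dists["remoteness"] = {"major_city": 1.0, "inner_regional": 0.0,
                               "outer_regional_remote": 0.0}
        pop = generate_population(_pop_spec(2_000, covariate_distributions=dists))
        assert (pop["remoteness"] == "major_city").all()

    def test_dependence_term_odds_ratio(self):
        """The empirical odds ratio between the two flagged indicators
        matches exp(theta) of the log-linear construction."""
        theta = 0.5
        spec = _pop_spec(200_000, covariate_dependence=[
            DependenceTerm("remoteness", "major_city", "ses_quintile", "1", theta)])
        pop = generate_population(spec)
        a = (pop["remoteness"] == "major_city").to_numpy()
        b = (pop["ses_quintile"] == "1").to_numpy()
        tab = np.array([[(a & b).sum(), (a & ~b).sum()],
                        [(~a & b).sum(), (~a & ~b).sum()]], dtype=float)
        emp_or = (tab[0, 0] * tab[1, 1]) / (tab[0, 1] * tab[1, 0])
        assert abs(emp_or - math.exp(theta)) / math.exp(theta) < 0.10

    def test_invalid_probability_vector_names_covariate(self):
        dists = default_covariate_distributions()
        dists["cob_group"] = {k: v * 2 for k, v in dists["cob_group"].items()}
        with pytest.raises(ValueError, match="cob_group"):
            generate_population(_pop_spec(100, covariate_distributions=dists))

    def test_reproducible(self):
        p1 = generate_population(_pop_spec(5_000, seed=11))
        p2 = generate_population(_pop_spec(5_000, seed=11))
        pd.testing.assert_frame_equal(p1, p2)


class TestParticipation:
    def test_null_baseline_rate(self):
        pop = generate_population(_pop_spec(60_000))
        pspec = ParticipationSpec(baseline_logodds=math.log(0.10 / 0.90),
                                  design_multipliers={})
        part = assign_participation(pop, pspec, seed=2)
        assert abs(part["participant"].mean() - 0.10) < 0.01

    def test_rural_oversampling_factor_two(self):
        """A x2 design multiplier doubles the participation probability of
        rural residents while major-city residents stay at baseline."""
        pop = generate_population(_pop_spec(60_000))
        pspec = ParticipationSpec(
            baseline_logodds=math.log(0.10 / 0.90),
            design_multipliers={"remoteness": {"inner_regional": 2.0,
                                               "outer_regional_remote": 2.0}})
        part = assign_participation(pop, pspec, seed=2)
        rate = part["participant"].groupby(pop["remoteness"].to_numpy()).mean()
        assert abs(rate["major_city"] - 0.10) < 0.012
        assert abs(rate["inner_regional"] - 0.20) < 0.02

    def test_certainty_stratum_all_sampled(self):
        pop = generate_population(_pop_spec(5_000))
        pspec = ParticipationSpec(
            design_multipliers={"remoteness": {"outer_regional_remote": math.inf}})
        part = assign_participation(pop, pspec, seed=3)
        remote = (pop["remoteness"] == "outer_regional_remote").to_numpy()
        assert part.loc[remote, "participant"].all()

    def test_negative_multiplier_rejected(self):
        pop = generate_population(_pop_spec(100))
        pspec = ParticipationSpec(design_multipliers={"remoteness":
                                                      {"major_city": -1.0}})
        with pytest.raises(ValueError, match="multiplier"):
            assign_participation(pop, pspec, seed=1)

    def test_health_dependent_participation(self):
        """With a positive latent loading, participants are healthier than
        non-participants on the latent propensity."""
        m_in, m_out = latent_participation_gap(outcome_dependence=0.5, seed=5)
        assert m_in > m_out + 0.05

    def test_recruitment_dates_inside_window(self):
        pop = generate_population(_pop_spec(5_000))
        pspec = ParticipationSpec()
        part = assign_participation(pop, pspec, seed=4)
        rec = part.loc[part["participant"], "recruitment_date"]
        lo, hi = pspec.recruitment_window
        assert (rec >= pd.Timestamp(lo)).all() and (rec <= pd.Timestamp(hi)).all()


class TestGenerateEvents:
    def test_covariate_free_survival_matches_intercept(self):
        """With all effects and loadings zero, empirical one-year survival
        equals the intercept-implied probability in every stratum."""
        spec = OutcomeSpec()
        p = 0.83
        b = math.log(p / (1 - p))
        spec.survival1_model = BinaryModel(intercept={"bowel": b, "lung": b})
        spec.survival3_model = BinaryModel(intercept={"bowel": b, "lung": b})
        pop = generate_population(_pop_spec(40_000))
        ev = generate_events(pop, spec, seed=9)
        death = pop["person_id"].map(
            dict(zip(ev["deaths"]["person_id"], ev["deaths"]["death_date"])))
        one_year = pd.to_datetime(pop["diagnosis_date"]) + pd.Timedelta(days=365)
        surv1 = death.isna() | (death >= one_year)
        assert abs(surv1.mean() - p) < 0.01

    def test_ed_coverage_thinning_is_nested(self):
        """Datasets differing only in ED coverage share events: full
        coverage keeps a superset of any thinned dataset, and zero
        coverage keeps nothing."""
        pop = generate_population(_pop_spec(4_000))

        def events(coverage):
            spec = OutcomeSpec()
            spec.ed_coverage_by_remoteness = {k: coverage for k in
                                              spec.ed_coverage_by_remoteness}
            ev = generate_events(pop, spec, seed=13)
            return set(map(tuple, ev["ed"].itertuples(index=False)))

        full, half, none = events(1.0), events(0.5), events(0.0)
        assert half < full
        assert none == set()

    def test_impossible_resection_never_occurs(self):
        spec = OutcomeSpec()
        spec.resection_model.effects = {"extent": {"distant": -math.inf}}
        pop = generate_population(_pop_spec(4_000))
        ev = generate_events(pop, spec, seed=17)
        adm = ev["admissions"]
        res = adm[adm["procedure_codes"].str.startswith("RES", na=False)]
        distant = set(pop.loc[pop["extent"] == "distant", "person_id"])
        assert not set(res["person_id"]) & distant

    def test_no_event_after_death(self):
        pop = generate_population(_pop_spec(4_000))
        ev = generate_events(pop, OutcomeSpec(), seed=19)
        dmap = dict(zip(ev["deaths"]["person_id"], ev["deaths"]["death_date"]))
        adm = ev["admissions"]
        dd = adm["person_id"].map(dmap)
        assert (dd.isna() | (adm["admission_date"] <= dd)).all()
        assert (dd.isna() | (adm["separation_date"] <= dd)).all()
        de = ev["ed"]["person_id"].map(dmap)
        assert (de.isna() | (ev["ed"]["attendance_date"] <= de)).all()


class TestSimulate:
    def test_byte_identical_given_seed(self, tmp_path):
        pop, part, osp = selection_scenario(1_500, seed=21)
        for sub in ("a", "b"):
            simulate(pop, part, osp, seed=21).write(tmp_path / sub)
        for name in ("registry", "admissions", "ed", "deaths", "roster"):
            fa = (tmp_path / "a" / f"{name}.csv").read_bytes()
            fb = (tmp_path / "b" / f"{name}.csv").read_bytes()
            assert fa == fb, name
        assert (tmp_path / "a" / "truth.json").read_bytes() == \
               (tmp_path / "b" / "truth.json").read_bytes()

    def test_truth_round_trip(self, tmp_path):
        pop, part, osp = selection_scenario(500, seed=23)
        ds = simulate(pop, part, osp, seed=23)
        ds.write(tmp_path)
        from cohortbias.synthetic_data import LinkedDataset

        back = LinkedDataset.read(tmp_path)
        p2, q2, o2 = specs_from_truth(back.truth)
        assert p2.to_dict() == pop.to_dict()
        assert q2.to_dict() == part.to_dict()
        assert o2.to_dict() == osp.to_dict()

    def test_censor_date_covers_three_years(self, sim_dataset):
        last_dx = pd.to_datetime(sim_dataset.registry["diagnosis_date"]).max()
        assert pd.Timestamp(sim_dataset.censor_date) >= \
            last_dx + pd.Timedelta(days=3 * 365)

    def test_roster_ids_in_registry(self, sim_dataset):
        assert set(sim_dataset.roster["person_id"]) <= \
            set(sim_dataset.registry["person_id"])
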