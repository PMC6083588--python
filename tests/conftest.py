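import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def _rec(pid, site, date, age, *, hist="M8140", dco=False, res_known=True,
         date_known=True, sex="male", remoteness="major_city", ses="3",
         cob="australia", extent="localised"):
    return {
        "person_id": pid, "cancer_site_code": site, "histology_code": hist,
        "diagnosis_date": date, "age_at_diagnosis": age, "sex": sex,
        "remoteness": remoteness, "ses_quintile": ses, "cob_group": cob,
        "extent": extent, "dco_flag": dco, "residence_known": res_known,
        "diagnosis_date_known": date_known,
    }


@pytest.fixture
def toy_registry() -> pd.DataFrame:
    """Handcrafted registry: 10 persons, of whom 5 are eligible and 5 hit
    one exclusion rule each (age, DCO, prior cancer, multiple primary,
    small-cell histology)."""
    rows = [
        _rec("P01", "C18", "2008-06-01", 60),
        _rec("P02", "C34", "2009-01-15", 70, sex="female"),
        _rec("P03", "C18", "2008-06-01", 44),                      # under age
        _rec("P04", "C19", "2008-06-01", 66, dco=True),            # DCO
        _rec("P05", "C50", "2003-03-01", 58),                      # prior cancer...
        _rec("P05", "C18", "2008-05-01", 63),                      # ...before this index
        _rec("P06", "C18", "2008-01-01", 72),                      # index...
        _rec("P06", "C34", "2008-03-01", 72),                      # ...second primary +60d
        _rec("P07", "C34", "2010-02-01", 68, hist="M8041"),        # small cell
        _rec("P08", "C19", "2006-02-01", 45, remoteness="inner_regional"),
        _rec("P09", "C34", "2012-12-31", 85, ses="5"),
        _rec("P10", "C20", "2010-07-15", 77, cob="non_english", extent="distant"),
    ]
    df = pd.DataFrame(rows)
    df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"])
    return df


TOY_EXPECTED_ELIGIBLE = {"P01", "P02", "P08", "P09", "P10"}
TOY_EXPECTED_REASONS = {
    "P03": "age",
    "P04": "dco",
    "P05": "prior_cancer",
    "P06": "multiple_primary",
    "P07": "site_histology",
}


@pytest.fixture(scope="session")
def sim_dataset():
    """One moderately sized simulated linked dataset (selection scenario),
    shared across tests."""
    from cohortbias.scenarios import selection_scenario
    from cohortbias.synthetic_data import simulate

    pop, part, osp = selection_scenario(12_000, seed=7)
    return simulate(pop, part, osp, seed=7)


@pytest.fixture(scope="session")
def sim_rows(sim_dataset):
    """Derived analysis rows for the shared simulated dataset."""
    from cohortbias import eligibility, outcomes

    cohort, _ = eligibility.select_index_cases(sim_dataset.registry)
    cohort = eligibility.split_by_membership(cohort, sim_dataset.roster)
    return outcomes.derive_analysis_rows(
        cohort, sim_dataset.admissions, sim_dataset.ed,
        sim_dataset.deaths, sim_dataset.censor_date)
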