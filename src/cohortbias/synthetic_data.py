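"""Seeded generator for linked cancer-registry / hospital / ED / death data.

The generator emulates the statistical structure a linkage-based
self-selection analysis assumes: a source population of cancer patients
with joint demographic covariates, a cohort-study participation process
with covariate-dependent log-odds plus designed oversampling, and
health-service-use / survival outcome processes that may share a latent
health propensity with participation (the collider knob).

Design notes
------------
* Covariates are drawn from an explicit joint table built as the product
  of the configured marginals times ``exp(theta)`` log-linear association
  terms, so the pairwise odds ratio between any two flagged categories is
  exactly ``exp(theta)`` by construction (checkable by tabulation).
* A per-person standard-normal latent health propensity enters
  participation and every outcome linearly on the log-odds / log-rate
  scale; higher values mean better health.
* Extent of disease is drawn conditionally on cancer type (its
  distribution differs strongly between bowel and lung cancer) and is
  therefore not available to the log-linear dependence machinery.
* Design multipliers act on the probability scale and are capped at 1;
  ``math.inf`` expresses a take-everyone stratum.
* ED events are generated first and thinned afterwards with a dedicated
  random stream, so datasets that differ only in ED coverage share the
  same underlying events.

All randomness flows from numpy ``default_rng``; identical specs and seed
produce byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import categories as cat
from ._util import as_date, logit, spawn_seeds

DAY = np.timedelta64(1, "D")


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

def default_covariate_distributions() -> dict[str, dict[str, float]]:
    """Marginals matching the source-population mix of a combined
    bowel + lung cancer cohort aged 45+ (NSW-like)."""
    return {
        "sex": {"male": 0.56, "female": 0.44},
        "age_group": {
            "45-54": 0.089, "55-64": 0.213, "65-74": 0.308,
            "75-84": 0.285, "85+": 0.105,
        },
        "remoteness": {
            "major_city": 0.664, "inner_regional": 0.246,
            "outer_regional_remote": 0.090,
        },
        "ses_quintile": {"1": 0.144, "2": 0.168, "3": 0.193, "4": 0.232, "5": 0.263},
        "cob_group": {
            "australia": 0.670, "other_english": 0.094,
            "non_english": 0.200, "unknown": 0.036,
        },
    }


def default_extent_by_cancer() -> dict[str, dict[str, float]]:
    return {
        "bowel": {"localised": 0.314, "regional": 0.426, "distant": 0.197, "unknown": 0.063},
        "lung": {"localised": 0.184, "regional": 0.213, "distant": 0.457, "unknown": 0.146},
    }


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class DependenceTerm:
    """Log-linear association between two covariate categories.

    The joint cell probability is multiplied by ``exp(log_or)`` whenever
    both indicated categories co-occur, which makes ``exp(log_or)`` the
    odds ratio between the two binary indicators.
    """

    covariate_a: str
    category_a: str
    covariate_b: str
    category_b: str
    log_or: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CancerMix:
    """Bowel vs lung assignment: logistic in covariates and latent health."""

    p_lung: float = 0.39
    logodds: dict[str, dict[str, float]] = field(default_factory=dict)
    latent_loading: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PopulationSpec:
    n_persons: int
    covariate_distributions: dict[str, dict[str, float]] = field(
        default_factory=default_covariate_distributions)
    covariate_dependence: list[DependenceTerm] = field(default_factory=list)
    cancer_mix: CancerMix = field(default_factory=CancerMix)
    extent_by_cancer: dict[str, dict[str, float]] = field(
        default_factory=default_extent_by_cancer)
    diagnosis_window: tuple[dt.date, dt.date] = (
        dt.date(2006, 2, 1), dt.date(2012, 12, 31))
    seed: int = 0

    def __post_init__(self) -> None:
        self.diagnosis_window = tuple(as_date(d) for d in self.diagnosis_window)

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        start, end = self.diagnosis_window
        if not start < end:
            raise ValueError("diagnosis_window start must precede end")
        for cov, dist in self.covariate_distributions.items():
            if cov not in cat.COVARIATES:
                raise ValueError(f"unknown covariate {cov!r}")
            if set(dist) != set(cat.COVARIATES[cov]):
                raise ValueError(f"covariate {cov!r}: categories {sorted(dist)} "
                                 f"do not match {sorted(cat.COVARIATES[cov])}")
            if any(p < 0 for p in dist.values()) or abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"covariate {cov!r}: probabilities must be "
                                 "non-negative and sum to 1 within 1e-9")
        for cancer, dist in self.extent_by_cancer.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9 or any(p < 0 for p in dist.values()):
                raise ValueError(f"extent distribution for {cancer!r}: "
                                 "probabilities must sum to 1 within 1e-9")
        for term in self.covariate_dependence:
            for cov in (term.covariate_a, term.covariate_b):
                if cov == "extent":
                    raise ValueError("covariate 'extent' is drawn per cancer type "
                                     "and cannot carry dependence terms")
                if cov not in self.covariate_distributions:
                    raise ValueError(f"dependence term references unknown covariate {cov!r}")
        if not 0.0 < self.cancer_mix.p_lung < 1.0:
            raise ValueError("cancer_mix.p_lung must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_persons": self.n_persons,
            "covariate_distributions": self.covariate_distributions,
            "covariate_dependence": [t.to_dict() for t in self.covariate_dependence],
            "cancer_mix": self.cancer_mix.to_dict(),
            "extent_by_cancer": self.extent_by_cancer,
            "diagnosis_window": [d.isoformat() for d in self.diagnosis_window],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(
            n_persons=d["n_persons"],
            covariate_distributions=d["covariate_distributions"],
            covariate_dependence=[DependenceTerm(**t) for t in d["covariate_dependence"]],
            cancer_mix=CancerMix(**d["cancer_mix"]),
            extent_by_cancer=d["extent_by_cancer"],
            diagnosis_window=tuple(d["diagnosis_window"]),
            seed=d["seed"],
        )


def default_design_multipliers() -> dict[str, dict[str, float]]:
    """The cohort study's designed oversampling: people aged 85+ and rural
    residents sampled at twice the base probability.  Use ``math.inf`` on a
    remoteness level to express a take-everyone (certainty) stratum."""
    return {
        "age_group": {"85+": 2.0},
        "remoteness": {"inner_regional": 2.0, "outer_regional_remote": 2.0},
    }


@dataclass
class ParticipationSpec:
    baseline_logodds: float = logit(0.07)
    covariate_logodds: dict[str, dict[str, float]] = field(default_factory=dict)
    design_multipliers: dict[str, dict[str, float]] = field(
        default_factory=default_design_multipliers)
    outcome_dependence: float = 0.0
    recruitment_window: tuple[dt.date, dt.date] = (
        dt.date(2006, 2, 1), dt.date(2009, 12, 31))

    def __post_init__(self) -> None:
        self.recruitment_window = tuple(as_date(d) for d in self.recruitment_window)

    def validate(self) -> None:
        start, end = self.recruitment_window
        if not start < end:
            raise ValueError("recruitment_window start must precede end")
        for cov, mults in self.design_multipliers.items():
            for level, m in mults.items():
                if m < 0:
                    raise ValueError(
                        f"design multiplier for {cov}={level} must be >= 0, got {m}")

    def to_dict(self) -> dict:
        return {
            "baseline_logodds": self.baseline_logodds,
            "covariate_logodds": self.covariate_logodds,
            "design_multipliers": self.design_multipliers,
            "outcome_dependence": self.outcome_dependence,
            "recruitment_window": [d.isoformat() for d in self.recruitment_window],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParticipationSpec":
        return cls(
            baseline_logodds=d["baseline_logodds"],
            covariate_logodds=d["covariate_logodds"],
            design_multipliers={k: {kk: float(vv) for kk, vv in v.items()}
                                for k, v in d["design_multipliers"].items()},
            outcome_dependence=d["outcome_dependence"],
            recruitment_window=tuple(d["recruitment_window"]),
        )


@dataclass
class BinaryModel:
    """Per-cancer intercept + per-category log-odds effects + latent loading."""

    intercept: dict[str, float]
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    latent_loading: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RateModel:
    """Per-cancer log-rate intercept + per-category log-rate effects."""

    intercept: dict[str, float]
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    latent_loading: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ConditionModel:
    """One chronic condition: baseline log-odds + latent-health loading."""

    intercept: float
    latent_loading: float = -0.6

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_comorbidity_model() -> dict[str, ConditionModel]:
    return {
        "diabetes": ConditionModel(logit(0.09)),
        "copd": ConditionModel(logit(0.07)),
        "chf": ConditionModel(logit(0.04)),
        "mi": ConditionModel(logit(0.04)),
        "cvd": ConditionModel(logit(0.04)),
        "renal": ConditionModel(logit(0.025)),
        "pud": ConditionModel(logit(0.015)),
        "dementia": ConditionModel(logit(0.025)),
        "diabetes_complications": ConditionModel(logit(0.025)),
    }


def _default_binary(p_bowel: float, p_lung: float,
                    effects: dict | None = None,
                    loading: float = 0.0) -> BinaryModel:
    return BinaryModel(intercept={"bowel": logit(p_bowel), "lung": logit(p_lung)},
                       effects=effects or {}, latent_loading=loading)


def _default_rate(lam_bowel: float, lam_lung: float,
                  loading: float = 0.0) -> RateModel:
    return RateModel(intercept={"bowel": float(np.log(lam_bowel)),
                                "lung": float(np.log(lam_lung))},
                     latent_loading=loading)


@dataclass
class OutcomeSpec:
    """Outcome processes.  Intercepts default to values implying the
    published population-level prevalences (e.g. 1-year bowel survival
    0.83, resection 0.79 bowel / 0.17 lung); extent and latent-health
    effects give the processes realistic structure."""

    resection_model: BinaryModel = field(default_factory=lambda: _default_binary(
        0.86, 0.30,
        effects={"extent": {"distant": -1.6, "unknown": -0.9},
                 "ses_quintile": {"4": -0.10, "5": -0.20},
                 "age_group": {"85+": -0.7}},
        loading=0.25))
    survival1_model: BinaryModel = field(default_factory=lambda: _default_binary(
        0.94, 0.72,
        effects={"extent": {"regional": -0.35, "distant": -2.0, "unknown": -0.8},
                 "age_group": {"75-84": -0.4, "85+": -1.0},
                 "ses_quintile": {"5": -0.15}},
        loading=0.45))
    survival3_model: BinaryModel = field(default_factory=lambda: _default_binary(
        0.91, 0.68,
        effects={"extent": {"regional": -0.3, "distant": -1.9, "unknown": -0.6},
                 "age_group": {"75-84": -0.4, "85+": -1.0}},
        loading=0.45))  # conditional on surviving year 1
    hospital_prior_model: RateModel = field(
        default_factory=lambda: _default_rate(0.30, 0.36, loading=-0.30))
    hospital_post_model: RateModel = field(
        default_factory=lambda: _default_rate(1.05, 1.35, loading=-0.45))
    ed_prior_model: RateModel = field(
        default_factory=lambda: _default_rate(0.32, 0.44, loading=-0.45))
    ed_post_model: RateModel = field(
        default_factory=lambda: _default_rate(0.85, 1.35, loading=-0.80))
    background_admission_model: RateModel = field(
        default_factory=lambda: _default_rate(3.0, 3.2, loading=-0.40))
    comorbidity_model: dict[str, ConditionModel] = field(
        default_factory=default_comorbidity_model)
    ed_coverage_by_remoteness: dict[str, float] = field(default_factory=lambda: {
        "major_city": 1.0, "inner_regional": 0.85, "outer_regional_remote": 0.70})
    resection_emergency_prob: dict[str, float] = field(
        default_factory=lambda: {"bowel": 0.15, "lung": 0.02})
    sameday_rate: float = 0.30
    mean_stay_days: float = 8.0
    coding_prob: float = 0.70
    private_prob: float = 0.28

    def validate(self) -> None:
        for name, p in self.ed_coverage_by_remoteness.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"ED coverage for {name!r} must lie in [0,1]")
        for cancer, p in self.resection_emergency_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"emergency probability for {cancer!r} outside [0,1]")

    def to_dict(self) -> dict:
        return {
            "resection_model": self.resection_model.to_dict(),
            "survival1_model": self.survival1_model.to_dict(),
            "survival3_model": self.survival3_model.to_dict(),
            "hospital_prior_model": self.hospital_prior_model.to_dict(),
            "hospital_post_model": self.hospital_post_model.to_dict(),
            "ed_prior_model": self.ed_prior_model.to_dict(),
            "ed_post_model": self.ed_post_model.to_dict(),
            "background_admission_model": self.background_admission_model.to_dict(),
            "comorbidity_model": {k: v.to_dict() for k, v in self.comorbidity_model.items()},
            "ed_coverage_by_remoteness": self.ed_coverage_by_remoteness,
            "resection_emergency_prob": self.resection_emergency_prob,
            "sameday_rate": self.sameday_rate,
            "mean_stay_days": self.mean_stay_days,
            "coding_prob": self.coding_prob,
            "private_prob": self.private_prob,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeSpec":
        return cls(
            resection_model=BinaryModel(**d["resection_model"]),
            survival1_model=BinaryModel(**d["survival1_model"]),
            survival3_model=BinaryModel(**d["survival3_model"]),
            hospital_prior_model=RateModel(**d["hospital_prior_model"]),
            hospital_post_model=RateModel(**d["hospital_post_model"]),
            ed_prior_model=RateModel(**d["ed_prior_model"]),
            ed_post_model=RateModel(**d["ed_post_model"]),
            background_admission_model=RateModel(**d["background_admission_model"]),
            comorbidity_model={k: ConditionModel(**v)
                               for k, v in d["comorbidity_model"].items()},
            ed_coverage_by_remoteness=d["ed_coverage_by_remoteness"],
            resection_emergency_prob=d["resection_emergency_prob"],
            sameday_rate=d["sameday_rate"],
            mean_stay_days=d["mean_stay_days"],
            coding_prob=d["coding_prob"],
            private_prob=d["private_prob"],
        )


@dataclass
class LinkedDataset:
    """Five linked tables plus the generating truth."""

    registry: pd.DataFrame
    admissions: pd.DataFrame
    ed: pd.DataFrame
    deaths: pd.DataFrame
    roster: pd.DataFrame
    truth: dict
    censor_date: dt.date

    FILES = ("registry", "admissions", "ed", "deaths", "roster")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self.FILES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        payload = dict(self.truth)
        payload["censor_date"] = self.censor_date.isoformat()
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def read(cls, indir: str | Path) -> "LinkedDataset":
        indir = Path(indir)
        frames = {}
        date_cols = {
            "registry": ["diagnosis_date"],
            "admissions": ["admission_date", "separation_date"],
            "ed": ["attendance_date"],
            "deaths": ["death_date"],
            "roster": ["recruitment_date"],
        }
        for name in cls.FILES:
            frames[name] = pd.read_csv(indir / f"{name}.csv",
                                       parse_dates=date_cols[name])
        truth = json.loads((indir / "truth.json").read_text())
        censor = as_date(truth.pop("censor_date"))
        return cls(**frames, truth=truth, censor_date=censor)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

_AGE_SAMPLING = {"45-54": (45, 54), "55-64": (55, 64), "65-74": (65, 74),
                 "75-84": (75, 84), "85+": (85, 97)}


def _category_offsets(pop: pd.DataFrame, effects: dict[str, dict[str, float]]) -> np.ndarray:
    eta = np.zeros(len(pop))
    for cov, levels in effects.items():
        eta += pop[cov].map(levels).fillna(0.0).to_numpy(dtype=float)
    return eta


def linear_predictor(pop: pd.DataFrame, model: BinaryModel | RateModel) -> np.ndarray:
    """Log-odds / log-rate linear predictor for a per-cancer model."""
    eta = pop["cancer"].map(model.intercept).to_numpy(dtype=float)
    eta += _category_offsets(pop, model.effects)
    if model.latent_loading:
        eta += model.latent_loading * pop["latent_health"].to_numpy()
    return eta


def draw_binary_outcome(pop: pd.DataFrame, model: BinaryModel,
                        rng: np.random.Generator) -> np.ndarray:
    """Bernoulli draw from a :class:`BinaryModel`; used by the event
    generator and by calibration simulations."""
    return rng.random(len(pop)) < expit(linear_predictor(pop, model))


def generate_population(spec: PopulationSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw the person-level source-population covariate table.

    Returns one row per cancer patient with demographic covariates, cancer
    type, extent, diagnosis date, age at diagnosis and the latent health
    propensity (kept for participation/outcome generation and recovery
    tests; it is not an observable column of the emitted registry).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_persons

    covs = list(spec.covariate_distributions)
    level_lists = [list(cat.COVARIATES[c]) for c in covs]
    shape = tuple(len(lv) for lv in level_lists)

    # joint table: product of marginals x exp(log-linear dependence terms)
    p = np.ones(shape)
    for axis, (c, levels) in enumerate(zip(covs, level_lists)):
        marg = np.array([spec.covariate_distributions[c][lv] for lv in levels])
        dims = [1] * len(shape)
        dims[axis] = len(levels)
        p = p * marg.reshape(dims)
    for term in spec.covariate_dependence:
        ia = covs.index(term.covariate_a)
        ib = covs.index(term.covariate_b)
        ja = level_lists[ia].index(term.category_a)
        jb = level_lists[ib].index(term.category_b)
        sl = [slice(None)] * len(shape)
        sl[ia], sl[ib] = ja, jb
        p[tuple(sl)] *= np.exp(term.log_or)
    flat = p.ravel() / p.sum()

    cells = rng.choice(flat.size, size=n, p=flat)
    idx = np.unravel_index(cells, shape)
    data = {c: np.asarray(levels, dtype=object)[i]
            for c, levels, i in zip(covs, level_lists, idx)}
    pop = pd.DataFrame(data)
    pop.insert(0, "person_id", [f"P{i:07d}" for i in range(n)])
    pop["latent_health"] = rng.standard_normal(n)

    # cancer type: logistic in covariates + latent health
    eta = logit(spec.cancer_mix.p_lung) + _category_offsets(pop, spec.cancer_mix.logodds)
    eta += spec.cancer_mix.latent_loading * pop["latent_health"].to_numpy()
    pop["cancer"] = np.where(rng.random(n) < expit(eta), "lung", "bowel")

    # extent per cancer type
    extent = np.empty(n, dtype=object)
    for cancer, dist in spec.extent_by_cancer.items():
        mask = (pop["cancer"] == cancer).to_numpy()
        levels = list(cat.EXTENT)
        probs = np.array([dist[lv] for lv in levels])
        extent[mask] = rng.choice(levels, size=int(mask.sum()), p=probs / probs.sum())
    pop["extent"] = extent

    # diagnosis date uniform over the window; age uniform inside the band
    start, end = spec.diagnosis_window
    span = (end - start).days + 1
    pop["diagnosis_date"] = (np.datetime64(start) +
                             rng.integers(0, span, size=n) * DAY)
    lo = pop["age_group"].map({g: a for g, (a, _) in _AGE_SAMPLING.items()}).to_numpy(int)
    hi = pop["age_group"].map({g: b for g, (_, b) in _AGE_SAMPLING.items()}).to_numpy(int)
    pop["age_at_diagnosis"] = rng.integers(lo, hi + 1)
    return pop


def assign_participation(pop: pd.DataFrame, pspec: ParticipationSpec,
                         seed: int) -> pd.DataFrame:
    """Draw the cohort-study participation flag and recruitment date.

    Participation probability = cap(logistic(baseline + covariate offsets
    + outcome_dependence x latent health) x design multiplier, 1).
    """
    if len(pop) == 0:
        raise ValueError("population table is empty")
    pspec.validate()
    rng = np.random.default_rng(seed)
    eta = pspec.baseline_logodds + _category_offsets(pop, pspec.covariate_logodds)
    if pspec.outcome_dependence:
        eta += pspec.outcome_dependence * pop["latent_health"].to_numpy()
    prob = expit(eta)
    mult = np.ones(len(pop))
    for cov, levels in pspec.design_multipliers.items():
        mult *= pop[cov].map(levels).fillna(1.0).to_numpy(dtype=float)
    prob = np.minimum(prob * mult, 1.0)
    participant = rng.random(len(pop)) < prob

    start, end = pspec.recruitment_window
    span = (end - start).days + 1
    rec = np.full(len(pop), np.datetime64("NaT"), dtype="datetime64[D]")
    rec[participant] = (np.datetime64(start) +
                        rng.integers(0, span, size=int(participant.sum())) * DAY)
    return pd.DataFrame({
        "person_id": pop["person_id"].to_numpy(),
        "participant": participant,
        "participation_prob": prob,
        "recruitment_date": rec.astype("datetime64[ns]"),
    })


_SITE_CODES = {"bowel": (["C18", "C19", "C20"], [0.70, 0.10, 0.20]),
               "lung": (["C34"], [1.0])}


def _repeat_persons(pop: pd.DataFrame, counts: np.ndarray) -> pd.DataFrame:
    idx = np.repeat(np.arange(len(pop)), counts)
    return pop.iloc[idx].reset_index(drop=True)


def generate_events(pop: pd.DataFrame, ospec: OutcomeSpec, seed: int,
                    charlson_codes: dict[str, str] | None = None,
                    resection_codes: dict[str, str] | None = None,
                    ) -> dict[str, object]:
    """Generate registry, admission, ED and death tables for ``pop``.

    ``charlson_codes`` maps condition name -> diagnosis code emitted on
    admissions; ``resection_codes`` maps cancer -> major-resection
    procedure code.  Defaults come from the packaged lookups.
    """
    ospec.validate()
    if charlson_codes is None:
        from .outcomes import load_charlson_map
        charlson_codes = {c.condition: c.prefixes[0] for c in load_charlson_map()}
    if resection_codes is None:
        from .outcomes import load_resection_codes
        rc = load_resection_codes()
        resection_codes = {"bowel": sorted(rc["bowel"])[0], "lung": sorted(rc["lung"])[0]}

    seeds = spawn_seeds(seed, 6)
    rng = np.random.default_rng(seeds[0])
    n = len(pop)
    diag = pop["diagnosis_date"].to_numpy(dtype="datetime64[D]")
    latent = pop["latent_health"].to_numpy()

    # ---- registry ---------------------------------------------------------
    site = np.empty(n, dtype=object)
    for cancer, (codes, probs) in _SITE_CODES.items():
        mask = (pop["cancer"] == cancer).to_numpy()
        site[mask] = rng.choice(codes, size=int(mask.sum()), p=probs)
    registry = pd.DataFrame({
        "person_id": pop["person_id"],
        "cancer_site_code": site,
        "histology_code": "M8140",
        "diagnosis_date": pop["diagnosis_date"],
        "age_at_diagnosis": pop["age_at_diagnosis"],
        "sex": pop["sex"],
        "remoteness": pop["remoteness"],
        "ses_quintile": pop["ses_quintile"],
        "cob_group": pop["cob_group"],
        "extent": pop["extent"],
        "dco_flag": False,
        "residence_known": True,
        "diagnosis_date_known": True,
    })

    # ---- chronic conditions ----------------------------------------------
    cond_names = list(ospec.comorbidity_model)
    cond_flags = np.column_stack([
        rng.random(n) < expit(m.intercept + m.latent_loading * latent)
        for m in ospec.comorbidity_model.values()
    ]) if cond_names else np.zeros((n, 0), dtype=bool)

    # ---- survival / deaths ------------------------------------------------
    surv1 = draw_binary_outcome(pop, ospec.survival1_model, rng)
    surv3 = surv1 & draw_binary_outcome(pop, ospec.survival3_model, rng)
    death_day = np.full(n, -1)
    d1 = ~surv1
    death_day[d1] = rng.integers(15, 365, size=int(d1.sum()))
    d3 = surv1 & ~surv3
    death_day[d3] = rng.integers(366, 1095, size=int(d3.sum()))
    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    has_death = death_day >= 0
    death_date[has_death] = diag[has_death] + death_day[has_death] * DAY
    deaths = pd.DataFrame({
        "person_id": pop.loc[has_death, "person_id"].to_numpy(),
        "death_date": pd.to_datetime(death_date[has_death]),
    })

    # ---- resection --------------------------------------------------------
    resect = draw_binary_outcome(pop, ospec.resection_model, rng)
    res_day = rng.integers(5, 61, size=n)
    res_date = diag + res_day * DAY
    # a death inside the pre-operative wait forecloses the operation
    resect &= ~(has_death & (death_day <= res_day))

    def _codes_for(person_idx: np.ndarray, gen: np.random.Generator) -> list[str]:
        out = []
        for i in person_idx:
            coded = [charlson_codes[cond]
                     for j, cond in enumerate(cond_names)
                     if cond_flags[i, j] and gen.random() < ospec.coding_prob]
            out.append(";".join(coded) if coded else "R69")
        return out

    adm_parts: list[pd.DataFrame] = []

    def _emit(person_idx, adm_dates, stay_days, urgency, private, acute,
              procedure, gen):
        sub = pop.iloc[person_idx]
        adm_parts.append(pd.DataFrame({
            "person_id": sub["person_id"].to_numpy(),
            "admission_date": pd.to_datetime(adm_dates),
            "separation_date": pd.to_datetime(adm_dates + stay_days * DAY),
            "hospital_type": np.where(private, "private", "public"),
            "urgency": urgency,
            "acute_flag": acute,
            "procedure_codes": procedure,
            "diagnosis_codes": _codes_for(person_idx, gen),
        }))

    # background admissions over [diag-5y, diag-1y): carry comorbidity codes
    rng_bg = np.random.default_rng(seeds[1])
    lam_bg = np.exp(linear_predictor(pop, ospec.background_admission_model))
    n_bg = rng_bg.poisson(lam_bg)
    if n_bg.sum():
        pidx = np.repeat(np.arange(n), n_bg)
        offs = rng_bg.integers(365, 5 * 365, size=pidx.size)
        dates = diag[pidx] - offs * DAY
        sameday = rng_bg.random(pidx.size) < 0.5
        stays = np.where(sameday, 0, 1 + rng_bg.geometric(1 / 3.0, size=pidx.size))
        _emit(pidx, dates, stays,
              np.where(rng_bg.random(pidx.size) < 0.35, "emergency", "planned_other"),
              rng_bg.random(pidx.size) < ospec.private_prob,
              rng_bg.random(pidx.size) < 0.97, None, rng_bg)

    # prior-year admissions
    rng_pr = np.random.default_rng(seeds[2])
    lam_pr = np.exp(linear_predictor(pop, ospec.hospital_prior_model))
    n_over = rng_pr.poisson(lam_pr)
    n_same = rng_pr.poisson(ospec.sameday_rate, size=n)
    for counts, is_over in ((n_over, True), (n_same, False)):
        if counts.sum() == 0:
            continue
        pidx = np.repeat(np.arange(n), counts)
        dates = diag[pidx] - rng_pr.integers(1, 366, size=pidx.size) * DAY
        stays = (1 + rng_pr.geometric(1 / 2.5, size=pidx.size)) if is_over \
            else np.zeros(pidx.size, dtype=int)
        _emit(pidx, dates, stays,
              np.where(rng_pr.random(pidx.size) < 0.4, "emergency", "planned_other"),
              rng_pr.random(pidx.size) < ospec.private_prob,
              rng_pr.random(pidx.size) < 0.97, None, rng_pr)

    # resection admission
    rng_rs = np.random.default_rng(seeds[3])
    if resect.sum():
        pidx = np.flatnonzero(resect)
        stays = 3 + rng_rs.geometric(1 / (ospec.mean_stay_days - 1), size=pidx.size)
        p_em = pop["cancer"].iloc[pidx].map(ospec.resection_emergency_prob).to_numpy(float)
        urgency = np.where(rng_rs.random(pidx.size) < p_em, "emergency", "planned_other")
        proc = pop["cancer"].iloc[pidx].map(resection_codes).to_numpy(object)
        _emit(pidx, res_date[pidx], stays, urgency,
              rng_rs.random(pidx.size) < ospec.private_prob,
              np.ones(pidx.size, dtype=bool), proc, rng_rs)

    # other post-year admissions
    rng_po = np.random.default_rng(seeds[4])
    lam_po = np.exp(linear_predictor(pop, ospec.hospital_post_model))
    n_over = rng_po.poisson(lam_po)
    n_same = rng_po.poisson(ospec.sameday_rate, size=n)
    for counts, is_over in ((n_over, True), (n_same, False)):
        if counts.sum() == 0:
            continue
        pidx = np.repeat(np.arange(n), counts)
        dates = diag[pidx] + rng_po.integers(0, 365, size=pidx.size) * DAY
        stays = (1 + rng_po.geometric(1 / (ospec.mean_stay_days - 1), size=pidx.size)) \
            if is_over else np.zeros(pidx.size, dtype=int)
        _emit(pidx, dates, stays,
              np.where(rng_po.random(pidx.size) < 0.35, "emergency", "planned_other"),
              rng_po.random(pidx.size) < ospec.private_prob,
              rng_po.random(pidx.size) < 0.97, None, rng_po)

    admissions = pd.concat(adm_parts, ignore_index=True) if adm_parts else pd.DataFrame(
        columns=["person_id", "admission_date", "separation_date", "hospital_type",
                 "urgency", "acute_flag", "procedure_codes", "diagnosis_codes"])
    admissions["procedure_codes"] = admissions["procedure_codes"].fillna("")

    # ---- ED events (generated fully, thinned by coverage afterwards) ------
    rng_ed = np.random.default_rng(seeds[5])
    ed_parts = []
    for model, sign in ((ospec.ed_prior_model, -1), (ospec.ed_post_model, +1)):
        lam = np.exp(linear_predictor(pop, model))
        counts = rng_ed.poisson(lam)
        if counts.sum() == 0:
            continue
        pidx = np.repeat(np.arange(n), counts)
        offs = rng_ed.integers(1, 366, size=pidx.size) if sign < 0 \
            else rng_ed.integers(0, 365, size=pidx.size)
        ed_parts.append(pd.DataFrame({
            "person_id": pop["person_id"].to_numpy()[pidx],
            "attendance_date": pd.to_datetime(diag[pidx] + sign * offs * DAY),
            "remoteness": pop["remoteness"].to_numpy()[pidx],
        }))
    ed = pd.concat(ed_parts, ignore_index=True) if ed_parts else pd.DataFrame(
        columns=["person_id", "attendance_date", "remoteness"])
    if len(ed):
        keep_p = ed["remoteness"].map(ospec.ed_coverage_by_remoteness).to_numpy(float)
        ed = ed[rng_ed.random(len(ed)) < keep_p].drop(columns=["remoteness"])
        ed = ed.reset_index(drop=True)
    else:
        ed = ed.drop(columns=["remoteness"])

    # ---- death consistency: no event after death ---------------------------
    death_map = dict(zip(deaths["person_id"], deaths["death_date"]))
    if death_map:
        dd = admissions["person_id"].map(death_map)
        admissions = admissions[dd.isna() | (admissions["admission_date"] <= dd)]
        admissions = admissions.copy()
        dd = admissions["person_id"].map(death_map)
        clip = dd.notna() & (admissions["separation_date"] > dd)
        admissions.loc[clip, "separation_date"] = dd[clip]
        de = ed["person_id"].map(death_map)
        ed = ed[de.isna() | (ed["attendance_date"] <= de)].reset_index(drop=True)

    admissions = admissions.sort_values(
        ["person_id", "admission_date", "separation_date"],
        kind="mergesort").reset_index(drop=True)
    ed = ed.sort_values(["person_id", "attendance_date"],
                        kind="mergesort").reset_index(drop=True)

    censor = as_date(pd.Timestamp(diag.max())) + dt.timedelta(days=3 * 365 + 1)
    return {"registry": registry, "admissions": admissions, "ed": ed,
            "deaths": deaths, "censor_date": censor}


def simulate(pop_spec: PopulationSpec, part_spec: ParticipationSpec,
             out_spec: OutcomeSpec, seed: int | None = None) -> LinkedDataset:
    """End-to-end: population -> participation -> events -> LinkedDataset.

    The roster holds participants only (person id + recruitment date), as
    a cohort membership file would.
    """
    root = pop_spec.seed if seed is None else seed
    s_pop, s_part, s_ev = spawn_seeds(root, 3)
    pop = generate_population(pop_spec, seed=s_pop)
    part = assign_participation(pop, part_spec, seed=s_part)
    ev = generate_events(pop, out_spec, seed=s_ev)
    roster = part.loc[part["participant"],
                      ["person_id", "recruitment_date"]].reset_index(drop=True)
    truth = {
        "population_spec": pop_spec.to_dict(),
        "participation_spec": part_spec.to_dict(),
        "outcome_spec": out_spec.to_dict(),
        "root_seed": int(root),
    }
    return LinkedDataset(registry=ev["registry"], admissions=ev["admissions"],
                         ed=ev["ed"], deaths=ev["deaths"], roster=roster,
                         truth=truth, censor_date=ev["censor_date"])


def specs_from_truth(truth: dict) -> tuple[PopulationSpec, ParticipationSpec, OutcomeSpec]:
    """Re-instantiate the three generating specs from a truth block."""
    return (PopulationSpec.from_dict(truth["population_spec"]),
            ParticipationSpec.from_dict(truth["participation_spec"]),
            OutcomeSpec.from_dict(truth["outcome_spec"]))
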