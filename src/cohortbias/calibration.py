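"""Simulation oracles for the RRF/ROR machinery.

These drive the package's own generator and estimators under designs with
known truth: nested simple-random-subsampling (true RRF and ROR are 1)
and a collider design in which participation and the outcome share the
latent health propensity (the ROR for the loaded factor is biased in an
analytically known direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._util import spawn_seeds
from .association_bias import ModelSpec, fit_logistic, ror
from .synthetic_data import (BinaryModel, ParticipationSpec, PopulationSpec,
                             assign_participation, draw_binary_outcome,
                             generate_population)


def _simple_rows(n: int, p_factor: float, beta0: float, beta1: float,
                 rng: np.random.Generator,
                 latent_out: float = 0.0) -> pd.DataFrame:
    """Minimal analysis table: one binary risk factor, optional latent term."""
    x = rng.random(n) < p_factor
    latent = rng.standard_normal(n)
    y = rng.random(n) < expit(beta0 + beta1 * x + latent_out * latent)
    return pd.DataFrame({
        "exposed": np.where(x, "yes", "no"),
        "outcome": y,
        "latent": latent,
    })


def _binary_spec() -> ModelSpec:
    # survival_1y is just the carrier column name for the generic binary fit
    return ModelSpec("survival_1y", risk_factors=("exposed",), adjusters=(),
                     references={"exposed": "no"})


def _fit_ror_binary(rows: pd.DataFrame):
    """Fit subsample and population logistic fits for the 'exposed' factor."""
    spec = _binary_spec()
    rows = rows.rename(columns={"outcome": "survival_1y"})
    sub = fit_logistic(rows, spec, "subsample", min_events_per_param=0)
    pop = fit_logistic(rows, spec, "population", min_events_per_param=0)
    if sub.status != "ok" or pop.status != "ok":
        return None
    return ror(sub, pop)[0]


def ror_null_calibration(n_pop: int = 4000, frac_sub: float = 0.25,
                         p_factor: float = 0.5, beta0: float = -0.5,
                         beta1: float = 0.3, n_reps: int = 1000,
                         seed: int = 0, alpha: float = 0.05) -> float:
    """Fraction of null-design RORs whose CI excludes 1.

    The subsample is a uniform random subset of the simulated population,
    so the true ROR is exactly 1 and the exclusion fraction should match
    the nominal error rate (~5%).
    """
    outside = 0
    used = 0
    for s in spawn_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        rows = _simple_rows(n_pop, p_factor, beta0, beta1, rng)
        rows["participant"] = rng.random(n_pop) < frac_sub
        r = _fit_ror_binary(rows)
        if r is None or r.status != "ok":
            continue
        used += 1
        if not (r.cl_lower <= 1.0 <= r.cl_upper):
            outside += 1
    return outside / max(used, 1)


@dataclass
class ColliderResult:
    mean_ln_ror: float
    sem_ln_ror: float
    expected_sign: int
    n_reps: int

    @property
    def detected(self) -> bool:
        """Bias detected: mean shifted from 0 in the expected direction by
        more than two standard errors."""
        return self.expected_sign * self.mean_ln_ror > 2 * self.sem_ln_ror


def collider_bias_simulation(n_pop: int = 6000, n_reps: int = 500,
                             participation_base: float = -1.4,
                             a_factor: float = 0.8, b_latent: float = 1.2,
                             c_factor: float = 0.4, d_latent: float = 1.2,
                             beta0: float = -0.3, seed: int = 0) -> ColliderResult:
    """Mean ln ROR when participation and outcome share the latent propensity.

    Participation log-odds: base + a*X + b*L; outcome log-odds:
    beta0 + c*X + d*L, with L a standard-normal latent never entering the
    fitted model.  Conditioning on participation makes X and L negatively
    associated among participants when a,b > 0, so with d > 0 the
    subsample OR for X is attenuated: the expected sign of ln ROR is
    -sign(a*b*d).
    """
    lns = []
    for s in spawn_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        rows = _simple_rows(n_pop, 0.5, beta0, c_factor, rng, latent_out=d_latent)
        x = (rows["exposed"] == "yes").to_numpy(float)
        eta = participation_base + a_factor * x + b_latent * rows["latent"].to_numpy()
        rows["participant"] = rng.random(n_pop) < expit(eta)
        r = _fit_ror_binary(rows)
        if r is not None and np.isfinite(r.ror):
            lns.append(np.log(r.ror))
    lns = np.asarray(lns)
    return ColliderResult(
        mean_ln_ror=float(lns.mean()),
        sem_ln_ror=float(lns.std(ddof=1) / np.sqrt(len(lns))),
        expected_sign=-int(np.sign(a_factor * b_latent * d_latent)),
        n_reps=len(lns))


def logistic_recovery(n: int = 50_000, target_logodds: float = 0.5,
                      seed: int = 0) -> float:
    """Recover a known SES log-odds from the full generator + fit path.

    Generates a population with the package generator, attaches a binary
    outcome whose quintile-5 log-odds is ``target_logodds``, fits the
    logistic model, and returns the estimated coefficient.
    """
    s_pop, s_out = spawn_seeds(seed, 2)
    pop = generate_population(PopulationSpec(n_persons=n, seed=s_pop))
    model = BinaryModel(intercept={"bowel": -0.4, "lung": -0.4},
                        effects={"ses_quintile": {"5": target_logodds}})
    rng = np.random.default_rng(s_out)
    rows = pop.copy()
    rows["survival_1y"] = draw_binary_outcome(pop, model, rng)
    rows["participant"] = True
    spec = ModelSpec("survival_1y", risk_factors=("ses_quintile",), adjusters=())
    fit = fit_logistic(rows, spec, "population")
    return fit.term("ses_quintile", "5").coef


def latent_participation_gap(n: int = 20_000, outcome_dependence: float = 0.5,
                             seed: int = 0) -> tuple[float, float]:
    """(mean latent health of participants, of non-participants) under a
    participation model loaded on the latent propensity."""
    s_pop, s_part = spawn_seeds(seed, 2)
    pop = generate_population(PopulationSpec(n_persons=n, seed=s_pop))
    pspec = ParticipationSpec(design_multipliers={},
                              outcome_dependence=outcome_dependence)
    part = assign_participation(pop, pspec, seed=s_part)
    mask = part["participant"].to_numpy()
    lat = pop["latent_health"].to_numpy()
    return float(lat[mask].mean()), float(lat[~mask].mean())
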