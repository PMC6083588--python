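"""Relative odds ratios: risk-factor associations in subsample vs population.

The same multivariable logistic model is fitted separately among cohort
participants and in the whole source population (participants included);
for every non-reference factor level the relative odds ratio is

    ROR = OR_subsample / OR_population,

with departure from 1 suggesting that self-selection distorts the
association.  Because the subsample is nested in the population the two
log-odds-ratio estimates are positively correlated, and

    se(ln ROR) = sqrt(max(se_sub^2 - se_pop^2, floor))

— the variance *difference*, by the same nested-sample argument as the
RRF limits (for maximum-likelihood estimates from a subsample vs the full
sample, cov(b_sub, b_pop) = var(b_pop)).

Fits use binomial GLMs on covariate-pattern-aggregated data (identical
likelihood to person-level logistic regression, far faster), with dummy
coding against declared reference levels.  Separation and sparse data are
flagged, never silently "fixed".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .categories import ORDERINGS
from ._util import z_quantile

SE_FLOOR = 1e-12

#: the four health-service-use / survival outcomes examined for bias
OUTCOME_COLUMNS = {
    "resection": lambda df: df["resection"].astype(bool),
    "gt4_weeks": lambda df: df["weeks_post_band"].eq("gt4_weeks"),
    "gt2_ed": lambda df: df["ed_post_band"].eq("3+"),
    "survival_1y": lambda df: df["survival_1y"].astype(bool),
}

DEFAULT_REFERENCES = {
    "remoteness": "major_city",
    "ses_quintile": "1",
    "cob_group": "australia",
    "charlson_band": "0",
    "sex": "male",
    "age_group": "65-74",
    "extent": "localised",
    "resection": "False",
}


@dataclass
class ModelSpec:
    """One outcome model: risk factors of interest plus prognostic adjusters."""

    outcome: str
    risk_factors: tuple[str, ...] = ("remoteness", "ses_quintile",
                                     "cob_group", "charlson_band")
    adjusters: tuple[str, ...] = ("sex", "age_group", "extent")
    references: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}; "
                             f"one of {sorted(OUTCOME_COLUMNS)}")
        refs = dict(DEFAULT_REFERENCES)
        refs.update(self.references)
        self.references = refs
        for f in self.factors:
            if f not in self.references:
                raise ValueError(f"no reference level declared for factor {f!r}")

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(self.risk_factors) + tuple(self.adjusters)


def default_model_specs() -> list[ModelSpec]:
    """The four bias-panel models: resection adjusted for sex/age/extent;
    the other outcomes additionally adjusted for resection status."""
    specs = [ModelSpec("resection")]
    for outcome in ("gt4_weeks", "gt2_ed", "survival_1y"):
        specs.append(ModelSpec(outcome,
                               adjusters=("sex", "age_group", "extent", "resection")))
    return specs


@dataclass
class TermEstimate:
    factor: str
    level: str
    coef: float
    se: float
    estimable: bool = True


@dataclass
class LogisticFit:
    outcome: str
    group: str
    terms: list[TermEstimate]
    n: int
    n_events: int
    n_params: int
    converged: bool = True
    separation: bool = False
    sparse: bool = False
    status: str = "ok"  # ok | degenerate_outcome | too_few_events

    def term(self, factor: str, level: str) -> TermEstimate:
        for t in self.terms:
            if t.factor == factor and t.level == level:
                return t
        raise KeyError((factor, level))


def _level_order(factor: str, observed: list[str], reference: str) -> list[str]:
    declared = ORDERINGS.get(factor)
    if declared is None:
        ordered = sorted(observed)
    else:
        ordered = [c for c in declared if c in observed] + \
                  sorted(c for c in observed if c not in declared)
    return [lv for lv in ordered if lv != reference]


def fit_logistic(rows: pd.DataFrame, spec: ModelSpec, group: str,
                 min_events_per_param: float = 10.0) -> LogisticFit:
    """Fit the multivariable logistic model in one group.

    ``group`` is ``"subsample"`` (participants only) or ``"population"``
    (everyone, participants included).  Non-convergence, separation and
    events-per-parameter below ``min_events_per_param`` are reported as
    flags on the result so batch runs always complete.
    """
    if group == "subsample":
        df = rows[rows["participant"].astype(bool)]
    elif group == "population":
        df = rows
    else:
        raise ValueError("group must be 'subsample' or 'population'")

    y = OUTCOME_COLUMNS[spec.outcome](df).astype(int)
    work = df.loc[:, list(spec.factors)].astype(str).copy()
    work["_y"] = y.to_numpy()
    agg = (work.groupby(list(spec.factors), observed=True)["_y"]
           .agg(events="sum", n="count").reset_index())

    n_events = int(agg["events"].sum())
    n_total = int(agg["n"].sum())
    fit = LogisticFit(outcome=spec.outcome, group=group, terms=[],
                      n=n_total, n_events=n_events, n_params=0)
    if n_events == 0 or n_events == n_total or n_total == 0:
        fit.status = "degenerate_outcome"
        fit.converged = False
        return fit

    X_cols: list[tuple[str, str]] = []
    X = [np.ones(len(agg))]
    for factor in spec.factors:
        ref = spec.references[factor]
        observed = list(dict.fromkeys(agg[factor]))
        for level in _level_order(factor, observed, ref):
            X_cols.append((factor, level))
            X.append((agg[factor] == level).to_numpy(float))
    design = np.column_stack(X)

    # drop all-zero / aliased columns so the information matrix is full rank
    keep = [0]
    seen = [design[:, 0]]
    dropped: list[tuple[str, str]] = []
    for j in range(1, design.shape[1]):
        col = design[:, j]
        if col.sum() == 0:
            dropped.append(X_cols[j - 1])
            continue
        keep.append(j)
        seen.append(col)
    design_kept = design[:, keep]
    kept_cols = [X_cols[j - 1] for j in keep[1:]]
    fit.n_params = design_kept.shape[1]

    endog = np.column_stack([agg["events"], agg["n"] - agg["events"]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, design_kept, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200, tol=1e-12)
        except Exception:
            fit.status = "degenerate_outcome"
            fit.converged = False
            return fit
    fit.converged = bool(getattr(res, "converged", True))

    coefs = dict(zip(kept_cols, res.params[1:]))
    ses = dict(zip(kept_cols, res.bse[1:]))
    fit.separation = any(abs(c) > 15 or ses[k] > 50 for k, c in coefs.items())
    epp = min(n_events, n_total - n_events) / max(fit.n_params, 1)
    fit.sparse = epp < min_events_per_param

    for factor in spec.factors:
        ref = spec.references[factor]
        observed = list(dict.fromkeys(agg[factor]))
        for level in _level_order(factor, observed, ref):
            key = (factor, level)
            if key in dropped or key not in coefs:
                fit.terms.append(TermEstimate(factor, level, np.nan, np.nan,
                                              estimable=False))
            else:
                fit.terms.append(TermEstimate(factor, level,
                                              float(coefs[key]), float(ses[key])))
    return fit


@dataclass
class RorResult:
    outcome: str
    factor: str
    level: str
    or_sub: float
    se_ln_or_sub: float
    or_pop: float
    se_ln_or_pop: float
    ror: float
    cl_lower: float
    cl_upper: float
    status: str = "ok"  # ok | se_floored | not_estimable


def ror(sub_fit: LogisticFit, pop_fit: LogisticFit,
        alpha: float = 0.05, floor: float = SE_FLOOR) -> list[RorResult]:
    """Relative odds ratios with nested-sample confidence limits.

    Requires the two fits to share outcome and terms (same ModelSpec and
    coding).  When se_sub^2 <= se_pop^2 the variance difference is floored
    at ``floor`` and the row flagged.
    """
    if sub_fit.outcome != pop_fit.outcome:
        raise ValueError("fits are for different outcomes")
    sub_keys = [(t.factor, t.level) for t in sub_fit.terms]
    pop_keys = [(t.factor, t.level) for t in pop_fit.terms]
    if sub_keys != pop_keys:
        raise ValueError("fits have mismatched model terms")
    z = z_quantile(alpha)
    out = []
    for ts, tp in zip(sub_fit.terms, pop_fit.terms):
        if not (ts.estimable and tp.estimable):
            out.append(RorResult(sub_fit.outcome, ts.factor, ts.level,
                                 np.nan, np.nan, np.nan, np.nan,
                                 np.nan, np.nan, np.nan, status="not_estimable"))
            continue
        ln_ror = ts.coef - tp.coef
        v = ts.se**2 - tp.se**2
        status = "ok"
        if v <= floor:
            warnings.warn(
                f"{ts.factor}={ts.level}: subsample variance not larger than "
                "population variance; SE difference floored", stacklevel=2)
            v = floor
            status = "se_floored"
        half = z * np.sqrt(v)
        with np.errstate(over="ignore"):  # inf limit on a separated fit
            out.append(RorResult(
                outcome=sub_fit.outcome, factor=ts.factor, level=ts.level,
                or_sub=float(np.exp(ts.coef)), se_ln_or_sub=ts.se,
                or_pop=float(np.exp(tp.coef)), se_ln_or_pop=tp.se,
                ror=float(np.exp(ln_ror)),
                cl_lower=float(np.exp(ln_ror - half)),
                cl_upper=float(np.exp(ln_ror + half)),
                status=status))
    return out


def ror_frame(results: list[RorResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def bias_panel(rows: pd.DataFrame, specs: list[ModelSpec] | None = None,
               min_events_per_param: float = 10.0,
               include_univariable: bool = True) -> pd.DataFrame:
    """OR / ROR panel across the four outcomes.

    One row per outcome x factor level: subsample and population ORs,
    the ROR with nested confidence limits, and the fit flags.  Models
    whose smaller outcome class gives fewer than ``min_events_per_param``
    events per parameter are refused with status ``too_few_events``
    rather than reported with unstable estimates.  Univariable
    (single-risk-factor, unadjusted) RORs are appended for comparison
    with the adjusted estimates when ``include_univariable``.
    """
    specs = specs if specs is not None else default_model_specs()
    frames = []
    for spec in specs:
        for adjusted in ((True, False) if include_univariable else (True,)):
            model_specs = [spec] if adjusted else [
                ModelSpec(spec.outcome, risk_factors=(f,), adjusters=(),
                          references=spec.references)
                for f in spec.risk_factors]
            for ms in model_specs:
                sub = fit_logistic(rows, ms, "subsample", min_events_per_param)
                pop = fit_logistic(rows, ms, "population", min_events_per_param)
                label = "multivariable" if adjusted else "univariable"
                if (sub.status != "ok" or pop.status != "ok"
                        or (adjusted and (sub.sparse or pop.sparse))):
                    reason = ("too_few_events"
                              if sub.sparse or pop.sparse or sub.status == "ok"
                              else sub.status)
                    frames.append(pd.DataFrame([{
                        "outcome": ms.outcome, "model": label,
                        "factor": f, "level": None, "status": reason}
                        for f in ms.risk_factors]))
                    continue
                res = ror(sub, pop)
                df = ror_frame([r for r in res
                                if r.factor in ms.risk_factors])
                df.insert(1, "model", label)
                df["separation_flag"] = sub.separation or pop.separation
                frames.append(df)
    return pd.concat(frames, ignore_index=True)
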