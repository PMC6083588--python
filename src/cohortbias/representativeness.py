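"""Ratios of relative frequency (RRF) with nested-subsample confidence limits.

For a category with ``x_sub`` of ``n_sub`` subsample members and
``x_pop`` of ``n_pop`` population members (subsample nested in the
population), the RRF is

    RRF = (x_sub / n_sub) / (x_pop / n_pop),

with >1 meaning over-representation of the category among subsample
members.  Because the subsample is contained in the population the two
proportions are positively correlated, and the log-scale variance is the
*difference*

    var(ln RRF) = (1 - p_sub) / x_sub  -  (1 - p_pop) / x_pop,

not the sum the independent-samples formula would give.  The difference
form assumes the subsample is a simple random sample of the population;
its limits are always inside the independent-samples limits.  If the
difference is non-positive (possible in extreme configurations) the
independent-samples variance is used instead and the result flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import ORDERINGS
from ._util import round_half_up, z_quantile


@dataclass
class RrfResult:
    variable: str
    category: str
    x_sub: int
    n_sub: int
    x_pop: int
    n_pop: int
    rrf: float = np.nan
    cl_lower: float = np.nan
    cl_upper: float = np.nan
    alpha: float = 0.05
    stratum: str | None = None
    status: str = "ok"  # ok | fallback_independent | undefined_zero_count

    p_sub: float = field(init=False)
    p_pop: float = field(init=False)

    def __post_init__(self) -> None:
        self.p_sub = self.x_sub / self.n_sub if self.n_sub else np.nan
        self.p_pop = self.x_pop / self.n_pop if self.n_pop else np.nan

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(rrf, lower, upper) rounded half-up for display."""
        return (round_half_up(self.rrf, ndigits),
                round_half_up(self.cl_lower, ndigits),
                round_half_up(self.cl_upper, ndigits))


def ln_rrf_variance(x_sub: int, n_sub: int, x_pop: int, n_pop: int,
                    nested: bool = True) -> float:
    """Log-scale variance of the RRF; nested (difference) form by default."""
    p_sub, p_pop = x_sub / n_sub, x_pop / n_pop
    a = (1.0 - p_sub) / x_sub
    b = (1.0 - p_pop) / x_pop
    return a - b if nested else a + b


def rrf(x_sub: int, n_sub: int, x_pop: int, n_pop: int,
        alpha: float = 0.05, variable: str = "", category: str = "",
        variance: str = "nested") -> RrfResult:
    """RRF point estimate and confidence limits for one category.

    ``variance`` selects the nested-subsample difference formula
    (default) or ``"independent"`` for the two-independent-proportions
    sum (provided for comparison; it overstates the uncertainty of a
    nested contrast).
    """
    if not (n_sub > 0 and n_pop > 0):
        raise ValueError("denominators must be positive")
    if x_sub > n_sub or x_pop > n_pop:
        raise ValueError("numerators cannot exceed denominators")
    if x_sub > x_pop or n_sub > n_pop:
        raise ValueError("subsample counts must be nested within population counts")
    res = RrfResult(variable=variable, category=category, x_sub=int(x_sub),
                    n_sub=int(n_sub), x_pop=int(x_pop), n_pop=int(n_pop),
                    alpha=alpha)
    if x_sub == 0 or x_pop == 0:
        res.status = "undefined_zero_count"
        return res
    res.rrf = res.p_sub / res.p_pop
    if variance == "nested":
        v = ln_rrf_variance(x_sub, n_sub, x_pop, n_pop, nested=True)
        if v <= 0:
            warnings.warn("nested variance difference non-positive; "
                          "falling back to the independent-samples variance",
                          stacklevel=2)
            v = ln_rrf_variance(x_sub, n_sub, x_pop, n_pop, nested=False)
            res.status = "fallback_independent"
    elif variance == "independent":
        v = ln_rrf_variance(x_sub, n_sub, x_pop, n_pop, nested=False)
    else:
        raise ValueError("variance must be 'nested' or 'independent'")
    z = z_quantile(alpha)
    half = z * np.sqrt(v)
    res.cl_lower = float(res.rrf * np.exp(-half))
    res.cl_upper = float(res.rrf * np.exp(half))
    return res


def _category_order(variable: str, observed) -> list:
    declared = ORDERINGS.get(variable)
    if declared is None:
        return sorted(observed)
    tail = [c for c in observed if c not in declared]
    return [c for c in declared if c in observed] + sorted(tail)


def rrf_table(rows: pd.DataFrame, variable: str, by: str | None = None,
              alpha: float = 0.05) -> list[RrfResult]:
    """Category-level RRFs for one variable, optionally within strata.

    The subsample is ``rows[rows.participant]``; the population is every
    row (participants included — nesting is what the variance formula
    assumes).  Denominators are within-stratum totals.  Categories with
    zero subsample or population count come back status-flagged rather
    than as silent NaNs.
    """
    if variable not in rows.columns:
        raise KeyError(f"variable {variable!r} not in rows")
    strata = [(None, rows)] if by is None else [
        (str(level), grp) for level, grp in rows.groupby(by, sort=True)]
    out: list[RrfResult] = []
    for stratum, grp in strata:
        col = grp[variable].dropna().astype(str)
        sub = col[grp.loc[col.index, "participant"].astype(bool)]
        n_pop, n_sub = len(col), len(sub)
        if n_pop == 0:
            continue
        pop_counts = col.value_counts()
        sub_counts = sub.value_counts()
        for category in _category_order(variable, pop_counts.index):
            x_pop = int(pop_counts.get(category, 0))
            x_sub = int(sub_counts.get(category, 0))
            if x_sub == 0 or x_pop == 0 or n_sub == 0:
                res = RrfResult(variable=variable, category=category,
                                x_sub=x_sub, n_sub=max(n_sub, 1), x_pop=x_pop,
                                n_pop=n_pop, alpha=alpha,
                                status="undefined_zero_count")
                res.n_sub = n_sub
            else:
                res = rrf(x_sub, n_sub, x_pop, n_pop, alpha=alpha,
                          variable=variable, category=category)
            res.stratum = stratum
            out.append(res)
    return out


def results_frame(results: list[RrfResult]) -> pd.DataFrame:
    """Tabulate RrfResults (one row per category x stratum)."""
    recs = []
    for r in results:
        recs.append({
            "variable": r.variable, "stratum": r.stratum, "category": r.category,
            "x_sub": r.x_sub, "n_sub": r.n_sub, "pct_sub": 100.0 * r.p_sub,
            "x_pop": r.x_pop, "n_pop": r.n_pop, "pct_pop": 100.0 * r.p_pop,
            "rrf": r.rrf, "cl_lower": r.cl_lower, "cl_upper": r.cl_upper,
            "status": r.status,
        })
    return pd.DataFrame(recs)


def representativeness_identity_check(results: list[RrfResult],
                                      tol: float = 1e-9) -> bool:
    """Check sum_c p_pop(c) * RRF(c) == 1 over a complete category block.

    This is algebra (it equals sum_c p_sub(c) = 1) whenever every category
    shares the same denominators; failure means inconsistent denominators
    or an incomplete block.
    """
    if not results:
        return False
    total = sum(r.p_pop * r.rrf if np.isfinite(r.rrf) else r.p_sub
                for r in results)
    return bool(abs(total - 1.0) <= tol)


def nested_coverage_simulation(n_pop: int, x_pop: int, n_sub: int,
                               n_reps: int, seed: int,
                               alpha: float = 0.05) -> float:
    """Empirical CI coverage under the hypergeometric nested-sampling oracle.

    The population (``x_pop`` of ``n_pop`` in the category) is held fixed
    and the subsample is drawn as a simple random sample without
    replacement, so the true RRF is exactly 1; returns the fraction of
    replicates whose confidence interval covers 1.
    """
    rng = np.random.default_rng(seed)
    x_sub = rng.hypergeometric(x_pop, n_pop - x_pop, n_sub, size=n_reps)
    covered = 0
    for x in x_sub:
        if x == 0:
            continue
        r = rrf(int(x), n_sub, x_pop, n_pop, alpha=alpha)
        if r.cl_lower <= 1.0 <= r.cl_upper:
            covered += 1
    return covered / n_reps
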