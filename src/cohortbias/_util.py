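"""Small shared helpers: rounding, seeds, dates."""

from __future__ import annotations

import datetime as _dt
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention).

    Python's built-in ``round`` is banker's rounding; published tables use
    half-up, so 1.005 -> 1.01 here.
    """
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def z_quantile(alpha: float = 0.05) -> float:
    """Two-sided normal critical value; 1.959964... at alpha=0.05."""
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit stage seeds from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def as_date(x) -> _dt.date:
    """Coerce ISO strings / datetimes / Timestamps to a ``datetime.date``."""
    if isinstance(x, _dt.datetime):
        return x.date()
    if isinstance(x, _dt.date):
        return x
    if isinstance(x, str):
        return _dt.date.fromisoformat(x[:10])
    # pandas Timestamp / numpy datetime64
    import pandas as pd

    return pd.Timestamp(x).date()


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))
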