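"""Spearman rank-correlation trends of output series against time.

Rho is the Pearson correlation of average-tie ranks. The two-sided p-value
comes from the exact permutation null for short series (n <= 8) and from the
t approximation otherwise; a trend is flagged significant at p <= 0.05 with
no multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TrendResult", "spearman_trend", "trend_matrix", "EXACT_N_MAX"]

EXACT_N_MAX = 8
ALPHA = 0.05


@dataclass(frozen=True)
class TrendResult:
    rho: float
    p_value: float
    significant: bool
    n: int

    @property
    def is_defined(self) -> bool:
        return math.isfinite(self.rho)


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_trend(series, time=None) -> TrendResult:
    """Spearman trend of a series against its time axis.

    ``series`` may be a pandas Series (index used as the time axis) or an
    array with an optional explicit ``time``. A constant series has no rank
    ordering: rho and p are returned as NaN and the trend is not significant.
    """
    if isinstance(series, pd.Series):
        values = series.to_numpy(dtype=float)
        t = series.index.to_numpy(dtype=float) if time is None else np.asarray(time, float)
    else:
        values = np.asarray(series, dtype=float)
        t = np.arange(len(values), dtype=float) if time is None else np.asarray(time, float)
    n = len(values)
    if n < 3:
        raise ValueError(f"need at least 3 points for a trend test, got {n}")
    if np.any(~np.isfinite(values)):
        raise ValueError("series has missing values")

    rho = _rank_rho(t, values)
    if not math.isfinite(rho):
        return TrendResult(float("nan"), float("nan"), False, n)

    if n <= EXACT_N_MAX:
        p = _exact_p(t, values, rho)
    else:
        p = float(stats.spearmanr(t, values).pvalue)
    return TrendResult(rho, p, p <= ALPHA, n)


def _exact_p(t: np.ndarray, values: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p: the share of value orderings whose |rho|
    reaches the observed one (ties kept as average ranks)."""
    ry = stats.rankdata(values)
    rt = stats.rankdata(t)
    perms = np.array(list(permutations(ry)))
    rt_c = rt - rt.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc**2).sum(axis=1)) * np.sqrt((rt_c**2).sum())
    rhos = pc @ rt_c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def trend_matrix(series_collection: dict[str, pd.Series] | pd.DataFrame) -> pd.DataFrame:
    """One TrendResult row per named series (tidy table: rho, p, significant, n)."""
    if isinstance(series_collection, pd.DataFrame):
        items = [(c, series_collection[c]) for c in series_collection.columns]
    else:
        items = list(series_collection.items())
    rows = []
    for name, s in items:
        r = spearman_trend(s)
        rows.append(
            dict(series=name, rho=r.rho, p=r.p_value, significant=r.significant, n=r.n)
        )
    return pd.DataFrame(rows).set_index("series")
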