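"""Environmental response functions.

A response maps a driver value (sea-surface temperature here) to a foraging
multiplier in [0, 1]: 1 inside the preferable range [q10, q90], 0 at or beyond
the tolerance limits [min, max], with linear shoulders in between. The
multiplier scales the whole consumption column of an affected predator and the
production rate of an affected producer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EnvResponse", "response_multiplier", "multiplier_series"]


@dataclass(frozen=True)
class EnvResponse:
    """Trapezoidal tolerance curve anchored at the absolute limits (min, max)
    and the 10th/90th preferable quantiles (q10, q90), all in driver units."""

    min: float
    q10: float
    q90: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.q10 <= self.q90 <= self.max):
            raise ValueError(
                f"response anchors must be ordered min <= q10 <= q90 <= max, "
                f"got ({self.min}, {self.q10}, {self.q90}, {self.max})"
            )
        if not self.min < self.max:
            raise ValueError("response needs strict min < max")

    def __call__(self, x):
        return response_multiplier(self, x)


def response_multiplier(resp: EnvResponse, x):
    """Multiplier f in [0, 1] at driver value ``x`` (scalar or array).

    Degenerate shoulders (min == q10, or q90 == max) behave as steps: the
    preferable plateau wins on the shared anchor.
    """
    x = np.asarray(x, dtype=float)
    f = np.zeros_like(x)
    lo_w = resp.q10 - resp.min
    hi_w = resp.max - resp.q90
    rising = (x > resp.min) & (x < resp.q10)
    if lo_w > 0:
        f = np.where(rising, (x - resp.min) / lo_w, f)
    falling = (x > resp.q90) & (x < resp.max)
    if hi_w > 0:
        f = np.where(falling, (resp.max - x) / hi_w, f)
    f = np.where((x >= resp.q10) & (x <= resp.q90), 1.0, f)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def multiplier_series(resp: EnvResponse, driver: pd.Series) -> pd.Series:
    """Elementwise response over a driver time series (same index back).

    Missing values are an error: the caller must supply a gap-free driver,
    no imputation is attempted here.
    """
    if driver.isna().any():
        bad = driver.index[driver.isna()].tolist()
        raise ValueError(f"driver series has missing values at {bad[:5]}")
    if len(driver) == 0:
        return driver.copy()
    return pd.Series(response_multiplier(resp, driver.to_numpy()), index=driver.index)
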