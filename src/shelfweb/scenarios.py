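"""Stressor scenarios: forcing sets for the eleven-scenario design.

Each scenario combines a fishing policy (status quo, new effort regulations,
or regulations plus a trawl closure), a temperature policy (constant or an
RCP warming track applied as anomalies on the observed SST series) and an
alien-biomass policy (free dynamics, forced along current trends, or forced
constant). Primary production is held constant in every scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PiecewiseLinear",
    "Scenario",
    "BaselineForcings",
    "ForcingSet",
    "SCENARIOS",
    "REGULATION_MULTIPLIERS",
    "scenario_table",
    "build_scenario",
    "build_sst_projection",
    "build_alien_trend_forcing",
]


class PiecewiseLinear:
    """Piecewise-linear series defined by knots, right-continuous at steps.

    A step is encoded as two knots sharing an abscissa; evaluation exactly at
    the shared abscissa returns the later (post-step) value. Evaluation
    outside the knot span is an error.
    """

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape or len(self.x) < 1:
            raise ValueError("knots must be two equal-length 1-d arrays")
        if np.any(np.diff(self.x) < 0):
            raise ValueError("knot abscissae must be non-decreasing")

    def __call__(self, t: float) -> float:
        x, y = self.x, self.y
        if t < x[0] - 1e-12 or t > x[-1] + 1e-12:
            raise ValueError(f"t={t} outside series span [{x[0]}, {x[-1]}]")
        t = min(max(t, x[0]), x[-1])
        j = int(np.searchsorted(x, t, side="right")) - 1
        if j < 0:
            return float(y[0])
        if j >= len(x) - 1:
            return float(y[-1])
        if x[j + 1] == x[j]:
            return float(y[j])
        w = (t - x[j]) / (x[j + 1] - x[j])
        return float(y[j] * (1 - w) + y[j + 1] * w)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PiecewiseLinear)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"PiecewiseLinear({self.x.tolist()}, {self.y.tolist()})"


@dataclass(frozen=True)
class Scenario:
    id: int
    name: str
    effort_policy: str  # constant | new_regulations | new_regulations_plus_trawl_closure
    temperature_policy: str  # constant | RCP26 | RCP45 | RCP85
    alien_policy: str  # model_predicts | force_trend | force_constant


SCENARIOS: dict[int, Scenario] = {
    s.id: s
    for s in [
        Scenario(1, "BAU (business as usual)", "constant", "constant", "model_predicts"),
        Scenario(2, "New fishing regulations", "new_regulations", "constant", "model_predicts"),
        Scenario(
            3, "Stop trawl", "new_regulations_plus_trawl_closure", "constant", "model_predicts"
        ),
        Scenario(
            4,
            "New fishing regulations (alien spp. constant)",
            "new_regulations",
            "constant",
            "force_constant",
        ),
        Scenario(5, "RCP2.6", "constant", "RCP26", "model_predicts"),
        Scenario(6, "RCP4.5", "constant", "RCP45", "model_predicts"),
        Scenario(7, "RCP8.5", "constant", "RCP85", "model_predicts"),
        Scenario(8, "Increase alien species", "constant", "constant", "force_trend"),
        Scenario(
            9,
            "Combination (no forcing of alien spp.)",
            "new_regulations",
            "RCP45",
            "model_predicts",
        ),
        Scenario(
            10, "Combination (forcing of alien spp.)", "new_regulations", "RCP45", "force_trend"
        ),
        Scenario(
            11,
            "Combination (forcing alien spp. constant)",
            "new_regulations",
            "RCP45",
            "force_constant",
        ),
    ]
}

# Effort multipliers under the new fishing regulations: trawl effort cut by
# ~50%, artisanal by ~15%, recreational capped (taken as a 20% cut); purse
# seine is not named by the regulations and is left unchanged.
REGULATION_MULTIPLIERS = {
    "trawl": 0.50,
    "artisanal": 0.85,
    "recreational": 0.80,
    "purse_seine": 1.00,
}
REGULATION_RAMP_YEARS = 2.0
TRAWL_CLOSURE_YEARS = 3.0


def scenario_table() -> pd.DataFrame:
    """Scenario-by-stressor state table (one row per scenario)."""
    return pd.DataFrame(
        [
            {
                "id": s.id,
                "name": s.name,
                "fishing": s.effort_policy,
                "temperature": s.temperature_policy,
                "alien": s.alien_policy,
            }
            for s in SCENARIOS.values()
        ]
    ).set_index("id")


@dataclass
class BaselineForcings:
    """Observed history up to the reference year: per-fleet relative effort
    (1.0 at the reference year), SST, alien-group biomass, plus the RCP SST
    anomaly tracks (anomaly 0 at the reference year)."""

    effort_history: dict[str, pd.Series]
    sst_history: pd.Series
    alien_biomass_history: dict[str, pd.Series]
    rcp_anomalies: dict[str, pd.Series]
    reference_year: int


@dataclass
class ForcingSet:
    """Drivers over the full simulation horizon.

    ``effort`` holds a right-continuous piecewise-linear series per fleet
    (relative, 1.0 = reference level); ``sst`` and ``pp_multiplier`` are
    annual series; ``biomass_forcing`` pins the listed groups to the given
    trajectories, overriding their dynamics.
    """

    start_year: float
    horizon: float
    effort: dict[str, PiecewiseLinear]
    sst: pd.Series
    biomass_forcing: dict[str, pd.Series] = field(default_factory=dict)
    pp_multiplier: pd.Series | None = None

    def __post_init__(self) -> None:
        years = np.arange(self.start_year, self.start_year + self.horizon + 1)
        if self.pp_multiplier is None:
            self.pp_multiplier = pd.Series(1.0, index=years)
        end = self.start_year + self.horizon
        if self.sst.index.min() > self.start_year or self.sst.index.max() < end:
            raise ValueError("SST series does not span the simulation horizon")
        for g, s in self.biomass_forcing.items():
            if s.index.min() > self.start_year or s.index.max() < end:
                raise ValueError(f"biomass forcing for {g!r} does not span the horizon")

    def sst_at(self, t: float) -> float:
        return float(np.interp(t, self.sst.index.to_numpy(float), self.sst.to_numpy(float)))

    def forced_biomass_at(self, group: str, t: float) -> float:
        s = self.biomass_forcing[group]
        return float(np.interp(t, s.index.to_numpy(float), s.to_numpy(float)))


def _reference_value(history: pd.Series, k: int = 3) -> float:
    """Reference ('current') level: mean of the last ``k`` observed years."""
    if history.isna().any():
        raise ValueError("history series has gaps")
    return float(history.sort_index().iloc[-k:].mean())


def build_sst_projection(baseline_sst: pd.Series, anomalies: pd.Series) -> pd.Series:
    """Projected SST = reference level + anomaly track.

    The reference level is the mean of the final three observed years, damping
    single-year noise; the anomaly series supplies the projection years.
    """
    if anomalies.isna().any():
        raise ValueError("anomaly series has gaps")
    ref = _reference_value(baseline_sst)
    return ref + anomalies.sort_index()


def build_alien_trend_forcing(history: pd.Series, horizon: float) -> pd.Series:
    """Extrapolate a biomass history along its current trend.

    The trend is the least-squares slope over the final five observed years,
    continued linearly from the last observation over ``horizon`` years and
    floored at zero.
    """
    history = history.sort_index()
    if history.isna().any():
        raise ValueError("biomass history has gaps")
    if len(history) < 5:
        raise ValueError(f"need >= 5 history points, got {len(history)}")
    tail = history.iloc[-5:]
    slope = float(np.polyfit(tail.index.to_numpy(float), tail.to_numpy(float), 1)[0])
    y0 = float(history.index[-1])
    b0 = float(history.iloc[-1])
    years = np.arange(y0, y0 + horizon + 1)
    values = np.maximum(b0 + slope * (years - y0), 0.0)
    return pd.Series(values, index=years)


def _effort_series(policy: str, fleet: str, start: float, horizon: float) -> PiecewiseLinear:
    end = start + horizon
    if policy == "constant":
        return PiecewiseLinear([start, end], [1.0, 1.0])
    mult = _regulation_multiplier(fleet)
    if policy == "new_regulations" or (
        policy == "new_regulations_plus_trawl_closure" and not _is_trawl(fleet)
    ):
        if mult == 1.0:
            return PiecewiseLinear([start, end], [1.0, 1.0])
        return PiecewiseLinear(
            [start, start + REGULATION_RAMP_YEARS, end], [1.0, mult, mult]
        )
    if policy == "new_regulations_plus_trawl_closure":
        return PiecewiseLinear([start, start + TRAWL_CLOSURE_YEARS, end], [1.0, 0.0, 0.0])
    raise ValueError(f"unknown effort policy {policy!r}")


def _is_trawl(fleet: str) -> bool:
    return "trawl" in fleet.lower()


def _regulation_multiplier(fleet: str) -> float:
    key = fleet.lower().replace(" ", "_")
    for name, mult in REGULATION_MULTIPLIERS.items():
        if name in key:
            return mult
    return 1.0  # fleets not named by the regulations keep their effort


def build_scenario(
    scenario_id: int, baseline: BaselineForcings, horizon: float = 50.0
) -> ForcingSet:
    """Assemble the ForcingSet for one scenario of the design table.

    All scenarios start at the baseline reference year and run ``horizon``
    years (50 by default). Effort reductions phase in linearly over the first
    two years; the trawl closure reaches zero effort at year three. Constant
    temperature means the reference SST (mean of the last three observed
    years); warming scenarios add the RCP anomaly track to that reference.
    """
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario id {scenario_id}; valid ids are 1..11")
    scn = SCENARIOS[scenario_id]
    start = float(baseline.reference_year)
    end = start + horizon
    years = np.arange(start, end + 1)

    effort = {
        fleet: _effort_series(scn.effort_policy, fleet, start, horizon)
        for fleet in baseline.effort_history
    }

    if scn.temperature_policy == "constant":
        sst = pd.Series(_reference_value(baseline.sst_history), index=years)
    else:
        key = scn.temperature_policy
        if key not in baseline.rcp_anomalies:
            raise ValueError(f"baseline lacks anomaly track for {key}")
        track = baseline.rcp_anomalies[key]
        track = track[(track.index >= start) & (track.index <= end)]
        if track.index.min() > start or track.index.max() < end:
            raise ValueError(f"anomaly track for {key} does not span {start}-{end}")
        sst = build_sst_projection(baseline.sst_history, track)

    biomass_forcing: dict[str, pd.Series] = {}
    if scn.alien_policy != "model_predicts":
        if not baseline.alien_biomass_history:
            raise ValueError(
                f"scenario {scenario_id} forces alien biomass but the baseline "
                "has no alien-group histories"
            )
        for g, hist in baseline.alien_biomass_history.items():
            if scn.alien_policy == "force_trend":
                biomass_forcing[g] = build_alien_trend_forcing(hist, horizon)
            else:  # force_constant: pinned at the reference-year level
                biomass_forcing[g] = pd.Series(float(hist.sort_index().iloc[-1]), index=years)

    return ForcingSet(
        start_year=start,
        horizon=horizon,
        effort=effort,
        sst=sst,
        biomass_forcing=biomass_forcing,
    )
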