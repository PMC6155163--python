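"""Ecological indicator suite.

Eleven indicators summarise a run: total, forage-fish, invertebrate and
predatory biomass; Kempton's biomass-diversity index of the upper trophic
web; total catch and its mean trophic level (mTLc); the biomass-weighted mean
trophic level of the community (mTLco); and three ecological-network measures
derived from the flow snapshot — Total System Throughput (TST), Finn's
Cycling Index (FCI, the recycled share of TST) and Path Length (the mean
number of compartments a unit of inflow traverses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import (
    EcopathModel,
    compute_trophic_levels,
    detritus_budget,
    total_catch_by_group,
    total_discards_by_group,
)
from .dynamics import GroupDynamics, SimulationResult

__all__ = [
    "FlowSnapshot",
    "biomass_indicators",
    "kemptons_q",
    "catch_indicators",
    "mean_tl_community",
    "flow_indicators",
    "flow_snapshot",
    "baseline_flow_snapshot",
    "indicator_series",
    "INDICATOR_NAMES",
]

INDICATOR_NAMES = [
    "TotalB", "ForF", "InvB", "PredB", "Kempton",
    "TotalC", "mTLc", "mTLco", "TST", "FCI", "PL",
]


@dataclass
class FlowSnapshot:
    """All flows at one instant (t km^-2 yr^-1), compartment-indexed by the
    model's group order.

    ``imports`` carries the external inputs: diet imports of consumers and
    the gross production of producers. ``exports`` holds landings, net export
    and the detritus surplus. ``detritus`` flags the detritus compartments so
    the cycling analysis can route ``flows_to_detritus`` into them.
    """

    q: np.ndarray  # prey x predator consumption matrix
    respiration: np.ndarray
    flows_to_detritus: np.ndarray
    exports: np.ndarray
    imports: np.ndarray
    detritus: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = self.q.shape[0]
        if self.detritus is None:
            self.detritus = np.zeros(n, dtype=bool)
        if np.any(self.respiration < -1e-9):
            bad = np.where(self.respiration < -1e-9)[0].tolist()
            raise ValueError(
                f"negative respiration for compartments {bad}: group is "
                "energetically infeasible (net growth efficiency exceeds the "
                "assimilated fraction)"
            )
        for name in ("q", "flows_to_detritus", "exports", "imports"):
            if np.any(np.asarray(getattr(self, name)) < -1e-9):
                raise ValueError(f"negative {name} flow")

    def internal_flows(self) -> np.ndarray:
        """Compartment-to-compartment flow matrix: consumption links plus the
        flows into the detritus pool(s), split equally across them."""
        f = self.q.copy()
        n_det = int(self.detritus.sum())
        if n_det:
            f += np.outer(self.flows_to_detritus, self.detritus / n_det)
        return f


def biomass_indicators(
    biomass: np.ndarray, model: EcopathModel, tls: np.ndarray
) -> tuple[float, float, float, float]:
    """(TotalB, ForF, InvB, PredB): living-group total, forage-tagged,
    benthic-invertebrate-tagged, and TL >= 4 biomass sums. Detritus (and any
    other non-living pool) is excluded from all four."""
    living = model.living()
    total = float(biomass[living].sum())
    forf = float(biomass[living & model.tagged("forage")].sum())
    invb = float(biomass[living & model.tagged("benthic_invertebrate")].sum())
    predb = float(biomass[living & (tls >= 4.0)].sum())
    return total, forf, invb, predb


def kemptons_q(biomass: np.ndarray, tls: np.ndarray) -> float:
    """Kempton's Q over the groups with TL >= 3.

    Half the qualifying group count divided by the log10 ratio of the
    interpolated upper- to lower-quartile biomasses of the ascending rank
    curve. NaN when fewer than four groups qualify or the quartile biomasses
    coincide (no diversity gradient to measure).
    """
    sel = np.asarray(biomass, dtype=float)[np.asarray(tls) >= 3.0]
    s = len(sel)
    if s < 4:
        return float("nan")
    ranked = np.sort(sel)
    ranks = np.arange(1, s + 1, dtype=float)
    b25 = float(np.interp(0.25 * s, ranks, ranked))
    b75 = float(np.interp(0.75 * s, ranks, ranked))
    if b25 <= 0 or b75 <= b25:
        return float("nan")
    return 0.5 * s / float(np.log10(b75 / b25))


def catch_indicators(catch_by_group: np.ndarray, tls: np.ndarray) -> tuple[float, float]:
    """(TotalC, mTLc): fleet-summed removals and their catch-weighted mean
    trophic level; mTLc is NaN when nothing is caught."""
    y = np.asarray(catch_by_group, dtype=float)
    if np.any(y < 0):
        raise ValueError("negative catches")
    total = float(y.sum())
    if total == 0:
        return 0.0, float("nan")
    return total, float((y * np.asarray(tls)).sum() / total)


def mean_tl_community(biomass: np.ndarray, model: EcopathModel, tls: np.ndarray) -> float:
    """Biomass-weighted mean TL over living groups (detritus excluded)."""
    living = model.living()
    b = np.asarray(biomass, dtype=float)[living]
    if b.sum() <= 0:
        raise ValueError("community has no living biomass")
    return float((b * np.asarray(tls)[living]).sum() / b.sum())


def flow_indicators(flows: FlowSnapshot) -> tuple[float, float, float]:
    """(TST, FCI, PL) from a flow snapshot.

    TST sums consumption, exports, respiration and flows to detritus. FCI
    uses the Leontief structure of the internal flow network: with G the
    input-proportion matrix (G_ij = flow i->j over the throughput of j) and
    l_jj the diagonal of (I - G)^-1, the cycled flow is
    sum_j T_j (l_jj - 1) / l_jj, reported as a percentage of TST. PL is TST
    over the total outflow (exports + respiration).
    """
    f = flows.internal_flows()
    n = f.shape[0]
    tst = float(
        flows.q.sum()
        + flows.exports.sum()
        + flows.respiration.sum()
        + flows.flows_to_detritus.sum()
    )
    throughput = f.sum(axis=0) + flows.imports
    g = np.divide(f, throughput[None, :], out=np.zeros_like(f), where=throughput[None, :] > 0)
    try:
        leontief = np.linalg.inv(np.eye(n) - g)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"ill-conditioned flow network: {exc}") from exc
    diag = np.diag(leontief)
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        raise ValueError("ill-conditioned flow network: non-positive path multipliers")
    cycled = float((throughput * (diag - 1.0) / diag).sum())
    fci = 100.0 * cycled / tst if tst > 0 else float("nan")
    outflow = float(flows.exports.sum() + flows.respiration.sum())
    pl = tst / outflow if outflow > 0 else float("nan")
    return tst, fci, pl


def flow_snapshot(
    model: EcopathModel,
    dynamics: GroupDynamics,
    biomass: np.ndarray,
    q: np.ndarray,
    landings_rate: np.ndarray,
    discards_rate: np.ndarray,
) -> FlowSnapshot:
    """Assemble the flow accounting for one simulated state.

    Consumer respiration closes the energy balance, (1 - GS) Q_j - P_j with
    P_j the realized production; flows to detritus collect unassimilated
    food, other-mortality deaths and discards; exports are landings plus net
    export plus the detritus surplus; imports are diet imports plus producer
    production.
    """
    n = model.n
    consumers = model.consumers()
    producers = model.producers()
    det = model.detritus()
    living = model.living()
    b = np.maximum(np.asarray(biomass, dtype=float), 0.0)

    intake = q.sum(axis=0) + dynamics.qb0 * dynamics.import_fraction * b
    production = np.zeros(n)
    production[consumers] = dynamics.net_growth_efficiency[consumers] * intake[consumers]
    mdd = dynamics.producer_density_dependence
    production[producers] = (
        dynamics.pb0[producers] * (1 + mdd)
        / (1 + mdd * b[producers] / dynamics.b0[producers])
        * b[producers]
    )
    respiration = np.zeros(n)
    respiration[consumers] = (1 - dynamics.gs[consumers]) * intake[consumers] - production[
        consumers
    ]
    respiration[np.abs(respiration) < 1e-12] = 0.0

    to_detritus = np.zeros(n)
    to_detritus[living] = (
        dynamics.gs[living] * intake[living]
        + dynamics.other_mortality[living] * b[living]
        + discards_rate[living]
    )

    exports = np.where(living, landings_rate - dynamics.net_migration, 0.0)
    exports = np.maximum(exports, 0.0)
    detritivory = q[det, :].sum()
    det_surplus = max(to_detritus.sum() - detritivory, 0.0)
    exports = exports + np.where(det, det_surplus / max(int(det.sum()), 1), 0.0)

    imports = dynamics.qb0 * dynamics.import_fraction * b
    imports = imports + np.where(producers, production, 0.0)

    return FlowSnapshot(
        q=q,
        respiration=respiration,
        flows_to_detritus=to_detritus,
        exports=exports,
        imports=imports,
        detritus=det,
    )


def baseline_flow_snapshot(model: EcopathModel) -> FlowSnapshot:
    """Flow accounting of the balanced snapshot itself (no dynamics needed)."""
    n = model.n
    b = model.array("biomass")
    pb = model.array("pb")
    qb = model.array("qb")
    ee = model.array("ee", fill=0.0)
    gs = model.array("gs")
    consumers = model.consumers()
    producers = model.producers()
    det = model.detritus()
    living = model.living()

    q = model.diet.dc * (b * qb)[None, :]
    intake = b * qb  # includes import share
    production = np.where(living, pb * b, 0.0)
    respiration = np.where(consumers, (1 - gs) * intake - production, 0.0)
    if np.any(respiration < -1e-9):
        bad = [model.groups[i].name for i in np.where(respiration < -1e-9)[0]]
        raise ValueError(f"negative respiration for {bad}")
    respiration = np.maximum(respiration, 0.0)

    discards = total_discards_by_group(model)
    landings = total_catch_by_group(model) - discards
    to_detritus = np.where(
        living, gs * intake + (1 - ee) * production + discards, 0.0
    )
    exports = np.maximum(np.where(living, landings - model.array("net_migration"), 0.0), 0.0)
    exports = exports + np.where(
        det, detritus_budget(model)["export"] / max(int(det.sum()), 1), 0.0
    )
    imports = qb * model.diet.import_fraction * b + np.where(producers, production, 0.0)
    return FlowSnapshot(
        q=q,
        respiration=respiration,
        flows_to_detritus=to_detritus,
        exports=exports,
        imports=imports,
        detritus=det,
    )


def indicator_series(
    result: SimulationResult,
    model: EcopathModel,
    dynamics: GroupDynamics,
    tls: np.ndarray | None = None,
) -> pd.DataFrame:
    """Annual indicator table for a run (year 1 .. horizon end).

    Trophic levels are the baseline snapshot's and are held fixed through
    time: diet rewiring over the simulation is not modelled, so the TL
    filters (PredB, Kempton) and the TL weights (mTLc, mTLco) keep their
    reference meaning.
    """
    if tls is None:
        tls = compute_trophic_levels(model)
    rows = []
    for yi in range(1, result.n_years + 1):
        b = result.biomass[:, yi]
        q = result.flows[yi]
        catch_fleet = result.catch[:, :, yi - 1]  # annual totals of the year ending here
        catch_group = catch_fleet.sum(axis=1)
        landings = (catch_fleet * (1 - dynamics.discard_fraction)).sum(axis=1)
        discards = (catch_fleet * dynamics.discard_fraction).sum(axis=1)
        totalb, forf, invb, predb = biomass_indicators(b, model, tls)
        kq = kemptons_q(b, tls)
        totalc, mtlc = catch_indicators(catch_group, tls)
        mtlco = mean_tl_community(b, model, tls)
        snap = flow_snapshot(model, dynamics, b, q, landings, discards)
        tst, fci, pl = flow_indicators(snap)
        rows.append(
            dict(
                year=result.years[yi],
                TotalB=totalb, ForF=forf, InvB=invb, PredB=predb, Kempton=kq,
                TotalC=totalc, mTLc=mtlc, mTLco=mtlco, TST=tst, FCI=fci, PL=pl,
            )
        )
    return pd.DataFrame(rows).set_index("year")
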