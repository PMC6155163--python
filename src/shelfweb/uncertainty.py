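"""Pedigree-driven Monte Carlo uncertainty propagation.

The pedigree records the data quality of every Ecopath input as a confidence
interval around the point value. Each replicate draws biomass, production and
consumption rates uniformly within those intervals, re-solves the mass
balance (rejecting energetically infeasible draws), re-calibrates the
dynamics and repeats the scenario run; the 5th and 95th percentiles across
replicates form the uncertainty envelope around the deterministic run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .balance import EcopathModel, UnbalancedModelError, solve_mass_balance
from .dynamics import simulate, calibrate
from .envresponse import EnvResponse
from .scenarios import ForcingSet

__all__ = ["Pedigree", "UncertaintyEnvelope", "draw_model", "run_monte_carlo"]

logger = logging.getLogger("shelfweb")

PEDIGREE_PARAMS = ("B", "PB", "QB")
MAX_REDRAWS = 50
MAX_FAILURE_FRACTION = 0.2


@dataclass
class Pedigree:
    """Confidence-interval half-widths, as fractions of the point value, per
    group and parameter in {B, PB, QB}. Missing entries default to 0 (the
    parameter is treated as known exactly)."""

    ci: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (g, p), v in self.ci.items():
            if p not in PEDIGREE_PARAMS:
                raise ValueError(f"pedigree parameter must be one of {PEDIGREE_PARAMS}, got {p!r}")
            if not 0 <= v <= 0.8:
                raise ValueError(f"pedigree ci for ({g}, {p}) must be in [0, 0.8], got {v}")

    def get(self, group: str, param: str) -> float:
        return self.ci.get((group, param), 0.0)

    def is_zero(self) -> bool:
        return all(v == 0 for v in self.ci.values())


@dataclass
class UncertaintyEnvelope:
    """Per-output percentile bands over replicates. ``central`` is the
    deterministic (point-estimate) run, not the replicate median, so it is
    not guaranteed to lie inside the band pointwise."""

    outputs: dict[str, dict[str, np.ndarray]]  # name -> {lower, upper, central}
    years: np.ndarray
    n_replicates: int
    n_failed: int
    seed: int


def draw_model(
    model: EcopathModel, pedigree: Pedigree, rng: np.random.Generator
) -> EcopathModel:
    """One feasible parameter draw: B, PB, QB uniform within the pedigree
    intervals, EE re-solved; draws with any EE > 1 are rejected and redrawn
    (up to 50 attempts)."""
    if not model.balanced:
        raise ValueError("Monte Carlo draws require a balanced base model")
    for _ in range(MAX_REDRAWS):
        m = model.copy()
        feasible = True
        for g in m.groups:
            ci_b = pedigree.get(g.name, "B")
            if ci_b and g.biomass is not None:
                g.biomass = g.biomass * rng.uniform(1 - ci_b, 1 + ci_b)
            if g.is_living:
                ci_pb = pedigree.get(g.name, "PB")
                if ci_pb:
                    g.pb = g.pb * rng.uniform(1 - ci_pb, 1 + ci_pb)
                if g.category == "consumer":
                    ci_qb = pedigree.get(g.name, "QB")
                    if ci_qb:
                        g.qb = g.qb * rng.uniform(1 - ci_qb, 1 + ci_qb)
                    if g.pb / g.qb >= 1:  # structurally invalid consumer draw
                        feasible = False
        if not feasible:
            continue
        m.balanced = False
        try:
            return solve_mass_balance(
                m, estimate={g.name: "EE" for g in m.groups if g.is_living}
            )
        except UnbalancedModelError:
            continue
    raise UnbalancedModelError(
        f"pedigree incompatible with balance: {MAX_REDRAWS} successive draws "
        "produced EE outside [0, 1]"
    )


def run_monte_carlo(
    model: EcopathModel,
    forcing: ForcingSet,
    pedigree: Pedigree,
    n: int = 500,
    seed: int = 0,
    years: int = 50,
    dt: float = 1.0 / 12.0,
    responses: dict[str, EnvResponse] | None = None,
    k_overrides: dict | None = None,
) -> UncertaintyEnvelope:
    """Replicate draw -> re-balance -> re-calibrate -> simulate cycles and
    collect 5%/95% bands (linear-interpolation percentiles) per output.

    Tracked outputs: each group's biomass trajectory (``B_<group>``) and the
    total annual catch (``TotalC``). Replicates that abort (failed draw or
    numerically invalid run) are logged and excluded; more than 20%
    exclusions is an error. Fully reproducible given ``seed``.
    """
    if n < 2:
        raise ValueError("need n >= 2 Monte Carlo replicates")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    central = simulate(model, *_calibrated(model, k_overrides), forcing, years, dt, responses)
    names = model.names
    n_marks = years + 1

    bio = np.full((n, model.n, n_marks), np.nan)
    totc = np.full((n, years), np.nan)
    failed = 0
    for r in range(n):
        try:
            m = draw_model(model, pedigree, np.random.default_rng(child_seeds[r]))
            res = simulate(m, *_calibrated(m, k_overrides), forcing, years, dt, responses)
        except (UnbalancedModelError, RuntimeError) as exc:
            failed += 1
            logger.warning("Monte Carlo replicate %d excluded: %s", r, exc)
            continue
        bio[r] = res.biomass
        totc[r] = res.catch.sum(axis=(0, 1))
    if failed > MAX_FAILURE_FRACTION * n:
        raise RuntimeError(
            f"{failed}/{n} Monte Carlo replicates failed (> {MAX_FAILURE_FRACTION:.0%})"
        )

    ok = ~np.isnan(bio[:, 0, 0])
    outputs: dict[str, dict[str, np.ndarray]] = {}
    for gi, name in enumerate(names):
        outputs[f"B_{name}"] = {
            "lower": np.percentile(bio[ok, gi, :], 5, axis=0),
            "upper": np.percentile(bio[ok, gi, :], 95, axis=0),
            "central": central.biomass[gi, :],
        }
    outputs["TotalC"] = {
        "lower": np.percentile(totc[ok], 5, axis=0),
        "upper": np.percentile(totc[ok], 95, axis=0),
        "central": central.catch.sum(axis=(0, 1)),
    }
    return UncertaintyEnvelope(
        outputs=outputs,
        years=central.years,
        n_replicates=n,
        n_failed=failed,
        seed=seed,
    )


def _calibrated(model: EcopathModel, k_overrides):
    return calibrate(model, k_overrides=k_overrides)
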