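"""Synthetic balanced food webs and baseline forcings.

The generator emulates the structure the analysis assumes for an exploited,
invaded, warming coastal shelf: a producer and a detritus pool at the base,
native and alien invertebrate and fish groups in the middle, top predators and
a vulnerable megafauna group on top, three fishing fleets (trawl, artisanal,
recreational; a purse seine as a fourth when asked), warm-shifted thermal
niches for alien groups, and a 17-year observed history of declining fishing
effort, mildly warming SST and rising alien biomass. Parameters are drawn
around fixed role archetypes, the mass balance is solved for EE, and webs are
re-drawn until they are balanced and locally stable at the calibrated
equilibrium, so downstream property tests are not flaky. Everything is
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import (
    BalanceError,
    DietMatrix,
    EcopathModel,
    Fleet,
    FunctionalGroup,
    UnbalancedModelError,
    solve_mass_balance,
)
from .dynamics import calibrate, jacobian_at_baseline
from .envresponse import EnvResponse
from .scenarios import BaselineForcings
from .uncertainty import Pedigree

__all__ = ["GeneratorConfig", "generate_web", "generate_baseline_forcing", "new_alien_k_overrides"]

MAX_ATTEMPTS = 100


@dataclass(frozen=True)
class ThermalRegime:
    """Preferable SST ranges (q10, q90) for native and alien groups, and the
    baseline SST; alien ranges sit warm of native ones. Tolerance limits are
    set 3-4 degC beyond the preferable bounds."""

    native_pref_range: tuple[float, float] = (18.0, 27.5)
    alien_pref_range: tuple[float, float] = (24.0, 34.0)
    baseline_sst: float = 26.0


@dataclass(frozen=True)
class GeneratorConfig:
    n_groups: int = 12
    n_fleets: int = 3
    alien_fraction: float = 0.3
    seed: int = 0
    thermal_regime: ThermalRegime = field(default_factory=ThermalRegime)

    def __post_init__(self) -> None:
        if self.n_groups < 6:
            raise ValueError("need n_groups >= 6 (producer, detritus, 2 native, alien, top)")
        if not 1 <= self.n_fleets <= 4:
            raise ValueError("n_fleets must be in 1..4")
        if not 0 <= self.alien_fraction <= 0.6:
            raise ValueError("alien_fraction must be in [0, 0.6]")


# Role archetypes: name, category, tags, point values for B, PB, QB, GS and a
# diet template (prey archetype -> weight). Values are in the range typical of
# coastal-shelf trophic models (biomass t km^-2, rates yr^-1).
_ARCHETYPES = [
    dict(name="phytoplankton", category="producer", tags=(), b=15.0, pb=70.0, qb=0.0, gs=0.0,
         diet={}),
    dict(name="detritus", category="detritus", tags=(), b=30.0, pb=0.0, qb=0.0, gs=0.0,
         diet={}),
    dict(name="zooplankton", category="consumer", tags=("native",), b=6.0, pb=25.0, qb=90.0,
         gs=0.3, diet={"phytoplankton": 0.85, "detritus": 0.15}),
    dict(name="native_benthic_invertebrates", category="consumer",
         tags=("native", "benthic_invertebrate"), b=10.0, pb=3.5, qb=14.0, gs=0.4,
         diet={"detritus": 0.7, "phytoplankton": 0.2, "zooplankton": 0.1}),
    dict(name="alien_benthic_invertebrates", category="consumer",
         tags=("alien", "benthic_invertebrate"), b=4.0, pb=3.0, qb=12.0, gs=0.4,
         diet={"detritus": 0.6, "phytoplankton": 0.15, "zooplankton": 0.1,
               "native_benthic_invertebrates": 0.15}),
    dict(name="native_forage_fish", category="consumer", tags=("native", "forage"),
         b=4.0, pb=1.6, qb=8.0, gs=0.2,
         diet={"zooplankton": 0.8, "phytoplankton": 0.1, "native_benthic_invertebrates": 0.1}),
    dict(name="native_small_demersal_fish", category="consumer", tags=("native",),
         b=3.0, pb=1.2, qb=6.0, gs=0.2,
         diet={"native_benthic_invertebrates": 0.5, "alien_benthic_invertebrates": 0.2,
               "zooplankton": 0.2, "detritus": 0.1}),
    dict(name="alien_demersal_fish", category="consumer", tags=("alien",),
         b=1.5, pb=1.1, qb=5.5, gs=0.2,
         diet={"native_benthic_invertebrates": 0.4, "alien_benthic_invertebrates": 0.3,
               "zooplankton": 0.2, "native_forage_fish": 0.1}),
    dict(name="new_alien_demersal_fish", category="consumer", tags=("alien", "new_alien"),
         b=0.6, pb=1.0, qb=5.0, gs=0.2,
         diet={"alien_benthic_invertebrates": 0.4, "native_benthic_invertebrates": 0.3,
               "native_forage_fish": 0.15, "native_small_demersal_fish": 0.15}),
    dict(name="native_large_demersal_fish", category="consumer", tags=("native",),
         b=1.2, pb=0.7, qb=3.2, gs=0.2,
         diet={"native_forage_fish": 0.35, "native_small_demersal_fish": 0.3,
               "alien_demersal_fish": 0.2, "new_alien_demersal_fish": 0.05,
               "native_benthic_invertebrates": 0.1}),
    dict(name="demersal_sharks", category="consumer", tags=("native", "vulnerable"),
         b=0.4, pb=0.4, qb=2.0, gs=0.2,
         diet={"native_large_demersal_fish": 0.3, "native_small_demersal_fish": 0.2,
               "native_forage_fish": 0.2, "alien_demersal_fish": 0.2,
               "new_alien_demersal_fish": 0.1}),
    dict(name="vulnerable_megafauna", category="consumer", tags=("native", "vulnerable"),
         b=0.25, pb=0.25, qb=1.8, gs=0.2,
         diet={"native_benthic_invertebrates": 0.3, "alien_benthic_invertebrates": 0.2,
               "native_forage_fish": 0.3, "native_small_demersal_fish": 0.2}),
]

# Baseline fishing mortalities (catch / biomass at reference effort) per fleet
# and target archetype, with the fleet's discard share of its catch.
_FLEET_TARGETS = {
    "trawl": dict(
        rates={"native_benthic_invertebrates": 0.05, "alien_benthic_invertebrates": 0.05,
               "native_small_demersal_fish": 0.15, "alien_demersal_fish": 0.10,
               "new_alien_demersal_fish": 0.05, "native_large_demersal_fish": 0.12,
               "demersal_sharks": 0.03, "vulnerable_megafauna": 0.02},
        discard_share=0.15,
    ),
    "artisanal": dict(
        rates={"native_large_demersal_fish": 0.08, "demersal_sharks": 0.04,
               "native_forage_fish": 0.05, "native_small_demersal_fish": 0.05},
        discard_share=0.02,
    ),
    "recreational": dict(
        rates={"native_large_demersal_fish": 0.04, "native_small_demersal_fish": 0.03,
               "demersal_sharks": 0.01},
        discard_share=0.02,
    ),
    "purse_seine": dict(
        rates={"native_forage_fish": 0.10, "zooplankton": 0.0},
        discard_share=0.02,
    ),
}

# Archetypes eligible to switch between native and alien identity when the
# requested alien fraction departs from the default mix.
_ALIEN_ARCHETYPES = [
    "alien_benthic_invertebrates", "alien_demersal_fish", "new_alien_demersal_fish"
]


def _select_archetypes(n_groups: int) -> list[dict]:
    """First n archetypes by priority; beyond 12, mid-trophic archetypes are
    duplicated with a numeric suffix."""
    base = list(_ARCHETYPES)
    if n_groups <= len(base):
        # keep producer, detritus, an alien group and a top predator in any cut
        priority = [0, 1, 2, 3, 4, 5, 9, 10, 6, 7, 8, 11]
        keep = sorted(priority[:n_groups])
        return [dict(base[i]) for i in keep]
    out = [dict(a) for a in base]
    extras = [3, 6, 7, 5]  # invertebrates and mid-trophic fish scale out first
    i = 0
    while len(out) < n_groups:
        src = dict(base[extras[i % len(extras)]])
        i += 1
        src["name"] = f"{src['name']}_{i + 1}"
        out.append(src)
    return out


def _apply_alien_fraction(archetypes: list[dict], frac: float) -> None:
    """Retag archetypes so roughly ``frac`` of the living groups are alien."""
    living = [a for a in archetypes if a["category"] == "consumer"]
    target = int(round(frac * len(living)))
    aliens = [a for a in archetypes if "alien" in a["tags"]]
    if target == 0:
        for a in aliens:
            a["tags"] = tuple(t for t in a["tags"] if t not in ("alien", "new_alien"))
            a["tags"] = a["tags"] + ("native",)
            a["name"] = a["name"].replace("alien", "native2")
        # fix diet keys referencing renamed groups
        renames = {"alien_benthic_invertebrates": "native2_benthic_invertebrates",
                   "alien_demersal_fish": "native2_demersal_fish",
                   "new_alien_demersal_fish": "new_native2_demersal_fish"}
        for a in archetypes:
            a["diet"] = {renames.get(k, k): v for k, v in a["diet"].items()}
    elif target < len(aliens):
        demote = [a for a in aliens if "new_alien" not in a["tags"]][: len(aliens) - target]
        for a in demote:
            a["tags"] = tuple(t for t in a["tags"] if t != "alien") + ("native",)


def _draw_web(config: GeneratorConfig, rng: np.random.Generator) -> tuple[EcopathModel, dict]:
    archetypes = _select_archetypes(config.n_groups)
    _apply_alien_fraction(archetypes, config.alien_fraction)
    names = [a["name"] for a in archetypes]

    groups = []
    for a in archetypes:
        jit = rng.uniform(0.85, 1.15, size=3)
        groups.append(
            FunctionalGroup(
                name=a["name"],
                category=a["category"],
                biomass=a["b"] * jit[0],
                pb=a["pb"] * jit[1] if a["category"] != "detritus" else 0.0,
                qb=a["qb"] * jit[2] if a["category"] == "consumer" else 0.0,
                ee=None,
                gs=a["gs"],
                role_tags=frozenset(a["tags"]),
            )
        )

    n = len(groups)
    dc = np.zeros((n, n))
    for j, a in enumerate(archetypes):
        if not a["diet"]:
            continue
        for prey, w in a["diet"].items():
            if prey in names:
                dc[names.index(prey), j] = w * rng.uniform(0.8, 1.2)
        col = dc[:, j].sum()
        if col <= 0:
            raise BalanceError(f"archetype {a['name']!r} has no prey in the web")
        dc[:, j] /= col
    diet = DietMatrix(dc=dc, import_fraction=np.zeros(n))

    fleets = []
    fleet_names = list(_FLEET_TARGETS)[: config.n_fleets]
    for fname in fleet_names:
        targets = _FLEET_TARGETS[fname]
        landings: dict[str, float] = {}
        discards: dict[str, float] = {}
        for target, f_rate in targets["rates"].items():
            if target not in names or f_rate == 0:
                continue
            gi = names.index(target)
            total = f_rate * groups[gi].biomass * rng.uniform(0.8, 1.2)
            d = total * targets["discard_share"]
            landings[target] = total - d
            if d > 0:
                discards[target] = d
        if sum(landings.values()) + sum(discards.values()) > 0:
            fleets.append(Fleet(fname, landings, discards))

    model = EcopathModel(groups=groups, diet=diet, fleets=fleets,
                         area_note=f"synthetic shelf web (seed {config.seed})")
    balanced = solve_mass_balance(model)
    return balanced, {"names": names}


def _thermal_responses(
    model: EcopathModel, regime: ThermalRegime, rng: np.random.Generator
) -> dict[str, EnvResponse]:
    """Trapezoids per group: aliens on the warm niche, native fish and
    invertebrates on the cool one; plankton, detritus and air-breathing
    megafauna are left temperature-insensitive."""
    insensitive = {"phytoplankton", "detritus", "zooplankton", "vulnerable_megafauna"}
    responses: dict[str, EnvResponse] = {}
    for g in model.groups:
        if g.name in insensitive or not g.is_living:
            continue
        lo, hi = (
            regime.alien_pref_range if "alien" in g.role_tags else regime.native_pref_range
        )
        jl = rng.uniform(-0.3, 0.3)
        jh = rng.uniform(-0.3, 0.3)
        q10, q90 = lo + jl, hi + jh
        responses[g.name] = EnvResponse(min=q10 - 4.0, q10=q10, q90=q90, max=q90 + 3.0)
    return responses


def new_alien_k_overrides(model: EcopathModel, k: float = 10.0) -> dict[str, float]:
    """Vulnerability overrides for newly established alien predators: their
    biomass is still far below capacity, so their links carry a high
    multiplier (k = 10) instead of the default 2."""
    return {g.name: k for g in model.groups if "new_alien" in g.role_tags}


def generate_web(
    config: GeneratorConfig,
) -> tuple[EcopathModel, dict[str, EnvResponse], Pedigree]:
    """Generate a balanced, locally stable synthetic web.

    Parameters are drawn around the role archetypes, the balance is solved
    for EE, and the draw is rejected unless every EE lies in [0, 1], the
    baseline SST sits inside every group's preferable range, and the
    calibrated dynamics are locally stable at baseline (all Jacobian
    eigenvalues with non-positive real part). Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    last_err: Exception | None = None
    for attempt in range(MAX_ATTEMPTS):
        try:
            model, _ = _draw_web(config, rng)
        except (UnbalancedModelError, BalanceError) as exc:
            last_err = exc
            continue
        responses = _thermal_responses(model, config.thermal_regime, rng)
        sst0 = config.thermal_regime.baseline_sst
        if any(not (r.q10 <= sst0 <= r.q90) for r in responses.values()):
            last_err = BalanceError("baseline SST outside a preferable range")
            continue
        try:
            params, dyn = calibrate(model, k_overrides=new_alien_k_overrides(model))
        except BalanceError as exc:
            last_err = exc
            continue
        jac = jacobian_at_baseline(model, params, dyn)
        if np.max(np.linalg.eigvals(jac).real) > 1e-6:
            last_err = BalanceError("baseline equilibrium not locally stable")
            continue
        pedigree = Pedigree(
            ci={
                (g.name, p): float(rng.uniform(0.1, 0.4))
                for g in model.groups
                if g.is_living
                for p in (("B", "PB", "QB") if g.category == "consumer" else ("B", "PB"))
            }
        )
        return model, responses, pedigree
    raise BalanceError(
        f"could not generate a balanced stable web in {MAX_ATTEMPTS} attempts "
        f"(last failure: {last_err})"
    )


def generate_baseline_forcing(
    config: GeneratorConfig, years_history: int = 17, model: EcopathModel | None = None
) -> BaselineForcings:
    """Observed-history emulation: per-fleet effort easing down to the
    reference level over the last years, SST with a mild warming trend plus
    noise ending at the regime's baseline, rising alien biomass ending at the
    balanced snapshot value, and smooth RCP anomaly tracks ordered
    RCP2.6 < RCP4.5 < RCP8.5 at the end of the 50-year horizon.
    """
    rng = np.random.default_rng(config.seed + 10_000)
    ref_year = 2010
    years = np.arange(ref_year - years_history + 1, ref_year + 1)
    rel = (years - years[0]) / (years[-1] - years[0])

    fleet_names = list(_FLEET_TARGETS)[: config.n_fleets]
    effort_history = {}
    for i, fname in enumerate(fleet_names):
        start = 1.2 + 0.1 * rng.uniform(-1, 1)
        decline = np.where(rel < 0.75, start + (1.05 - start) * rel / 0.75,
                           1.05 + (1.0 - 1.05) * (rel - 0.75) / 0.25)
        noise = rng.normal(0, 0.02, size=len(years))
        noise[-1] = 0.0  # effort is 1.0 by definition at the reference year
        effort_history[fname] = pd.Series(np.maximum(decline + noise, 0.1), index=years)

    sst0 = config.thermal_regime.baseline_sst
    sst = sst0 - 0.5 + 0.5 * rel + rng.normal(0, 0.12, size=len(years))
    sst[-1] = sst0
    sst_history = pd.Series(sst, index=years)

    if model is None:  # same seed -> same web, so histories end at its B0
        model, _, _ = generate_web(config)
    alien_names: list[str] = []
    b0 = {}
    for g in model.groups:
        if "alien" in g.role_tags:
            alien_names.append(g.name)
            b0[g.name] = g.biomass
    alien_history = {}
    for name in alien_names:
        growth = 0.02 + 0.01 * rng.uniform(0, 1)  # fraction of B0 per year
        traj = b0[name] * (1 - growth * (years[-1] - years))
        traj = traj * (1 + rng.normal(0, 0.01, size=len(years)))
        traj[-1] = b0[name]
        alien_history[name] = pd.Series(np.maximum(traj, 0.01 * b0[name]), index=years)

    horizon = np.arange(ref_year, ref_year + 51)
    s = (horizon - ref_year) / 50.0
    rcp = {
        "RCP26": pd.Series(0.6 * (1 - (1 - s) ** 2), index=horizon),
        "RCP45": pd.Series(1.8 * s * (0.5 + 0.5 * s), index=horizon),
        "RCP85": pd.Series(3.5 * s**2, index=horizon),
    }

    return BaselineForcings(
        effort_history=effort_history,
        sst_history=sst_history,
        alien_biomass_history=alien_history,
        rcp_anomalies=rcp,
        reference_year=ref_year,
    )
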