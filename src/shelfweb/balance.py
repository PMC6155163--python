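"""Static food-web snapshot: functional groups, diet matrix, fleets, and the
mass-balance solve that initializes the dynamic model.

The snapshot follows the classical trophic mass-balance formulation: for every
living group i,

    B_i * PB_i * EE_i = sum_j B_j * QB_j * DC(i, j) + Y_i + BA_i + E_i

where B is biomass (t km^-2), PB the production/biomass ratio (yr^-1), QB the
consumption/biomass ratio (yr^-1), EE the ecotrophic efficiency (fraction of
production used within the system), DC(i, j) the fraction of prey i in the diet
of predator j, Y_i the fisheries removal (landings + discards), BA_i the
biomass accumulation and E_i the net export (emigration minus immigration).
For each group exactly one of {B, EE} may be unknown; the balance is then a
linear system in the unknowns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FunctionalGroup",
    "DietMatrix",
    "Fleet",
    "EcopathModel",
    "BalanceError",
    "UnbalancedModelError",
    "solve_mass_balance",
    "compute_trophic_levels",
    "total_catch_by_group",
    "detritus_budget",
]

CATEGORIES = ("consumer", "producer", "detritus")
ROLE_TAGS = frozenset(
    {"native", "alien", "forage", "benthic_invertebrate", "vulnerable", "new_alien"}
)

_ATOL = 1e-9


class BalanceError(ValueError):
    """Raised when a model violates a structural precondition."""


class UnbalancedModelError(BalanceError):
    """Raised when the solved snapshot is energetically infeasible (EE outside
    [0, 1], or detritus demand exceeding detritus supply)."""

    def __init__(self, message: str, offending_groups: list[str] | None = None):
        super().__init__(message)
        self.offending_groups = offending_groups or []


@dataclass
class FunctionalGroup:
    """One compartment of the food web.

    ``biomass`` (t km^-2) or ``ee`` may be ``None`` when it is the quantity the
    balance solve should estimate. ``net_migration`` is immigration minus
    emigration (t km^-2 yr^-1); its negative enters the balance as net export.
    """

    name: str
    category: str
    biomass: float | None = None
    pb: float = 0.0  # production/biomass, yr^-1
    qb: float = 0.0  # consumption/biomass, yr^-1
    ee: float | None = None  # ecotrophic efficiency
    gs: float = 0.0  # unassimilated fraction of consumption
    ba: float = 0.0  # biomass accumulation, t km^-2 yr^-1
    net_migration: float = 0.0  # immigration - emigration, t km^-2 yr^-1
    role_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise BalanceError(f"unknown category {self.category!r} for {self.name!r}")
        bad = set(self.role_tags) - ROLE_TAGS
        if bad:
            raise BalanceError(f"unknown role tags {sorted(bad)} for {self.name!r}")
        self.role_tags = frozenset(self.role_tags)
        if not 0.0 <= self.gs < 1.0:
            raise BalanceError(f"{self.name!r}: GS must be in [0, 1), got {self.gs}")
        if self.category == "consumer":
            if self.qb <= 0:
                raise BalanceError(f"consumer {self.name!r} needs QB > 0")
            if self.pb / self.qb >= 1:
                raise BalanceError(f"consumer {self.name!r} needs PB/QB < 1")
        if self.category == "producer" and self.qb != 0:
            raise BalanceError(f"producer {self.name!r} must have QB = 0")
        if self.biomass is not None:
            if self.category == "detritus":
                if self.biomass < 0:
                    raise BalanceError(f"detritus {self.name!r} needs B >= 0")
            elif self.biomass <= 0:
                raise BalanceError(f"living group {self.name!r} needs B > 0")

    @property
    def is_living(self) -> bool:
        return self.category != "detritus"


@dataclass
class DietMatrix:
    """Diet fractions, entry (i, j) = fraction of prey i in predator j's diet.

    Columns of producers and detritus are all zero; consumer columns plus the
    per-predator import fraction sum to one.
    """

    dc: np.ndarray
    import_fraction: np.ndarray

    def validate(self, groups: list[FunctionalGroup]) -> None:
        n = len(groups)
        if self.dc.shape != (n, n):
            raise BalanceError(f"diet matrix shape {self.dc.shape} != ({n}, {n})")
        if self.import_fraction.shape != (n,):
            raise BalanceError("import_fraction must have one entry per group")
        if np.any(self.dc < -_ATOL) or np.any(self.dc > 1 + _ATOL):
            raise BalanceError("diet fractions must lie in [0, 1]")
        for j, g in enumerate(groups):
            col = self.dc[:, j].sum() + self.import_fraction[j]
            if g.category == "consumer":
                if abs(col - 1.0) > 1e-9:
                    raise BalanceError(
                        f"diet column of consumer {g.name!r} sums to {col:.12g}, not 1"
                    )
            else:
                if self.dc[:, j].any() or self.import_fraction[j]:
                    raise BalanceError(
                        f"{g.category} {g.name!r} must have an all-zero diet column"
                    )


@dataclass
class Fleet:
    """A fishing fleet with per-group landings and discards (t km^-2 yr^-1)."""

    name: str
    landings: dict[str, float] = field(default_factory=dict)
    discards: dict[str, float] = field(default_factory=dict)
    baseline_effort: float = 1.0

    def __post_init__(self) -> None:
        for d in (self.landings, self.discards):
            for g, v in d.items():
                if v < 0:
                    raise BalanceError(f"fleet {self.name!r}: negative catch on {g!r}")
        if self.total_catch() <= 0:
            raise BalanceError(f"fleet {self.name!r} has zero total catch")

    def total_catch(self) -> float:
        return sum(self.landings.values()) + sum(self.discards.values())

    def catch_of(self, group: str) -> float:
        return self.landings.get(group, 0.0) + self.discards.get(group, 0.0)


@dataclass
class EcopathModel:
    """Ordered groups, diet matrix and fleets; the group order is the single
    authoritative index shared by all matrices."""

    groups: list[FunctionalGroup]
    diet: DietMatrix
    fleets: list[Fleet] = field(default_factory=list)
    area_note: str = ""
    balanced: bool = False

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise BalanceError("duplicate group names")
        cats = [g.category for g in self.groups]
        if "producer" not in cats or "detritus" not in cats:
            raise BalanceError("model needs at least one producer and one detritus group")
        self.diet.validate(self.groups)
        for f in self.fleets:
            unknown = (set(f.landings) | set(f.discards)) - set(names)
            if unknown:
                raise BalanceError(f"fleet {f.name!r} catches unknown groups {sorted(unknown)}")

    # -- indexing helpers -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def n(self) -> int:
        return len(self.groups)

    def living(self) -> np.ndarray:
        return np.array([g.is_living for g in self.groups])

    def consumers(self) -> np.ndarray:
        return np.array([g.category == "consumer" for g in self.groups])

    def producers(self) -> np.ndarray:
        return np.array([g.category == "producer" for g in self.groups])

    def detritus(self) -> np.ndarray:
        return np.array([g.category == "detritus" for g in self.groups])

    def tagged(self, tag: str) -> np.ndarray:
        return np.array([tag in g.role_tags for g in self.groups])

    def array(self, attr: str, fill: float = np.nan) -> np.ndarray:
        out = np.empty(self.n)
        for i, g in enumerate(self.groups):
            v = getattr(g, attr)
            out[i] = fill if v is None else v
        return out

    def copy(self) -> "EcopathModel":
        return EcopathModel(
            groups=[replace(g) for g in self.groups],
            diet=DietMatrix(self.diet.dc.copy(), self.diet.import_fraction.copy()),
            fleets=[
                Fleet(f.name, dict(f.landings), dict(f.discards), f.baseline_effort)
                for f in self.fleets
            ],
            area_note=self.area_note,
            balanced=self.balanced,
        )


def total_catch_by_group(model: EcopathModel) -> np.ndarray:
    """Fleet-summed removals Y_i = sum_f (landings_if + discards_if)."""
    y = np.zeros(model.n)
    for f in model.fleets:
        for i, g in enumerate(model.groups):
            y[i] += f.catch_of(g.name)
    return y


def total_discards_by_group(model: EcopathModel) -> np.ndarray:
    d = np.zeros(model.n)
    for f in model.fleets:
        for i, g in enumerate(model.groups):
            d[i] += f.discards.get(g.name, 0.0)
    return d


def solve_mass_balance(
    model: EcopathModel, estimate: dict[str, str] | None = None
) -> EcopathModel:
    """Fill the unknown B or EE of every group so the balance closes.

    ``estimate`` maps group name to ``"EE"`` or ``"B"``; by default the choice
    is inferred from which field is ``None`` (a living group with both set has
    its EE re-estimated, the common bookkeeping when re-balancing a perturbed
    model). Returns a new balanced model; the input is untouched.

    Raises :class:`UnbalancedModelError` when any solved EE falls outside
    [0, 1] or detritus demand exceeds supply, and :class:`BalanceError` when
    the linear system is structurally indeterminate.
    """
    m = model.copy()
    n = m.n
    living = m.living()
    det = m.detritus()

    # Decide per-group unknown.
    unknowns: list[tuple[int, str]] = []
    for i, g in enumerate(m.groups):
        if not g.is_living:
            continue
        choice = (estimate or {}).get(g.name)
        if choice is None:
            if g.ee is None and g.biomass is None:
                raise BalanceError(f"group {g.name!r}: both B and EE unknown")
            choice = "EE" if g.ee is None or g.biomass is not None else "B"
        choice = choice.upper()
        if choice not in ("EE", "B"):
            raise BalanceError(f"group {g.name!r}: estimate must be 'EE' or 'B'")
        if choice == "B" and g.ee is None:
            raise BalanceError(f"group {g.name!r}: cannot estimate B without EE")
        if choice == "EE" and g.biomass is None:
            raise BalanceError(f"group {g.name!r}: cannot estimate EE without B")
        unknowns.append((i, choice))

    y = total_catch_by_group(m)
    dc = m.diet.dc
    pb = m.array("pb")
    qb = m.array("qb")
    ba = m.array("ba")
    net_export = -m.array("net_migration")

    b_known = m.array("biomass")
    ee_known = m.array("ee")
    unk_b = {i for i, c in unknowns if c == "B"}
    unk_ee = {i for i, c in unknowns if c == "EE"}
    b0 = np.where([i in unk_b for i in range(n)], 0.0, np.nan_to_num(b_known))
    ee0 = np.where([i in unk_ee for i in range(n)], 0.0, np.nan_to_num(ee_known))

    rows = [i for i in range(n) if living[i]]
    nu = len(unknowns)
    if nu != len(rows):
        raise BalanceError(
            f"{len(rows)} balance equations but {nu} unknowns; "
            "each living group needs exactly one unknown"
        )

    # Residual with unknowns at zero gives the constant part of each equation.
    def residual(b: np.ndarray, ee: np.ndarray) -> np.ndarray:
        predation = dc @ (b * qb)
        return b * pb * ee - predation - y - ba - net_export

    c = residual(b0, ee0)

    a = np.zeros((len(rows), nu))
    for col, (g, kind) in enumerate(unknowns):
        if kind == "EE":
            r = rows.index(g)
            a[r, col] = b0[g] * pb[g]
        else:  # unknown B_g: production term in row g, predation term in all rows
            for r, i in enumerate(rows):
                a[r, col] -= qb[g] * dc[i, g]
            a[rows.index(g), col] += pb[g] * ee0[g]

    try:
        x = np.linalg.solve(a, -c[rows])
    except np.linalg.LinAlgError as exc:
        raise BalanceError(f"structurally indeterminate balance system: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise BalanceError("structurally indeterminate balance system: non-finite solution")

    for (g, kind), val in zip(unknowns, x):
        if kind == "EE":
            m.groups[g].ee = float(val)
        else:
            m.groups[g].biomass = float(val)

    # Verify.
    b = m.array("biomass")
    ee = m.array("ee")
    res = residual(b, ee)
    bad_ee = [
        m.groups[i].name
        for i in range(n)
        if living[i] and not (-1e-9 <= ee[i] <= 1 + 1e-9)
    ]
    if bad_ee:
        raise UnbalancedModelError(
            "unbalanced model: EE outside [0, 1] for " + ", ".join(bad_ee), bad_ee
        )
    for i in range(n):
        if living[i] and abs(res[i]) > _ATOL * max(1.0, b[i] * pb[i]):
            raise BalanceError(
                f"balance residual {res[i]:.3e} too large for {m.groups[i].name!r}"
            )
        if living[i]:
            m.groups[i].ee = float(min(max(ee[i], 0.0), 1.0))

    # Detritus closure: EE = detritivory / inflow, surplus leaves as export.
    inflow, detritivory = _detritus_flows(m)
    for i in range(n):
        if det[i]:
            if detritivory[i] > inflow[i] * (1 + 1e-9) + _ATOL:
                raise UnbalancedModelError(
                    f"unbalanced model: detritivory on {m.groups[i].name!r} "
                    f"({detritivory[i]:.6g}) exceeds detritus inflow ({inflow[i]:.6g})",
                    [m.groups[i].name],
                )
            m.groups[i].ee = float(detritivory[i] / inflow[i]) if inflow[i] > 0 else 0.0

    m.balanced = True
    return m


def _detritus_flows(m: EcopathModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-detritus-group (inflow, detritivory).

    Inflow = unassimilated consumption + non-predation deaths + discards,
    split equally across detritus groups (one group in practice).
    """
    b = m.array("biomass")
    qb = m.array("qb")
    pb = m.array("pb")
    ee = m.array("ee", fill=0.0)
    gs = m.array("gs")
    living = m.living()
    det = m.detritus()

    unassim = float(np.sum(gs * qb * b))
    deaths = float(np.sum(np.where(living, (1 - np.nan_to_num(ee)) * b * pb, 0.0)))
    discards = float(total_discards_by_group(m).sum())
    n_det = int(det.sum())
    inflow = np.where(det, (unassim + deaths + discards) / n_det, 0.0)
    detritivory = np.where(det, m.diet.dc @ (b * qb), 0.0)
    return inflow, detritivory


def detritus_budget(model: EcopathModel) -> dict[str, float]:
    """Baseline detritus budget of a balanced model: inflow, detritivory and
    the export term that closes the pool at equilibrium."""
    if not model.balanced:
        raise BalanceError("detritus budget requires a balanced model")
    inflow, detritivory = _detritus_flows(model)
    det = model.detritus()
    return {
        "inflow": float(inflow[det].sum()),
        "detritivory": float(detritivory[det].sum()),
        "export": float((inflow[det] - detritivory[det]).sum()),
    }


def compute_trophic_levels(model: EcopathModel) -> np.ndarray:
    """Fractional trophic levels: 1 for producers and detritus, and for each
    consumer 1 + the diet-weighted mean TL of its prey, with the import share
    of the diet removed and the remainder renormalized. Solved as a linear
    system; the fixed point is unique whenever every consumer's diet chain
    grounds out in a producer or detritus pool.
    """
    n = model.n
    dc = model.diet.dc
    imp = model.diet.import_fraction
    a = np.eye(n)
    b = np.ones(n)
    for j, g in enumerate(model.groups):
        if g.category != "consumer":
            continue
        dom = 1.0 - imp[j]
        if dom <= 1e-12:
            raise BalanceError(
                f"TL undefined under import convention for {g.name!r} (diet is 100% import)"
            )
        a[j, :] -= dc[:, j] / dom
        # row stays TL_j - sum_i dc'(i,j) TL_i = 1
    try:
        tl = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate webs
        raise BalanceError(f"trophic-level system is singular: {exc}") from exc
    if np.any(tl < 1 - 1e-9) or not math.isfinite(float(tl.sum())):
        raise BalanceError("trophic-level solution is infeasible")
    return tl
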