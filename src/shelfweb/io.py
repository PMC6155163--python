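"""CSV/YAML readers and writers and the run manifest.

A model directory holds groups.csv (one row per functional group, unknowns
blank), diet.csv (square prey-by-predator matrix with a final ``import``
row), fleets.csv (long format), and optionally responses.csv and
pedigree.csv. Files are name-keyed; group order in groups.csv is the
authoritative index. All writers are deterministic: stable row order, ten
significant digits.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balance import (
    BalanceError,
    DietMatrix,
    EcopathModel,
    Fleet,
    FunctionalGroup,
)
from .envresponse import EnvResponse
from .scenarios import BaselineForcings, ForcingSet
from .uncertainty import Pedigree, UncertaintyEnvelope

__all__ = [
    "read_model",
    "write_model",
    "write_baseline",
    "read_baseline",
    "write_results",
    "write_manifest",
    "read_manifest",
    "verify_manifest",
]

_FLOAT_FMT = "%.10g"
_GROUP_COLUMNS = [
    "name", "category", "biomass", "production_rate", "consumption_rate",
    "ecotrophic_efficiency", "unassimilated_fraction", "biomass_accumulation",
    "net_migration", "role_tags",
]


def _fmt(x: float | None) -> str:
    return "" if x is None else _FLOAT_FMT % x


# ---------------------------------------------------------------- model IO


def write_model(
    model: EcopathModel,
    directory: str | Path,
    responses: dict[str, EnvResponse] | None = None,
    pedigree: Pedigree | None = None,
) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    rows = []
    for g in model.groups:
        rows.append({
            "name": g.name,
            "category": g.category,
            "biomass": _fmt(g.biomass),
            "production_rate": _fmt(g.pb),
            "consumption_rate": _fmt(g.qb),
            "ecotrophic_efficiency": _fmt(g.ee),
            "unassimilated_fraction": _fmt(g.gs),
            "biomass_accumulation": _fmt(g.ba),
            "net_migration": _fmt(g.net_migration),
            "role_tags": ";".join(sorted(g.role_tags)),
        })
    pd.DataFrame(rows, columns=_GROUP_COLUMNS).to_csv(d / "groups.csv", index=False)

    names = model.names
    diet = pd.DataFrame(model.diet.dc, index=names, columns=names)
    diet.loc["import"] = model.diet.import_fraction
    diet.index.name = "prey"
    diet.to_csv(d / "diet.csv", float_format=_FLOAT_FMT)

    frows = []
    for f in model.fleets:
        for g in names:
            land = f.landings.get(g, 0.0)
            disc = f.discards.get(g, 0.0)
            if land or disc:
                frows.append({"fleet": f.name, "group": g,
                              "landings": _FLOAT_FMT % land, "discards": _FLOAT_FMT % disc})
    pd.DataFrame(frows, columns=["fleet", "group", "landings", "discards"]).to_csv(
        d / "fleets.csv", index=False
    )

    if responses is not None:
        rrows = [
            {"group": g, "min": _FLOAT_FMT % r.min, "q10": _FLOAT_FMT % r.q10,
             "q90": _FLOAT_FMT % r.q90, "max": _FLOAT_FMT % r.max}
            for g, r in sorted(responses.items())
        ]
        pd.DataFrame(rrows, columns=["group", "min", "q10", "q90", "max"]).to_csv(
            d / "responses.csv", index=False
        )

    if pedigree is not None:
        prows = [
            {"group": g, "parameter": p, "ci": _FLOAT_FMT % v}
            for (g, p), v in sorted(pedigree.ci.items())
        ]
        pd.DataFrame(prows, columns=["group", "parameter", "ci"]).to_csv(
            d / "pedigree.csv", index=False
        )


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_model(
    directory: str | Path,
) -> tuple[EcopathModel, dict[str, EnvResponse], Pedigree]:
    """Read a model directory back into validated objects.

    Missing responses.csv means every group is temperature-insensitive;
    missing pedigree.csv means all confidence intervals are zero; a missing
    fleets.csv means an unexploited system.
    """
    d = Path(directory)
    for required in ("groups.csv", "diet.csv"):
        if not (d / required).exists():
            raise FileNotFoundError(f"{d / required} is missing")

    gdf = pd.read_csv(d / "groups.csv", dtype={"role_tags": str})
    groups = []
    for ln, row in gdf.iterrows():
        tags = row.get("role_tags")
        tags = frozenset(t for t in str(tags).split(";") if t) if pd.notna(tags) else frozenset()
        try:
            groups.append(FunctionalGroup(
                name=str(row["name"]),
                category=str(row["category"]),
                biomass=_opt_float(row.get("biomass")),
                pb=float(row.get("production_rate", 0) or 0),
                qb=float(row.get("consumption_rate", 0) or 0),
                ee=_opt_float(row.get("ecotrophic_efficiency")),
                gs=float(row.get("unassimilated_fraction", 0) or 0),
                ba=float(row.get("biomass_accumulation", 0) or 0),
                net_migration=float(row.get("net_migration", 0) or 0),
                role_tags=tags,
            ))
        except (BalanceError, ValueError) as exc:
            raise BalanceError(f"groups.csv line {ln + 2}: {exc}") from exc
    names = [g.name for g in groups]

    ddf = pd.read_csv(d / "diet.csv", index_col=0)
    missing = set(names) - set(ddf.columns)
    if missing:
        raise BalanceError(f"diet.csv lacks columns for groups {sorted(missing)}")
    unknown = set(ddf.index) - set(names) - {"import"}
    if unknown:
        raise BalanceError(f"diet.csv has unknown prey rows {sorted(unknown)}")
    dc = np.zeros((len(names), len(names)))
    imp = np.zeros(len(names))
    for j, pred in enumerate(names):
        col = ddf[pred]
        for prey, v in col.items():
            if prey == "import":
                imp[j] = float(v)
            else:
                dc[names.index(str(prey)), j] = float(v)
    diet = DietMatrix(dc=dc, import_fraction=imp)

    fleets: list[Fleet] = []
    if (d / "fleets.csv").exists():
        fdf = pd.read_csv(d / "fleets.csv")
        for fname, sub in fdf.groupby("fleet", sort=False):
            landings, discards = {}, {}
            for _, row in sub.iterrows():
                g = str(row["group"])
                if g not in names:
                    raise BalanceError(f"fleets.csv: unknown group {g!r} for fleet {fname!r}")
                if float(row.get("landings", 0) or 0):
                    landings[g] = float(row["landings"])
                if float(row.get("discards", 0) or 0):
                    discards[g] = float(row["discards"])
            fleets.append(Fleet(str(fname), landings, discards))

    model = EcopathModel(groups=groups, diet=diet, fleets=fleets)
    if all(g.ee is not None for g in groups if g.is_living):
        model.balanced = True

    responses: dict[str, EnvResponse] = {}
    if (d / "responses.csv").exists():
        rdf = pd.read_csv(d / "responses.csv")
        for _, row in rdf.iterrows():
            g = str(row["group"])
            if g not in names:
                raise BalanceError(f"responses.csv: unknown group {g!r}")
            responses[g] = EnvResponse(
                min=float(row["min"]), q10=float(row["q10"]),
                q90=float(row["q90"]), max=float(row["max"]),
            )

    ped = Pedigree()
    if (d / "pedigree.csv").exists():
        pdf = pd.read_csv(d / "pedigree.csv")
        ci = {}
        for _, row in pdf.iterrows():
            g = str(row["group"])
            if g not in names:
                raise BalanceError(f"pedigree.csv: unknown group {g!r}")
            ci[(g, str(row["parameter"]))] = float(row["ci"])
        ped = Pedigree(ci=ci)

    return model, responses, ped


# ------------------------------------------------------------- baseline IO


def write_baseline(baseline: BaselineForcings, path: str | Path) -> None:
    """Baseline histories and anomaly tracks as one tidy CSV
    (series, name, year, value)."""
    rows = []

    def emit(series: str, name: str, s: pd.Series) -> None:
        for year, value in s.sort_index().items():
            rows.append({"series": series, "name": name, "year": int(year),
                         "value": _FLOAT_FMT % value})

    for fleet, s in sorted(baseline.effort_history.items()):
        emit("effort", fleet, s)
    emit("sst", "sst", baseline.sst_history)
    for g, s in sorted(baseline.alien_biomass_history.items()):
        emit("alien_biomass", g, s)
    for rcp, s in sorted(baseline.rcp_anomalies.items()):
        emit("rcp_anomaly", rcp, s)
    rows.append({"series": "meta", "name": "reference_year",
                 "year": baseline.reference_year, "value": str(baseline.reference_year)})
    pd.DataFrame(rows, columns=["series", "name", "year", "value"]).to_csv(path, index=False)


def read_baseline(path: str | Path) -> BaselineForcings:
    df = pd.read_csv(path)
    ref = int(df[df.series == "meta"].iloc[0]["year"])

    def series_of(kind: str) -> dict[str, pd.Series]:
        out = {}
        for name, sub in df[df.series == kind].groupby("name", sort=False):
            out[str(name)] = pd.Series(
                sub["value"].astype(float).to_numpy(), index=sub["year"].astype(int).to_numpy()
            ).sort_index()
        return out

    return BaselineForcings(
        effort_history=series_of("effort"),
        sst_history=series_of("sst")["sst"],
        alien_biomass_history=series_of("alien_biomass"),
        rcp_anomalies=series_of("rcp_anomaly"),
        reference_year=ref,
    )


# -------------------------------------------------------------- results IO


def write_results(result, indicators: pd.DataFrame | None, directory: str | Path) -> None:
    """Tidy result tables: biomass.csv, catch.csv, forcing_used.csv and
    (when supplied) indicators.csv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    rows = []
    for gi, g in enumerate(result.group_names):
        for yi, year in enumerate(result.years):
            rows.append({"year": _FLOAT_FMT % year, "group": g,
                         "value": _FLOAT_FMT % result.biomass[gi, yi]})
    pd.DataFrame(rows, columns=["year", "group", "value"]).to_csv(
        d / "biomass.csv", index=False
    )

    rows = []
    for gi, g in enumerate(result.group_names):
        for fi, f in enumerate(result.fleet_names):
            for yi in range(result.n_years):
                v = result.catch[gi, fi, yi]
                if v:
                    rows.append({"year": _FLOAT_FMT % result.years[yi + 1], "fleet": f,
                                 "group": g, "value": _FLOAT_FMT % v})
    pd.DataFrame(rows, columns=["year", "fleet", "group", "value"]).to_csv(
        d / "catch.csv", index=False
    )

    rows = []
    for yi, year in enumerate(result.years):
        rows.append({"year": _FLOAT_FMT % year, "series": "sst", "name": "sst",
                     "value": _FLOAT_FMT % result.sst[yi]})
        for fi, f in enumerate(result.fleet_names):
            rows.append({"year": _FLOAT_FMT % year, "series": "effort", "name": f,
                         "value": _FLOAT_FMT % result.effort[fi, yi]})
    pd.DataFrame(rows, columns=["year", "series", "name", "value"]).to_csv(
        d / "forcing_used.csv", index=False
    )

    if indicators is not None:
        tidy = indicators.reset_index().melt(
            id_vars="year", var_name="indicator", value_name="value"
        ).sort_values(["indicator", "year"], kind="stable")
        tidy["year"] = tidy["year"].map(lambda y: _FLOAT_FMT % y)
        tidy["value"] = tidy["value"].map(lambda v: _FLOAT_FMT % v)
        tidy.to_csv(d / "indicators.csv", index=False)


def write_envelopes(env: UncertaintyEnvelope, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sorted(env.outputs):
        bands = env.outputs[name]
        axis = env.years if len(bands["central"]) == len(env.years) else env.years[1:]
        for yi, year in enumerate(axis):
            rows.append({
                "output": name, "year": _FLOAT_FMT % year,
                "lower": _FLOAT_FMT % bands["lower"][yi],
                "central": _FLOAT_FMT % bands["central"][yi],
                "upper": _FLOAT_FMT % bands["upper"][yi],
            })
    pd.DataFrame(rows, columns=["output", "year", "lower", "central", "upper"]).to_csv(
        d / "envelopes.csv", index=False
    )


# --------------------------------------------------------------- manifest


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    results_dir: str | Path,
    input_files: list[str | Path],
    scenario_id: int | None = None,
    seed: int | None = None,
) -> None:
    from . import __version__

    manifest = {
        "tool_version": __version__,
        "scenario_id": scenario_id,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "inputs": {str(p): _digest(Path(p)) for p in sorted(map(str, input_files))},
    }
    with open(Path(results_dir) / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(results_dir: str | Path) -> dict:
    with open(Path(results_dir) / "manifest.yaml") as fh:
        return yaml.safe_load(fh)


def verify_manifest(results_dir: str | Path) -> bool:
    """True when every recorded input digest still matches the file."""
    manifest = read_manifest(results_dir)
    for path, digest in manifest.get("inputs", {}).items():
        p = Path(path)
        if not p.exists() or _digest(p) != digest:
            return False
    return True
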