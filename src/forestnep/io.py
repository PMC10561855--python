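"""Configuration handling and on-disk formats.

The run configuration is a YAML mapping with four sections —
``simulation``, ``soil``, ``species`` and ``synth`` — every key of
which has a documented default; unknown keys are rejected with their
full path so typos cannot silently fall back to defaults. Grids
(including every tree and soil pool) round-trip through JSON; forcing
through tidy CSV or CF-style NetCDF; annual fluxes through CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import (
    ForestType,
    GridCell,
    SoilParams,
    SoilState,
    SpeciesParams,
    TreeState,
    species_defaults,
)
from .simulation import SimulationConfig

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "save_config",
    "config_hash",
    "species_params_from_config",
    "soil_params_from_config",
    "simulation_config_from_config",
    "save_cells",
    "load_cells",
    "fluxes_to_frame",
    "provenance",
]


def _soil_defaults() -> dict[str, Any]:
    p = SoilParams()
    return {
        "S_u": [float(x) for x in p.S_u],
        "P_u": [float(x) for x in p.P_u],
        "CN_u": [float(x) for x in p.CN_u],
        "b": p.b,
        "e_w": p.e_w,
        "shield_all_pools": p.shield_all_pools,
    }


DEFAULT_CONFIG: dict[str, Any] = {
    "simulation": {
        "soil_temp_tau": 15.0,
        "phenology_tau": 10.0,
        "k_daytime": 0.5,        # day-mean temperature interpolation in forcing synthesis
        "metabolic_frac": 0.6,
        "starvation_tolerance": 0.5,
        "spinup_tol": 1e-4,
        "spinup_max_cycles": 200,
    },
    "soil": _soil_defaults(),
    # per-type overrides of any SpeciesParams field, e.g. {"ECF": {"A_m": 1e-3}}
    "species": {t.name: {} for t in ForestType},
    "synth": {
        "n_trees": 36,
        "patch_area": 900.0,
        "start_year": 2001,
    },
}

_SPECIES_FIELDS = {f.name for f in dataclasses.fields(SpeciesParams)}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if path.startswith("species.") and path.count(".") == 1:
            # species.<TYPE> level: keys are SpeciesParams fields
            if key not in _SPECIES_FIELDS:
                raise KeyError(f"unknown config key: {here}")
            out[key] = value
            continue
        if key not in defaults:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Resolve a YAML config file against the defaults.

    ``None`` or an empty file yields the pure defaults. Unknown keys
    raise ``KeyError`` with the offending key path.
    """
    user: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable short hash of a resolved configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def species_params_from_config(cfg: dict, forest_type: ForestType) -> SpeciesParams:
    overrides = cfg.get("species", {}).get(forest_type.name, {})
    return dataclasses.replace(species_defaults(forest_type), **overrides)


def soil_params_from_config(cfg: dict) -> SoilParams:
    s = cfg["soil"]
    return SoilParams(
        S_u=np.array(s["S_u"], dtype=float),
        P_u=np.array(s["P_u"], dtype=float),
        CN_u=np.array(s["CN_u"], dtype=float),
        b=float(s["b"]),
        e_w=float(s["e_w"]),
        shield_all_pools=bool(s["shield_all_pools"]),
    )


def simulation_config_from_config(cfg: dict) -> SimulationConfig:
    s = cfg["simulation"]
    return SimulationConfig(
        soil_params=soil_params_from_config(cfg),
        soil_temp_tau=float(s["soil_temp_tau"]),
        phenology_tau=float(s["phenology_tau"]),
        metabolic_frac=float(s["metabolic_frac"]),
        starvation_tolerance=float(s["starvation_tolerance"]),
    )


# ---------------------------------------------------------------------------
# grid serialization
# ---------------------------------------------------------------------------

def _tree_to_dict(t: TreeState) -> dict:
    d = dataclasses.asdict(t)
    return d


def _cell_to_dict(c: GridCell) -> dict:
    return {
        "id": c.id,
        "lat": c.lat,
        "lon": c.lon,
        "forest_type": c.forest_type.name,
        "coverage": c.coverage,
        "area": c.area,
        "patch_area": c.patch_area,
        "ndvi": c.ndvi,
        "spinup_converged": c.spinup_converged,
        "soil": {
            "W_s": c.soil.W_s, "W_f": c.soil.W_f, "T_s": c.soil.T_s,
            "N_s": c.soil.N_s, "N_pool": c.soil.N_pool, "L_s": c.soil.L_s,
            "C_u": [float(x) for x in c.soil.C_u],
        },
        "trees": [_tree_to_dict(t) for t in c.trees],
    }


def save_cells(cells: list[GridCell], path: str | Path,
               meta: dict | None = None) -> None:
    """Write a grid (with full tree and soil state) to JSON."""
    payload = {"_provenance": meta or {}, "cells": [_cell_to_dict(c) for c in cells]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_cells(path: str | Path) -> list[GridCell]:
    with open(path) as fh:
        payload = json.load(fh)
    cells = []
    for d in payload["cells"]:
        soil = SoilState(
            W_s=d["soil"]["W_s"], W_f=d["soil"]["W_f"], T_s=d["soil"]["T_s"],
            N_s=d["soil"]["N_s"], N_pool=d["soil"]["N_pool"],
            C_u=np.array(d["soil"]["C_u"]), L_s=d["soil"]["L_s"],
        )
        trees = [TreeState(**t) for t in d["trees"]]
        cells.append(GridCell(
            id=d["id"], lat=d["lat"], lon=d["lon"],
            forest_type=ForestType[d["forest_type"]],
            coverage=d["coverage"], trees=trees, soil=soil,
            area=d["area"], patch_area=d["patch_area"], ndvi=d.get("ndvi"),
            spinup_converged=d.get("spinup_converged"),
        ))
    return cells


def fluxes_to_frame(results: dict[str, list]) -> pd.DataFrame:
    """Annual flux table: one row per cell-year, kgC·m^-2·a^-1 columns."""
    rows = []
    for cell_id, years in results.items():
        for res in years:
            r = res.record
            rows.append((cell_id, r.year, r.GPP, r.R_a, r.NPP, r.R_s, r.NEP))
    return pd.DataFrame(
        rows, columns=["cell_id", "year", "GPP", "R_a", "NPP", "R_s", "NEP"]
    )


def provenance(seed: int | None, cfg: dict[str, Any]) -> dict[str, Any]:
    """Run header: package version, seed and resolved config hash."""
    try:
        ver = version("forestnep")
    except PackageNotFoundError:
        ver = "unknown"
    return {"package": "forestnep", "version": ver,
            "seed": seed, "config_hash": config_hash(cfg)}
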