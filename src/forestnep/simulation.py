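"""Orchestration: daily cell stepping, spin-up, runs, regional accounting.

One simulated day per cell proceeds boundary-layer downward: soil
temperature and the water bucket update first, then canopy GPP with its
CO2/water/temperature modifiers and the nitrogen cap, per-tree
maintenance and growth respiration into the photosynthate buffer,
background litterfall, and finally the ten-pool soil decomposition step
that releases heterotrophic respiration and mineralizes nitrogen. On
December 31 each tree's buffer is allocated to structure and the annual
fluxes close as NEP = NPP - R_s.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import canopy, soil as soil_mod
from .core import (
    FluxRecord,
    ForestType,
    GridCell,
    RegionalSummary,
    SoilParams,
    SpeciesParams,
    species_defaults,
)
from .growth import annual_growth, daily_litterfall, leaf_cap
from .respiration import growth_respiration, maintenance_respiration

__all__ = [
    "SimulationConfig",
    "step_day",
    "run_cell_year",
    "spinup",
    "run",
    "aggregate_regional",
    "contributions",
    "round_half_up",
    "evaluate_monthly",
    "CellYearResult",
]


@dataclass
class SimulationConfig:
    """Knobs of the daily loop that are not species or soil constants."""

    soil_params: SoilParams = field(default_factory=SoilParams)
    soil_temp_tau: float = 15.0        # d, air->soil smoothing constant
    phenology_tau: float = 10.0        # d, smoothing for the leaf-on mask
    metabolic_frac: float = 0.6        # leaf/fine-root litter metabolic share
    starvation_tolerance: float = 0.5  # kgC of allowed buffer deficit
    freeze_vegetation: bool = False    # soil-only spin-up: static stand, constant litter


@dataclass
class CellYearResult:
    """Annual fluxes plus the daily NEP trace of one cell-year."""

    record: FluxRecord
    daily_nep: pd.Series               # kgC m^-2 d^-1, indexed by date
    litter_in: np.ndarray | None = None    # annual additions per soil pool, kgC m^-2
    annual_rate: np.ndarray | None = None  # sum over days of S_u G_t G_w shield_u


@dataclass
class _PhenologyState:
    smoothed_T: float
    leaf_on: bool


def step_day(
    cell: GridCell,
    day,
    params: SpeciesParams,
    cfg: SimulationConfig,
    pheno: _PhenologyState,
) -> tuple[float, float, float, float, np.ndarray, np.ndarray]:
    """Advance one cell by one day.

    Returns ``(GPP, R_m, R_g, R_s, litter_additions, rate_vector)`` —
    fluxes in kgC·m^-2·d^-1, plus the day's soil-pool litter additions
    and the capped per-pool decomposition rates (needed by the
    semi-analytical spin-up).
    """
    soil = cell.soil
    area = cell.patch_area

    # phenology mask (deciduous canopies only), with 2 degC hysteresis so a
    # single cold snap does not thrash the canopy
    w = 1.0 - math.exp(-1.0 / cfg.phenology_tau)
    pheno.smoothed_T += w * (day.T_avg - pheno.smoothed_T)
    if cell.forest_type.deciduous:
        off_threshold = (params.leafon_threshold - 2.0 if pheno.leaf_on
                         else params.leafon_threshold)
        leaf_on = pheno.smoothed_T > off_threshold
    else:
        leaf_on = True
    shed_today = cell.forest_type.deciduous and pheno.leaf_on and not leaf_on
    flush_today = (cell.forest_type.deciduous and leaf_on and not pheno.leaf_on
                   and not cfg.freeze_vegetation)
    pheno.leaf_on = leaf_on

    # spring flush: rebuild the canopy from the buffer (reserves may be
    # borrowed; a chronically failing stand shows up as carbon starvation)
    if flush_today:
        leaf_budget = max(
            0.0,
            params.LAI_v * area / params.sla
            - sum(t.C_leaf for t in cell.trees),
        )
        for tree in cell.trees:
            need = min(max(0.0, leaf_cap(tree.dbh, params) - tree.C_leaf),
                       leaf_budget)
            if need > 0.0:
                tree.C_leaf += need
                tree.C_buffer -= need
                tree.lai_tree = tree.C_leaf * params.sla / area
                leaf_budget -= need

    # soil physics
    soil.T_s = soil_mod.soil_temperature_step(soil.T_s, day.T_avg, cfg.soil_temp_tau)
    pet_mm = soil_mod.potential_evapotranspiration(day.T_avg, day.D)
    soil.W_s = soil_mod.water_balance_step(soil.W_s, soil.W_f, day.precip, pet_mm / 10.0)

    # canopy GPP on the patch, kgC m^-2 d^-1
    lai_eff = cell.lai if leaf_on else 0.0
    if lai_eff > 0.0 and day.D > 0.0 and day.PAR_noon > 0.0:
        gpp_m = canopy.gpp_max(params.A_m, day.D, params.K, params.S,
                               day.PAR_noon, lai_eff)
        f_c = canopy.f_co2(day.C_t, day.C_0)
        f_w = canopy.f_water(soil.W_s, soil.W_f, day.Rh, params.W)
        f_t = canopy.f_temp(day.T_avg, params.T_min_p, params.T_opt_p, params.T_max_p)
        gpp_d = canopy.gpp_daily(gpp_m, f_c, f_w, f_t, params.alpha, soil.N_s)
    else:
        gpp_d = 0.0
    soil.N_s = max(soil.N_s - gpp_d / params.alpha, 0.0)

    # per-tree respiration and buffer update
    lai_total = cell.lai
    litter_leaf = litter_root = 0.0
    R_m_patch = R_g_patch = 0.0
    if cfg.freeze_vegetation:
        # static stand: constant background litter, no pool mutation
        for tree in cell.trees:
            litter_leaf += params.leaf_turnover * tree.C_leaf
            litter_root += params.fineroot_turnover * tree.C_fineroot
    else:
        for tree in cell.trees:
            share = (tree.lai_tree / lai_total if lai_total > 0
                     else 1.0 / len(cell.trees))
            assim = gpp_d * area * share
            # an "off" deciduous canopy is dormant bud/storage tissue:
            # it neither respires at the leaf rate nor sheds background litter
            r_m = maintenance_respiration(day.D, day.T_d, day.T_n, {
                "leaf": (params.R_k_leaf, tree.C_leaf if leaf_on else 0.0),
                "fineroot": (params.R_k_fineroot, tree.C_fineroot),
                "wood": (params.R_k_wood, tree.C_sapwood),
            })
            r_g = growth_respiration(assim, r_m, params.r_g)
            tree.C_buffer += assim - r_m - r_g
            R_m_patch += r_m
            R_g_patch += r_g
            lit = daily_litterfall(tree, params, area,
                                   shed_all_leaves=shed_today,
                                   leaves_active=leaf_on or shed_today)
            litter_leaf += lit["leaf"]
            litter_root += lit["fineroot"]

    # soil decomposition with today's litter
    g_t = soil_mod.temp_effect(soil.T_s)
    g_w = soil_mod.water_effect(soil.W_s, soil.W_f, cfg.soil_params.e_w)
    rate_vec = soil_mod.capped_rates(soil, cfg.soil_params, g_t, g_w)
    new_pools, rs_daily, mineral_n = soil_mod.decomposition_step(
        soil, cfg.soil_params, g_t, g_w
    )
    additions = soil_mod.litter_partition(
        leaf=litter_leaf / area, fineroot=litter_root / area,
        metabolic_frac=cfg.metabolic_frac,
    )
    soil.C_u = new_pools + additions
    soil.N_s += mineral_n

    return gpp_d, R_m_patch / area, R_g_patch / area, rs_daily, additions, rate_vec


def run_cell_year(
    cell: GridCell,
    days: list,
    params: SpeciesParams | None = None,
    cfg: SimulationConfig | None = None,
    pheno: _PhenologyState | None = None,
) -> CellYearResult:
    """Simulate one calendar year on a cell (state mutates in place)."""
    if len(days) not in (365, 366):
        raise ValueError(f"need one full calendar year, got {len(days)} days")
    params = params or species_defaults(cell.forest_type)
    cfg = cfg or SimulationConfig()
    if pheno is None:
        pheno = _PhenologyState(smoothed_T=days[0].T_avg, leaf_on=False)

    year = days[0].date.year
    gpp = np.empty(len(days))
    r_m = np.empty(len(days))
    r_g = np.empty(len(days))
    r_s = np.empty(len(days))
    litter_in = np.zeros(10)
    annual_rate = np.zeros(10)
    for i, day in enumerate(days):
        if day.date.year != year:
            raise ValueError(f"forcing day {day.date} outside year {year}")
        gpp[i], r_m[i], r_g[i], r_s[i], adds, rates = step_day(
            cell, day, params, cfg, pheno
        )
        litter_in += adds
        annual_rate += rates

    # annual allocation of the buffered photosynthate; fruit litter to soil.
    # Leaf refill shares a stand-level budget so the canopy cannot
    # overshoot the species' maximum LAI.
    fruit_patch = 0.0
    if not cfg.freeze_vegetation:
        leaf_budget = max(
            0.0,
            params.LAI_v * cell.patch_area / params.sla
            - sum(t.C_leaf for t in cell.trees),
        )
        for tree in cell.trees:
            alloc = annual_growth(tree, params, cell.patch_area,
                                  cfg.starvation_tolerance,
                                  leaf_budget=leaf_budget)
            leaf_budget = max(0.0, leaf_budget - alloc.leaf_alloc)
            fruit_patch += alloc.fruit_litter
    fruit_adds = soil_mod.litter_partition(
        reproductive=fruit_patch / cell.patch_area,
        metabolic_frac=cfg.metabolic_frac,
    )
    cell.soil.C_u = cell.soil.C_u + fruit_adds
    litter_in += fruit_adds

    npp = float((gpp - r_m - r_g).sum())
    rs_annual = float(r_s.sum())
    record = FluxRecord(
        year=year, GPP=float(gpp.sum()), R_a=float((r_m + r_g).sum()),
        NPP=npp, R_s=rs_annual, NEP=npp - rs_annual,
    )
    daily_nep = pd.Series(
        gpp - r_m - r_g - r_s, index=pd.to_datetime([d.date for d in days])
    )
    return CellYearResult(record=record, daily_nep=daily_nep,
                          litter_in=litter_in, annual_rate=annual_rate)


def soil_steady_state(
    litter_in: np.ndarray, annual_rate: np.ndarray, transfer_matrix: np.ndarray,
    current: np.ndarray,
) -> np.ndarray:
    """Analytic soil equilibrium under a repeated forcing year.

    With annual litter inputs ``litter_in`` and per-pool annual
    decomposition fractions ``annual_rate`` (sum of the daily capped
    rates), the steady annual outflow of every pool solves the linear
    balance ``x = litter_in + T^T x``; the equilibrium stock is
    ``C_u* = x_u / annual_rate_u``. Pools with a vanishing rate keep
    their ``current`` stock.
    """
    x = np.linalg.solve(np.eye(10) - transfer_matrix.T, litter_in)
    out = current.copy()
    active = annual_rate > 0
    out[active] = x[active] / annual_rate[active]
    return out


def spinup(
    cell: GridCell,
    forcing_year: list,
    tol: float = 1e-4,
    max_cycles: int = 200,
    cfg: SimulationConfig | None = None,
    accelerate: bool = True,
    accel_cycle: int = 40,
) -> tuple[GridCell, int]:
    """Cycle one forcing year until total soil carbon equilibrates.

    Repeats the designated year (single-year recycle) until the relative
    change in total soil carbon between consecutive cycles drops below
    ``tol``. The slowest organic-matter pool turns over on a timescale
    of decades, so by default the spin-up is semi-analytically
    accelerated: once the stand and its litter flux have settled
    (``accel_cycle`` cycles), the soil pools jump to the closed-form
    equilibrium of :func:`soil_steady_state`, after which cycling
    continues until the convergence criterion is met honestly. The cell
    mutates in place and is returned with its cycle count; exhausting
    ``max_cycles`` flags it non-converged (warning, not fatal).
    """
    if len(forcing_year) not in (365, 366):
        raise ValueError("spin-up needs exactly one full year of forcing")
    cfg = cfg or SimulationConfig()
    params = species_defaults(cell.forest_type)
    pheno = _PhenologyState(smoothed_T=forcing_year[0].T_avg, leaf_on=False)
    cycles = 0
    for cycles in range(1, max_cycles + 1):
        before = cell.soil.total_carbon
        res = run_cell_year(cell, forcing_year, params, cfg, pheno)
        after = cell.soil.total_carbon
        if after > 0 and abs(after - before) / after < tol:
            cell.spinup_converged = True
            return cell, cycles
        if accelerate and cycles % accel_cycle == 0:
            cell.soil.C_u = soil_steady_state(
                res.litter_in, res.annual_rate,
                cfg.soil_params.transfer_matrix, cell.soil.C_u,
            )
    cell.spinup_converged = False
    warnings.warn(
        f"cell {cell.id}: spin-up did not converge within {max_cycles} cycles",
        stacklevel=2,
    )
    return cell, cycles


def run(
    cells: list[GridCell],
    forcing: dict[str, list],
    cfg: SimulationConfig | None = None,
) -> dict[str, list[CellYearResult]]:
    """Transient run over every full calendar year in the forcing.

    ``forcing`` maps cell id to its daily weather series; each cell is
    stepped through its years in order. Missing forcing for a cell is
    fatal. Deterministic given states and forcing.
    """
    cfg = cfg or SimulationConfig()
    out: dict[str, list[CellYearResult]] = {}
    for cell in cells:
        if cell.id not in forcing:
            raise KeyError(f"no forcing for cell {cell.id}")
        days = forcing[cell.id]
        params = species_defaults(cell.forest_type)
        pheno = _PhenologyState(smoothed_T=days[0].T_avg, leaf_on=False)
        results = []
        for year, group in itertools.groupby(days, key=lambda d: d.date.year):
            year_days = list(group)
            if len(year_days) not in (365, 366):
                raise ValueError(
                    f"cell {cell.id}: year {year} has {len(year_days)} forcing days"
                )
            results.append(run_cell_year(cell, year_days, params, cfg, pheno))
        out[cell.id] = results
    return out


# ---------------------------------------------------------------------------
# regional accounting
# ---------------------------------------------------------------------------

def aggregate_regional(
    nep_per_cell: dict[str, float],
    cells: list[GridCell],
) -> RegionalSummary:
    """Aggregate per-cell NEP (gC·m^-2·a^-1) to per-type TgC·a^-1 totals.

    Each cell contributes ``NEP * area * coverage``; totals convert at
    1 TgC = 10^12 gC and the national total at 1 PgC = 10^3 TgC.
    """
    by_cell = {c.id: c for c in cells}
    per_type = {t: 0.0 for t in ForestType}
    for cell_id, nep in nep_per_cell.items():
        cell = by_cell[cell_id]
        per_type[cell.forest_type] += nep * cell.area * cell.coverage * 1e-12
    national = sum(per_type.values()) * 1e-3
    if national != 0.0:
        contribution = contributions(per_type)
    else:                       # degenerate net-zero region: shares undefined
        contribution = {t: float("nan") for t in per_type}
    return RegionalSummary(
        per_type_nep=per_type,
        contribution=contribution,
        national_total=national,
    )


def contributions(per_type_nep: dict[ForestType, float]) -> dict[ForestType, float]:
    """Relative contribution of each forest type, percent of the net total.

    The denominator is the *net* sum including negative (carbon-source)
    types, so contributions sum to exactly 100 with source types
    appearing as negative percentages.
    """
    total = sum(per_type_nep.values())
    if total == 0:
        raise ZeroDivisionError("net total NEP is zero; contributions undefined")
    return {t: 100.0 * v / total for t, v in per_type_nep.items()}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used only at the reporting layer."""
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def evaluate_monthly(
    daily_nep: pd.Series,
    observed_nee: pd.Series,
    nee_sign_flipped: bool = True,
) -> dict[str, float]:
    """Compare simulated NEP with flux-tower NEE month by month.

    ``daily_nep`` (kgC·m^-2·d^-1, datetime-indexed) is summed to months
    and paired with ``observed_nee`` (kgC·m^-2·month^-1, indexed by
    month start). Eddy-covariance NEE is positive toward the
    atmosphere, so by default its sign is flipped to the NEP convention
    (positive = sink). Returns bias (sim - obs), RMSE and Pearson r
    over the paired months; fewer than 3 overlapping months is an
    error.
    """
    monthly_sim = daily_nep.resample("MS").sum()
    obs = -observed_nee if nee_sign_flipped else observed_nee
    paired = pd.DataFrame({"sim": monthly_sim, "obs": obs}).dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 overlapping months")
    diff = paired["sim"] - paired["obs"]
    r = float(np.corrcoef(paired["sim"], paired["obs"])[0, 1])
    return {
        "bias": float(diff.mean()),
        "rmse": float(np.sqrt((diff**2).mean())),
        "pearson_r": r,
        "n_months": int(len(paired)),
    }
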