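"""Daily soil water balance, ten-pool decomposition and N mineralization.

The soil column is a single bucket of depth-integrated water plus ten
carbon pools (surface and buried metabolic/structural litter, three
woody litter classes, and active/slow/resistant organic matter). Each
day every pool u loses ``S_u G_t G_w shield_u C_u`` of carbon, of which
the fraction ``P_u`` is respired and the rest is routed to downstream
pools by a fixed transfer matrix; respired carbon mineralizes nitrogen
at the pool's C:N ratio into the plant-available store.
"""

from __future__ import annotations

import math

import numpy as np

from .core import STRUCTURAL_POOLS, SoilParams, SoilState

__all__ = [
    "soil_temperature_step",
    "potential_evapotranspiration",
    "water_balance_step",
    "temp_effect",
    "water_effect",
    "capped_rates",
    "decomposition_step",
    "annual_rs",
    "litter_partition",
]


def soil_temperature_step(T_s: float, T_avg: float, tau: float = 15.0) -> float:
    """One-day exponential smoothing of air temperature into soil temperature.

    First-order response with time constant ``tau`` days:
    ``T_s' = T_s + (1 - e^(-1/tau)) (T_avg - T_s)``; ``tau = 0`` tracks
    the air temperature exactly.
    """
    if tau <= 0:
        return T_avg
    w = 1.0 - math.exp(-1.0 / tau)
    return T_s + w * (T_avg - T_s)


def potential_evapotranspiration(T_avg: float, D: float) -> float:
    """Daylength-weighted saturation-vapour PET (Hamon form), mm·d^-1.

    ``PET = 0.1651 (D/12) * 216.7 e_s / (T + 273.3)`` with saturated
    vapour pressure ``e_s`` in hPa from the Magnus formula; zero below
    freezing. A deliberately simple temperature-and-daylength formula —
    the bucket needs a demand term, not an energy balance.
    """
    if T_avg <= 0.0:
        return 0.0
    e_s = 6.108 * math.exp(17.27 * T_avg / (T_avg + 237.3))
    rho_sat = 216.7 * e_s / (T_avg + 273.3)
    return 0.1651 * (D / 12.0) * rho_sat


def water_balance_step(W_s: float, W_f: float, precip: float, PET: float) -> float:
    """One-day bucket update; returns the new soil water in cm.

    ``W_s' = clamp(W_s + precip/10 - AET, 0, W_f)`` with actual
    evapotranspiration ``AET = PET * W_s/W_f``. Rain enters in mm
    (10 mm = 1 cm); the PET demand enters in cm·d^-1 and is scaled by
    relative wetness. Water in excess of field capacity drains and is
    discarded.
    """
    if precip < 0:
        raise ValueError("precipitation must be non-negative")
    if W_f <= 0:
        raise ValueError("field capacity must be positive")
    if W_s > W_f + 1e-12:
        raise ValueError("require W_s <= W_f")
    aet = PET * (W_s / W_f)
    return min(max(W_s + precip / 10.0 - aet, 0.0), W_f)


def temp_effect(T_s: float) -> float:
    """Temperature multiplier of decomposition: e^(3.36 (T_s-40)/(T_s+31.79)).

    Strictly increasing, equal to 1 at 40 °C; undefined at and below the
    pole -31.79 °C.
    """
    if T_s <= -31.79:
        raise ValueError("soil temperature at or below the -31.79 °C pole")
    return math.exp(3.36 * (T_s - 40.0) / (T_s + 31.79))


def water_effect(W_s: float, W_f: float, e_w: float = 0.6) -> float:
    """Moisture multiplier of decomposition: 1 - (W_s/(e_w W_f) - 1)^2.

    A parabola peaking at 1 when soil water sits at the fraction ``e_w``
    of field capacity, zero in bone-dry soil, clamped to [0, 1].
    """
    if W_f <= 0:
        raise ValueError("field capacity must be positive")
    if not (0.0 <= W_s <= W_f + 1e-12):
        raise ValueError("require 0 <= W_s <= W_f")
    g = 1.0 - (W_s / (e_w * W_f) - 1.0) ** 2
    return min(max(g, 0.0), 1.0)


def capped_rates(
    soil: SoilState, params: SoilParams, G_t: float, G_w: float
) -> np.ndarray:
    """Per-pool daily decomposition rates ``S_u G_t G_w shield_u``, capped at 1.

    Lignin shielding ``e^(-b L_s)`` applies to the structural litter
    pools, or to every pool when ``params.shield_all_pools`` is set.
    """
    shield = np.ones(10)
    lignin_shield = math.exp(-params.b * soil.L_s)
    if params.shield_all_pools:
        shield[:] = lignin_shield
    else:
        for u in STRUCTURAL_POOLS:
            shield[u] = lignin_shield
    return np.minimum(params.S_u * G_t * G_w * shield, 1.0)


def decomposition_step(
    soil: SoilState, params: SoilParams, G_t: float, G_w: float
) -> tuple[np.ndarray, float, float]:
    """One daily decomposition step.

    Returns ``(new_pools, R_s_daily, mineralized_N)`` with fluxes in
    kgC·m^-2·d^-1 (N in kgN·m^-2·d^-1). The decomposition flux of pool
    u is ``S_u G_t G_w shield_u C_u`` capped at the pool size; lignin
    shielding ``e^(-b L_s)`` applies to the structural litter pools (or
    to all pools when ``params.shield_all_pools``). Carbon is conserved:
    total pool decrease equals respiration, because the transfer matrix
    routes the whole non-respired share.
    """
    if G_t < 0 or G_w < 0:
        raise ValueError("decomposition multipliers must be non-negative")
    C = soil.C_u
    flux = capped_rates(soil, params, G_t, G_w) * C
    respired = params.P_u * flux
    transfers = params.transfer_matrix.T @ flux   # inflow per receiving pool
    new_pools = C - flux + transfers
    # guard against -0.0 / rounding dust
    new_pools[new_pools < 0] = 0.0
    R_s_daily = float(respired.sum())
    mineralized = float((respired / params.CN_u).sum())
    return new_pools, R_s_daily, mineralized


def annual_rs(daily_rs: "list[float] | np.ndarray") -> float:
    """Annual heterotrophic respiration: the sum of daily values."""
    n = len(daily_rs)
    if n not in (365, 366):
        raise ValueError(f"need one full calendar year, got {n} days")
    return float(np.sum(daily_rs))


def litter_partition(
    leaf: float = 0.0,
    fineroot: float = 0.0,
    branch: float = 0.0,
    stem: float = 0.0,
    coarseroot: float = 0.0,
    reproductive: float = 0.0,
    metabolic_frac: float = 0.6,
) -> np.ndarray:
    """Route litter masses (kgC·m^-2) to the ten soil pool additions.

    Leaf (and reproductive) litter splits metabolic/structural by
    ``metabolic_frac`` into the above-ground pools; fine-root litter
    splits the same way below ground; branch, stem and coarse-root
    litter feed the fine-woody, coarse-woody and below-ground coarse
    pools whole. Total input equals total addition.
    """
    masses = (leaf, fineroot, branch, stem, coarseroot, reproductive)
    if any(m < 0 for m in masses):
        raise ValueError("litter masses must be non-negative")
    if not (0.0 <= metabolic_frac <= 1.0):
        raise ValueError("metabolic fraction must lie in [0, 1]")
    add = np.zeros(10)
    surface = leaf + reproductive
    add[0] = surface * metabolic_frac
    add[1] = surface * (1.0 - metabolic_frac)
    add[2] = fineroot * metabolic_frac
    add[3] = fineroot * (1.0 - metabolic_frac)
    add[4] = branch
    add[5] = stem
    add[6] = coarseroot
    return add
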