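"""Core state and parameter records shared by every process module.

Units follow a single internal convention: carbon fluxes are kgC per m^2
ground area per day, carbon pools are kgC·m^-2 for soil and kgC per tree
for vegetation, water is cm of column, temperatures are degrees Celsius.
Annual totals are kgC·m^-2·a^-1; reporting layers convert to gC, TgC or
PgC explicitly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "ForestType",
    "SpeciesParams",
    "WeatherDay",
    "TreeState",
    "SoilState",
    "SoilParams",
    "GridCell",
    "FluxRecord",
    "RegionalSummary",
    "SOIL_POOL_NAMES",
    "species_defaults",
]


class ForestType(Enum):
    """The eight forest types of the simulator's classification."""

    ECF = "evergreen coniferous forest"
    DCF = "deciduous coniferous forest"
    CBF = "coniferous and broad-leaved mixed forest"
    DBF = "deciduous broad-leaved forest"
    EBF = "evergreen broad-leaved forest"
    EDBF = "evergreen deciduous broad-leaved mixed forest"
    SRF = "seasonal rain forest"
    RF = "rain forest"

    @property
    def deciduous(self) -> bool:
        """Whether the canopy sheds its leaves outside the growing season."""
        return self in (ForestType.DCF, ForestType.DBF, ForestType.EDBF)


#: Names of the ten soil carbon pools, in storage order.
SOIL_POOL_NAMES = (
    "ag_metabolic",      # above-ground metabolic litter
    "ag_structural",     # above-ground structural litter
    "bg_metabolic",      # below-ground metabolic litter
    "bg_structural",     # below-ground structural litter
    "fine_woody",        # fine woody litter (branches)
    "coarse_woody",      # coarse woody litter (stems)
    "bg_coarse",         # below-ground coarse litter (coarse roots)
    "active_som",        # active soil organic matter
    "slow_som",          # slow soil organic matter
    "resistant_som",     # resistant soil organic matter
)

#: Indices of the structural litter pools subject to lignin shielding.
STRUCTURAL_POOLS = (1, 3)


@dataclass(frozen=True)
class SpeciesParams:
    """Physiological and allometric constants for one forest type.

    Parameters
    ----------
    A_m : float
        Maximum leaf photosynthesis rate, kgC·m^-2 leaf·h^-1.
    K : float
        Canopy light extinction coefficient (Beer–Lambert), dimensionless.
    S : float
        Initial slope of the leaf light response,
        kgC·m^-2·h^-1 per W·m^-2 of PAR.
    W : float
        Drought-tolerance exponent of the soil-water multiplier.
    T_min_p, T_opt_p, T_max_p : float
        Cardinal temperatures of photosynthesis, °C.
    R_k_leaf, R_k_fineroot, R_k_wood : float
        Relative maintenance respiration rates at 15 °C, d^-1
        (wood rate applies to sapwood carbon).
    r_g : float
        Growth respiration coefficient (fraction of net daily assimilate).
    alpha : float
        Carbon:nitrogen ratio of assimilation; caps daily GPP at
        ``alpha * N_s``.
    NDVI_max, NDVI_min : float
        Scene NDVI bounds used to invert NDVI to an initial LAI.
    LAI_v : float
        Maximum leaf area index of the type.
    sla : float
        Specific leaf area, m^2 leaf per kgC leaf.
    leaf_turnover, fineroot_turnover : float
        Daily background litter rates, d^-1.
    a_w, b_w : float
        Stem allometry, stem carbon kgC = a_w * DBH^b_w (DBH in cm).
    a_h, b_h : float
        Height allometry, height m = a_h * DBH^b_h.
    a_l, b_l : float
        Maximum leaf carbon per tree, kgC = a_l * DBH^b_l.
    root_leaf_ratio : float
        Fine-root carbon allocated per unit leaf carbon.
    fruit_fraction : float
        Fraction of the annual positive buffer spent on flower/fruit litter.
    sapwood_fraction : float
        Fraction of woody carbon that is live sapwood.
    litter_lignin_frac : float
        Lignin fraction of structural litter inputs.
    leafon_threshold : float
        Smoothed air temperature (°C) above which deciduous canopies
        carry leaves.
    """

    A_m: float
    K: float
    S: float
    W: float
    T_min_p: float
    T_opt_p: float
    T_max_p: float
    R_k_leaf: float
    R_k_fineroot: float
    R_k_wood: float
    NDVI_max: float
    NDVI_min: float
    LAI_v: float
    r_g: float = 0.25
    alpha: float = 150.0
    sla: float = 12.0
    leaf_turnover: float = 0.0010
    fineroot_turnover: float = 0.0015
    a_w: float = 0.06
    b_w: float = 2.5
    a_h: float = 1.5
    b_h: float = 0.6
    a_l: float = 0.18
    b_l: float = 1.5
    root_leaf_ratio: float = 0.8
    fruit_fraction: float = 0.05
    sapwood_fraction: float = 0.3
    litter_lignin_frac: float = 0.22
    leafon_threshold: float = 5.0

    def __post_init__(self) -> None:
        if not (self.T_min_p < self.T_opt_p < self.T_max_p):
            raise ValueError(
                "cardinal temperatures must satisfy T_min_p < T_opt_p < T_max_p"
            )
        if self.K <= 0:
            raise ValueError("extinction coefficient K must be positive")
        if not (0.0 < self.r_g < 1.0):
            raise ValueError("growth respiration coefficient r_g must be in (0,1)")
        if not (self.NDVI_min < self.NDVI_max):
            raise ValueError("NDVI_min must be below NDVI_max")
        if self.LAI_v <= 0:
            raise ValueError("LAI_v must be positive")


def species_defaults(forest_type: ForestType) -> SpeciesParams:
    """Default parameter set for a forest type.

    NDVI bounds and maximum LAI for ECF/DCF/DBF/CBF follow the published
    per-type table; the remaining entries are field-typical package
    defaults (see docs/methods.md).
    """
    common = dict(NDVI_max=0.687, NDVI_min=0.033)
    table = {
        ForestType.ECF: dict(
            A_m=0.9e-3, K=0.5, S=1.0e-5, W=1.5,
            T_min_p=-2.0, T_opt_p=18.0, T_max_p=38.0,
            R_k_leaf=0.0012, R_k_fineroot=0.0012, R_k_wood=0.00015,
            LAI_v=8.0, **common,
        ),
        ForestType.DCF: dict(
            A_m=1.0e-3, K=0.5, S=1.0e-5, W=1.5,
            T_min_p=-2.0, T_opt_p=16.0, T_max_p=35.0,
            R_k_leaf=0.0014, R_k_fineroot=0.0014, R_k_wood=0.00015,
            LAI_v=8.0, **common,
        ),
        ForestType.DBF: dict(
            A_m=1.1e-3, K=0.55, S=1.1e-5, W=1.2,
            T_min_p=0.0, T_opt_p=22.0, T_max_p=40.0,
            R_k_leaf=0.0015, R_k_fineroot=0.0015, R_k_wood=0.0002,
            LAI_v=7.0, **common,
        ),
        ForestType.CBF: dict(
            A_m=1.0e-3, K=0.52, S=1.05e-5, W=1.3,
            T_min_p=-1.0, T_opt_p=20.0, T_max_p=39.0,
            R_k_leaf=0.0013, R_k_fineroot=0.0013, R_k_wood=0.00018,
            LAI_v=7.5, **common,
        ),
        ForestType.EBF: dict(
            A_m=1.2e-3, K=0.58, S=1.2e-5, W=1.0,
            T_min_p=2.0, T_opt_p=25.0, T_max_p=42.0,
            R_k_leaf=0.0016, R_k_fineroot=0.0016, R_k_wood=0.00022,
            LAI_v=7.0, **common,
        ),
        ForestType.EDBF: dict(
            A_m=1.1e-3, K=0.56, S=1.1e-5, W=1.1,
            T_min_p=1.0, T_opt_p=23.0, T_max_p=41.0,
            R_k_leaf=0.0015, R_k_fineroot=0.0015, R_k_wood=0.0002,
            LAI_v=7.5, **common,
        ),
        ForestType.SRF: dict(
            A_m=1.3e-3, K=0.6, S=1.2e-5, W=0.9,
            T_min_p=5.0, T_opt_p=27.0, T_max_p=45.0,
            R_k_leaf=0.0018, R_k_fineroot=0.0018, R_k_wood=0.00025,
            LAI_v=6.0, **common,
        ),
        ForestType.RF: dict(
            A_m=1.3e-3, K=0.6, S=1.25e-5, W=0.8,
            T_min_p=6.0, T_opt_p=27.0, T_max_p=45.0,
            R_k_leaf=0.0018, R_k_fineroot=0.0018, R_k_wood=0.00025,
            LAI_v=6.5, **common,
        ),
    }
    return SpeciesParams(**table[forest_type])


@dataclass
class WeatherDay:
    """One day of meteorological forcing plus derived quantities.

    ``T_d``/``T_n`` (day/night mean temperatures) and ``PAR_noon`` are
    derived fields, filled by :mod:`forestnep.forcing` helpers.
    """

    date: _dt.date
    T_max: float
    T_min: float
    T_avg: float
    precip: float          # mm d^-1
    D: float               # sunshine hours, h
    Rh: float              # relative humidity, fraction
    C_t: float = 380.0     # annual mean CO2, ppm
    C_0: float = 380.0     # reference CO2, ppm
    T_d: float | None = None
    T_n: float | None = None
    PAR_noon: float | None = None   # W m^-2

    def __post_init__(self) -> None:
        if not (self.T_min <= self.T_avg <= self.T_max):
            raise ValueError(
                f"{self.date}: require T_min <= T_avg <= T_max, got "
                f"{self.T_min}, {self.T_avg}, {self.T_max}"
            )
        if not (0.0 <= self.D <= 24.0):
            raise ValueError("sunshine hours D must lie in [0, 24]")
        if self.precip < 0:
            raise ValueError("precipitation must be non-negative")
        if not (0.0 <= self.Rh <= 1.0):
            raise ValueError("relative humidity must lie in [0, 1]")
        if self.PAR_noon is not None and self.PAR_noon < 0:
            raise ValueError("PAR_noon must be non-negative")


@dataclass
class TreeState:
    """Size and carbon pools of one individual on the patch.

    Structural pools are kgC per tree and never negative; the
    nonstructural ``C_buffer`` may dip below zero when maintenance
    respiration outruns assimilation (the buffer-pool scheme), in which
    case ``carbon_starved`` is flagged.
    """

    dbh: float                       # cm
    height: float                    # m
    C_leaf: float
    C_fineroot: float
    C_branch: float
    C_stem: float
    C_coarseroot: float
    C_sapwood: float
    C_buffer: float = 0.0
    underbranch_height: float = 0.0
    lai_tree: float = 0.0            # m^2 leaf per m^2 patch ground
    carbon_starved: bool = False

    def __post_init__(self) -> None:
        if self.dbh <= 0 or self.height <= 0:
            raise ValueError("dbh and height must be positive")
        for name in ("C_leaf", "C_fineroot", "C_branch", "C_stem", "C_coarseroot", "C_sapwood"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        woody = self.C_branch + self.C_stem + self.C_coarseroot
        if self.C_sapwood > woody + 1e-9:
            raise ValueError("sapwood cannot exceed total woody carbon")

    @property
    def total_carbon(self) -> float:
        """All per-tree carbon including the buffer, kgC."""
        return (self.C_leaf + self.C_fineroot + self.C_branch + self.C_stem
                + self.C_coarseroot + self.C_buffer)


@dataclass
class SoilState:
    """Soil water, temperature, nitrogen, and the ten carbon pools."""

    W_s: float                         # soil water, cm
    W_f: float                         # field capacity, cm
    T_s: float                         # soil temperature, °C
    N_s: float                         # available N, kgN m^-2
    N_pool: float                      # total soil N, kgN m^-2
    C_u: np.ndarray                    # 10 pools, kgC m^-2
    L_s: float = 0.22                  # lignin fraction of structural litter

    def __post_init__(self) -> None:
        self.C_u = np.asarray(self.C_u, dtype=float)
        if self.C_u.shape != (10,):
            raise ValueError("C_u must hold exactly 10 pools")
        if np.any(self.C_u < 0):
            raise ValueError("soil carbon pools must be non-negative")
        if not (0.0 <= self.W_s <= self.W_f):
            raise ValueError("require 0 <= W_s <= W_f")
        if not (0.0 <= self.L_s < 1.0):
            raise ValueError("lignin fraction must lie in [0, 1)")
        if self.N_s < 0:
            raise ValueError("available nitrogen must be non-negative")

    @property
    def total_carbon(self) -> float:
        return float(self.C_u.sum())

    def copy(self) -> "SoilState":
        return replace(self, C_u=self.C_u.copy())


def _default_transfer_matrix() -> np.ndarray:
    """CENTURY-style routing of non-respired decomposition flux.

    Row u gives the fractions of pool u's decomposed carbon sent to each
    receiving pool; every row sums to 1 - P_u so that no carbon leaves
    the column except as respiration.
    """
    P = _DEFAULT_P
    T = np.zeros((10, 10))
    T[0, 7] = 1 - P[0]                      # ag metabolic -> active
    T[1, 7] = (1 - P[1]) * 0.7              # ag structural -> active (cellulosic)
    T[1, 8] = (1 - P[1]) * 0.3              #               -> slow (lignin)
    T[2, 7] = 1 - P[2]                      # bg metabolic -> active
    T[3, 7] = (1 - P[3]) * 0.7
    T[3, 8] = (1 - P[3]) * 0.3
    T[4, 7] = (1 - P[4]) * 0.5              # fine woody -> active/slow
    T[4, 8] = (1 - P[4]) * 0.5
    T[5, 7] = (1 - P[5]) * 0.3              # coarse woody -> active/slow
    T[5, 8] = (1 - P[5]) * 0.7
    T[6, 7] = (1 - P[6]) * 0.3              # bg coarse -> active/slow
    T[6, 8] = (1 - P[6]) * 0.7
    T[7, 8] = 1 - P[7]                      # active -> slow
    T[8, 7] = (1 - P[8]) * 0.5              # slow -> active/resistant
    T[8, 9] = (1 - P[8]) * 0.5
    T[9, 7] = 1 - P[9]                      # resistant -> active
    return T


_DEFAULT_S = np.array(
    [0.021, 0.1, 0.027, 0.13, 0.01, 0.002, 0.002, 0.042, 0.001, 3.5e-5]
)
_DEFAULT_P = np.array(
    [0.55, 0.45, 0.55, 0.45, 0.45, 0.45, 0.45, 0.60, 0.55, 0.55]
)
_DEFAULT_CN = np.array(
    [15.0, 150.0, 15.0, 150.0, 250.0, 500.0, 250.0, 8.0, 12.0, 7.0]
)


@dataclass
class SoilParams:
    """Decomposition constants of the ten-pool soil submodel."""

    S_u: np.ndarray = field(default_factory=lambda: _DEFAULT_S.copy())
    P_u: np.ndarray = field(default_factory=lambda: _DEFAULT_P.copy())
    transfer_matrix: np.ndarray = field(default_factory=_default_transfer_matrix)
    CN_u: np.ndarray = field(default_factory=lambda: _DEFAULT_CN.copy())
    b: float = 5.0          # lignin shielding constant
    e_w: float = 0.6        # moisture-optimum constant
    shield_all_pools: bool = False

    def __post_init__(self) -> None:
        self.S_u = np.asarray(self.S_u, dtype=float)
        self.P_u = np.asarray(self.P_u, dtype=float)
        self.transfer_matrix = np.asarray(self.transfer_matrix, dtype=float)
        self.CN_u = np.asarray(self.CN_u, dtype=float)
        if self.S_u.shape != (10,) or self.P_u.shape != (10,):
            raise ValueError("S_u and P_u must have 10 entries")
        if self.transfer_matrix.shape != (10, 10):
            raise ValueError("transfer_matrix must be 10x10")
        if np.any(self.P_u < 0) or np.any(self.P_u > 1):
            raise ValueError("respired fractions P_u must lie in [0, 1]")
        row_sums = self.transfer_matrix.sum(axis=1)
        if np.any(row_sums > 1 - self.P_u + 1e-12):
            raise ValueError("transfer_matrix row sums may not exceed 1 - P_u")


@dataclass
class GridCell:
    """One grid cell: a representative tree patch plus its soil column."""

    id: str
    lat: float
    lon: float
    forest_type: ForestType
    coverage: float
    trees: list[TreeState]
    soil: SoilState
    area: float = 1.0e8          # m^2 (10 km x 10 km)
    patch_area: float = 900.0    # m^2 of the representative patch
    ndvi: float | None = None
    spinup_converged: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")
        if self.patch_area <= 0:
            raise ValueError("patch area must be positive")

    @property
    def lai(self) -> float:
        """Patch leaf area index: sum of per-tree contributions."""
        return sum(t.lai_tree for t in self.trees)

    @property
    def vegetation_carbon(self) -> float:
        """Vegetation carbon per m^2 of patch ground, kgC m^-2."""
        return sum(t.total_carbon for t in self.trees) / self.patch_area

    @property
    def ecosystem_carbon(self) -> float:
        return self.vegetation_carbon + self.soil.total_carbon


@dataclass
class FluxRecord:
    """Annual carbon fluxes of one cell, kgC·m^-2·a^-1."""

    year: int
    GPP: float
    R_a: float          # autotrophic (maintenance + growth)
    NPP: float
    R_s: float          # soil heterotrophic
    NEP: float

    def __post_init__(self) -> None:
        if abs(self.NEP - (self.NPP - self.R_s)) > 1e-9 * max(1.0, abs(self.NPP)):
            raise ValueError("NEP must equal NPP - R_s")


@dataclass
class RegionalSummary:
    """Per-forest-type annual NEP totals and relative contributions."""

    per_type_nep: dict[ForestType, float]       # TgC a^-1
    contribution: dict[ForestType, float]       # percent of net total
    national_total: float                       # PgC a^-1
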