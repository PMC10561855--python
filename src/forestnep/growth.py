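"""Annual tree growth: allometry, photosynthate allocation, litter.

Daily net assimilate accumulates in each tree's nonstructural buffer;
once a year the buffer is spent — a fixed share on flower/fruit litter,
then leaf mass up to its allometric cap, fine roots toward a fixed
root:leaf ratio, and the remainder (less a small retained reserve) on
wood. The stem increment inverts the power-law stem allometry to a new
DBH, from which height follows. No establishment or mortality: the
stand's composition is fixed over a run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SpeciesParams, TreeState

__all__ = [
    "lai_from_ndvi",
    "stem_carbon",
    "dbh_from_stem_carbon",
    "height_from_dbh",
    "leaf_cap",
    "build_stand",
    "daily_litterfall",
    "annual_growth",
    "AllocationResult",
]

#: Wood allocation split between stem, branches and coarse roots.
WOOD_SPLIT = {"stem": 0.60, "branch": 0.25, "coarseroot": 0.15}

#: Fraction of the post-allocation surplus retained in the buffer.
BUFFER_RETAIN = 0.10


def lai_from_ndvi(ndvi: float, params: SpeciesParams) -> float:
    """Invert a scene NDVI to the initial stand LAI.

    Linear ramp between the scene bounds:
    ``LAI = LAI_v (NDVI - NDVI_min) / (NDVI_max - NDVI_min)``.
    Out-of-range NDVI is clamped with a warning.
    """
    if not (params.NDVI_min <= ndvi <= params.NDVI_max):
        warnings.warn(
            f"NDVI {ndvi:.3f} outside [{params.NDVI_min}, {params.NDVI_max}]; clamped",
            stacklevel=2,
        )
        ndvi = min(max(ndvi, params.NDVI_min), params.NDVI_max)
    return params.LAI_v * (ndvi - params.NDVI_min) / (params.NDVI_max - params.NDVI_min)


def stem_carbon(dbh: float, params: SpeciesParams) -> float:
    """Stem carbon (kgC) from DBH (cm): ``a_w DBH^b_w``."""
    return params.a_w * dbh ** params.b_w


def dbh_from_stem_carbon(c_stem: float, params: SpeciesParams) -> float:
    """Invert the stem allometry: DBH = (C_stem/a_w)^(1/b_w)."""
    if c_stem <= 0:
        raise ValueError("stem carbon must be positive")
    return (c_stem / params.a_w) ** (1.0 / params.b_w)


def height_from_dbh(dbh: float, params: SpeciesParams) -> float:
    """Tree height (m) from DBH (cm): ``a_h DBH^b_h``."""
    return params.a_h * dbh ** params.b_h


def leaf_cap(dbh: float, params: SpeciesParams) -> float:
    """Allometric maximum leaf carbon per tree, kgC: ``a_l DBH^b_l``."""
    return params.a_l * dbh ** params.b_l


def build_stand(
    params: SpeciesParams,
    lai: float,
    n_trees: int = 36,
    patch_area: float = 900.0,
    rng: np.random.Generator | None = None,
) -> list[TreeState]:
    """Initialize a stand whose summed leaf area matches a target LAI.

    DBH is drawn lognormally (median ~15 cm); leaf carbon is distributed
    across trees in proportion to each tree's allometric leaf cap and
    scaled so the patch leaf area equals ``lai`` (or the allometric
    maximum, whichever is smaller). Fine roots, wood pools and sapwood
    follow the allometric defaults.
    """
    if n_trees < 1:
        raise ValueError("need at least one tree")
    rng = rng or np.random.default_rng(0)
    dbh = np.clip(np.exp(rng.normal(np.log(15.0), 0.3, size=n_trees)), 5.0, 45.0)
    caps = np.array([leaf_cap(d, params) for d in dbh])
    target_leaf = lai * patch_area / params.sla
    scale = min(1.0, target_leaf / caps.sum()) if caps.sum() > 0 else 0.0
    trees = []
    for d, cap in zip(dbh, caps):
        c_stem = stem_carbon(d, params)
        c_branch = 0.25 * c_stem
        c_croot = 0.25 * c_stem
        c_leaf = scale * cap
        trees.append(TreeState(
            dbh=float(d),
            height=height_from_dbh(float(d), params),
            C_leaf=float(c_leaf),
            C_fineroot=float(params.root_leaf_ratio * c_leaf),
            C_branch=float(c_branch),
            C_stem=float(c_stem),
            C_coarseroot=float(c_croot),
            C_sapwood=float(params.sapwood_fraction * (c_stem + c_branch + c_croot)),
            C_buffer=float(0.1 * c_leaf),
            underbranch_height=0.4 * height_from_dbh(float(d), params),
            lai_tree=float(c_leaf * params.sla / patch_area),
        ))
    return trees


def daily_litterfall(
    tree: TreeState,
    params: SpeciesParams,
    patch_area: float,
    shed_all_leaves: bool = False,
    leaves_active: bool = True,
) -> dict[str, float]:
    """Remove one day of background litter from a tree (in place).

    Leaf and fine-root pools shed at constant daily turnover rates; on a
    deciduous leaf-off day ``shed_all_leaves`` drops the whole canopy,
    and a dormant canopy (``leaves_active=False``) sheds no leaf litter.
    Returns the litter masses in kgC per tree.
    """
    if shed_all_leaves:
        leaf_litter = tree.C_leaf
    elif leaves_active:
        leaf_litter = params.leaf_turnover * tree.C_leaf
    else:
        leaf_litter = 0.0
    root_litter = params.fineroot_turnover * tree.C_fineroot
    tree.C_leaf -= leaf_litter
    tree.C_fineroot -= root_litter
    tree.lai_tree = tree.C_leaf * params.sla / patch_area
    return {"leaf": leaf_litter, "fineroot": root_litter}


@dataclass
class AllocationResult:
    """Carbon accounting of one annual allocation, kgC per tree."""

    fruit_litter: float
    leaf_alloc: float
    root_alloc: float
    wood_alloc: float
    retained: float

    @property
    def total(self) -> float:
        return (self.fruit_litter + self.leaf_alloc + self.root_alloc
                + self.wood_alloc + self.retained)


def annual_growth(
    tree: TreeState,
    params: SpeciesParams,
    patch_area: float,
    starvation_tolerance: float = 0.5,
    leaf_budget: float | None = None,
) -> AllocationResult:
    """Spend the year's buffered photosynthate on structure (in place).

    A positive buffer pays flower/fruit litter first, then fills leaf
    mass to its allometric cap, fine roots toward the root:leaf ratio,
    and wood; a small reserve stays in the buffer. The stem share of the
    wood increment updates DBH and height through the inverted stem
    allometry. Carbon closes exactly:
    ``buffer_before = fruit + leaf + root + wood + retained``.

    ``leaf_budget`` (kgC) is the stand-level leaf headroom — the caller
    passes the remaining distance to the species' maximum canopy LAI so
    the patch canopy cannot overshoot ``LAI_v``; ``None`` means no
    stand-level limit.

    A non-positive buffer allocates nothing; below
    ``-starvation_tolerance`` kgC the tree is flagged carbon-starved.
    """
    if not np.isfinite(tree.C_buffer):
        raise ValueError("buffer must be finite")
    buffer_before = tree.C_buffer
    if buffer_before <= 0.0:
        if buffer_before < -starvation_tolerance:
            tree.carbon_starved = True
        return AllocationResult(0.0, 0.0, 0.0, 0.0, buffer_before)

    fruit = params.fruit_fraction * buffer_before
    available = buffer_before - fruit

    deficit = max(0.0, leaf_cap(tree.dbh, params) - tree.C_leaf)
    if leaf_budget is not None:
        deficit = min(deficit, max(leaf_budget, 0.0))
    leaf_alloc = min(deficit, available)
    available -= leaf_alloc
    tree.C_leaf += leaf_alloc
    tree.lai_tree = tree.C_leaf * params.sla / patch_area

    root_target = params.root_leaf_ratio * tree.C_leaf
    root_alloc = min(max(0.0, root_target - tree.C_fineroot), available)
    available -= root_alloc
    tree.C_fineroot += root_alloc

    retained = BUFFER_RETAIN * available
    wood_alloc = available - retained
    tree.C_stem += WOOD_SPLIT["stem"] * wood_alloc
    tree.C_branch += WOOD_SPLIT["branch"] * wood_alloc
    tree.C_coarseroot += WOOD_SPLIT["coarseroot"] * wood_alloc
    tree.C_sapwood = min(
        tree.C_sapwood + params.sapwood_fraction * wood_alloc,
        tree.C_branch + tree.C_stem + tree.C_coarseroot,
    )

    tree.dbh = dbh_from_stem_carbon(tree.C_stem, params)
    tree.height = height_from_dbh(tree.dbh, params)
    tree.underbranch_height = 0.4 * tree.height
    tree.C_buffer = retained
    return AllocationResult(fruit, leaf_alloc, root_alloc, wood_alloc, retained)
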