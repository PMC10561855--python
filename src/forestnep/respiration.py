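"""Maintenance and growth respiration of individual trees.

Maintenance respiration follows a modified-Q10 law referenced to 15 °C:
the exponent ``0.069315 (T-15) - 0.009 (T-15)^2`` doubles respiration per
10 °C near the reference (0.069315 = ln(2)/10) while the quadratic term
caps the response at high temperature (vertex near 18.85 °C above the
reference). Day and night are weighted by sunshine hours.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

__all__ = [
    "temperature_factor",
    "maintenance_respiration",
    "growth_respiration",
    "accumulate_npp",
]

_LN2_10 = 0.069315
_QUAD = 0.009


def temperature_factor(T: float) -> float:
    """Respiration multiplier relative to 15 °C: e^(0.069315 dT - 0.009 dT^2)."""
    dT = T - 15.0
    return math.exp(_LN2_10 * dT - _QUAD * dT * dT)


def maintenance_respiration(
    D: float, T_d: float, T_n: float,
    components: Mapping[str, tuple[float, float]],
) -> float:
    """Daily maintenance respiration of one tree, kgC·d^-1.

    ``R_m = sum_k (1/24)[D f(T_d) + (24-D) f(T_n)] R_k C_k`` where ``f``
    is :func:`temperature_factor`. ``components`` maps a component name
    to its ``(R_k, C_k)`` pair — for leaves and fine roots ``C_k`` is
    the pool itself; for branches, stems and coarse roots it is the
    live sapwood carbon.
    """
    if not (0.0 <= D <= 24.0):
        raise ValueError("sunshine hours D must lie in [0, 24]")
    weight = (D * temperature_factor(T_d) + (24.0 - D) * temperature_factor(T_n)) / 24.0
    total = 0.0
    for name, (R_k, C_k) in components.items():
        if R_k < 0:
            raise ValueError(f"negative respiration rate for {name!r}")
        if C_k < 0:
            raise ValueError(f"negative carbon pool for {name!r}")
        total += weight * R_k * C_k
    return total


def growth_respiration(GPP_d: float, R_m: float, r_g: float) -> float:
    """Daily growth respiration ``R_g = r_g max(GPP_d - R_m, 0)``, kgC·d^-1.

    Construction cost is charged only on the surplus over maintenance;
    deficit days carry no (negative) growth respiration.
    """
    if not (0.0 < r_g < 1.0):
        raise ValueError("growth respiration coefficient r_g must be in (0,1)")
    return r_g * max(GPP_d - R_m, 0.0)


def accumulate_npp(daily: Iterable[tuple[float, float, float]]) -> float:
    """Annual NPP = sum over the year of (GPP_d - R_m - R_g), kgC·m^-2·a^-1.

    ``daily`` yields one ``(GPP_d, R_m, R_g)`` triple per day; a full
    calendar year (365 or 366 entries) is required. The result may be
    negative in years when respiration outruns assimilation.
    """
    records = list(daily)
    if len(records) not in (365, 366):
        raise ValueError(
            f"need one full calendar year of records, got {len(records)} days"
        )
    return float(sum(g - m - r for g, m, r in records))
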