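"""Daily canopy gross primary production.

The canopy is a single big leaf: light attenuates exponentially with
cumulative leaf area (Beer–Lambert, coefficient ``K``), each leaf layer
follows a rectangular-hyperbola light response with initial slope ``S``
and asymptote ``A_m``, and the analytic integral over the canopy and the
daylight period yields the daily light-saturated maximum ``GPP_m``.
Actual daily GPP scales ``GPP_m`` by multiplicative CO2, soil-water and
temperature modifiers and is capped by available soil nitrogen via the
assimilation C:N ratio ``alpha``.
"""

from __future__ import annotations

import math

__all__ = ["f_co2", "f_water", "f_temp", "gpp_max", "gpp_daily"]


def f_co2(C_t: float, C_0: float) -> float:
    """CO2 fertilization multiplier.

    ``F_c = 1 + (C_t - C_0) / (C_t + 2 C_0)``: unity at the reference
    concentration, approaching 2 as ``C_t`` grows without bound.
    """
    if C_t <= 0 or C_0 <= 0:
        raise ValueError("CO2 concentrations must be positive")
    return 1.0 + (C_t - C_0) / (C_t + 2.0 * C_0)


def f_water(W_s: float, W_f: float, Rh: float, W: float) -> float:
    """Soil-water multiplier ``F_w = min[1, W_s/W_f + max(Rh-0.5, 0.1)]^(W/2)``.

    ``W`` is the species drought tolerance; larger values punish dry soil
    harder. The result lies in (0, 1] and is non-decreasing in both soil
    water and air humidity.
    """
    if W_f <= 0:
        raise ValueError("field capacity W_f must be positive")
    if not (0.0 <= W_s <= W_f):
        raise ValueError("require 0 <= W_s <= W_f")
    if not (0.0 <= Rh <= 1.0):
        raise ValueError("relative humidity must lie in [0, 1]")
    if W <= 0:
        raise ValueError("drought tolerance W must be positive")
    inner = min(1.0, W_s / W_f + max(Rh - 0.5, 0.1))
    return inner ** (W / 2.0)


def f_temp(T: float, T_min_p: float, T_opt_p: float, T_max_p: float) -> float:
    """Beta-type temperature response of photosynthesis.

    ``F_t = ((T_max-T)/(T_max-T_opt))^e1 * ((T-T_min)/(T_opt-T_min))^e2``
    with exponents ``e1 = (T_max-T_opt)/(T_max-T_min)`` and
    ``e2 = (T_opt-T_min)/(T_max-T_min)`` — the unique pair for which the
    response peaks at exactly 1 at ``T_opt`` and stays within [0, 1].
    Clamped to zero outside the cardinal range, where the expression is
    undefined.
    """
    if not (T_min_p < T_opt_p < T_max_p):
        raise ValueError("cardinal temperatures out of order")
    if T <= T_min_p or T >= T_max_p:
        return 0.0
    span = T_max_p - T_min_p
    e1 = (T_max_p - T_opt_p) / span
    e2 = (T_opt_p - T_min_p) / span
    left = ((T_max_p - T) / (T_max_p - T_opt_p)) ** e1
    right = ((T - T_min_p) / (T_opt_p - T_min_p)) ** e2
    return left * right


def gpp_max(A_m: float, D: float, K: float, S: float,
            PAR_noon: float, LAI: float) -> float:
    """Daily light-saturated canopy GPP, kgC·m^-2·d^-1.

    ``GPP_m = (2 A_m D / K) ln[(1 + sqrt(1 + K S PAR / A_m)) /
    (1 + sqrt(1 + K S PAR e^{-K LAI} / A_m))]`` — the big-leaf canopy
    integral of the leaf light response over ``LAI`` and ``D`` daylight
    hours driven by noon PAR in W·m^-2.
    """
    if A_m <= 0 or K <= 0 or S <= 0:
        raise ValueError("A_m, K and S must be positive")
    if not (0.0 <= D <= 24.0):
        raise ValueError("sunshine hours D must lie in [0, 24]")
    if PAR_noon < 0 or LAI < 0:
        raise ValueError("PAR and LAI must be non-negative")
    top = 1.0 + math.sqrt(1.0 + K * S * PAR_noon / A_m)
    bot = 1.0 + math.sqrt(1.0 + K * S * PAR_noon * math.exp(-K * LAI) / A_m)
    return (2.0 * A_m * D / K) * math.log(top / bot)


def gpp_daily(GPP_m: float, F_c: float, F_w: float, F_t: float,
              alpha: float, N_s: float) -> float:
    """Daily GPP: ``min(GPP_m F_c F_w F_t, alpha N_s)``, kgC·m^-2·d^-1.

    The second branch is the nitrogen cap — daily assimilation cannot
    exceed the carbon supportable by available soil N at the
    assimilation C:N ratio ``alpha``.
    """
    if min(GPP_m, F_c, F_w, F_t, alpha, N_s) < 0:
        raise ValueError("all factors must be non-negative")
    return min(GPP_m * F_c * F_w * F_t, alpha * N_s)
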