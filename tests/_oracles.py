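"""Independent brute-force oracles shared between test modules.

These deliberately avoid the package's own vectorized code paths:
scalar loops, explicit arithmetic, high-precision arithmetic where the
tolerance demands it.
"""

import math


def gpp_max_oracle(A_m, D, K, S, PAR, LAI):
    """50-digit evaluation of the big-leaf daily canopy integral."""
    from mpmath import mp, mpf

    with mp.workdps(50):
        A_m, D, K, S, PAR, LAI = map(mpf, (A_m, D, K, S, PAR, LAI))
        top = 1 + mp.sqrt(1 + K * S * PAR / A_m)
        bot = 1 + mp.sqrt(1 + K * S * PAR * mp.exp(-K * LAI) / A_m)
        return float(2 * A_m * D / K * mp.log(top / bot))


def decomposition_oracle(C, S, P, transfer, G_t, G_w, b, L_s, shielded_pools,
                         CN):
    """Scalar-loop re-derivation of one daily decomposition step.

    Returns (new_pools, respired_total, mineralized_N) as plain lists
    and floats.
    """
    n = len(C)
    shield = [math.exp(-b * L_s) if u in shielded_pools else 1.0 for u in range(n)]
    flux = [min(S[u] * G_t * G_w * shield[u], 1.0) * C[u] for u in range(n)]
    respired = [P[u] * flux[u] for u in range(n)]
    new = list(C)
    for u in range(n):
        new[u] -= flux[u]
        for v in range(n):
            new[v] += transfer[u][v] * flux[u]
    mineral = sum(respired[u] / CN[u] for u in range(n))
    return new, sum(respired), mineral
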