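"""Independent reference implementations used only as test oracles.

These deliberately re-derive results through different routes than the
package (closed-form steady state vs time evolution; hand-written pooled
t formula vs scipy) so agreement is informative.
"""

import numpy as np

GAMMA_HZ_PER_UT = 42.577


def steady_state_water_mz(pools, water, offset_ppm, power_ut,
                          field_hz_per_ppm=300.0, b1_scale=1.0):
    """Closed-form steady state of the linearized Bloch–McConnell system.

    Solves A x = −b for the full coupled system assembled independently of
    the package (per-pool blocks built explicitly), returning water Mz/M0.
    """
    omega1 = 2 * np.pi * GAMMA_HZ_PER_UT * power_ut * b1_scale
    all_pools = [water] + list(pools)
    n = len(all_pools)
    A = np.zeros((3 * n, 3 * n))
    b = np.zeros(3 * n)
    k_w = sum(p.proton_fraction * p.exchange_rate for p in pools)
    for i, p in enumerate(all_pools):
        r1, r2 = 1 / p.t1, 1 / p.t2
        m0 = 1.0 if i == 0 else p.proton_fraction
        k = k_w if i == 0 else p.exchange_rate
        d = 2 * np.pi * field_hz_per_ppm * (p.chemical_shift - offset_ppm)
        j = 3 * i
        A[j:j + 3, j:j + 3] = [[-(r2 + k), -d, 0.0],
                               [d, -(r2 + k), omega1],
                               [0.0, -omega1, -(r1 + k)]]
        b[j + 2] = r1 * m0
    for i, p in enumerate(pools):
        j = 3 * (i + 1)
        for ax in range(3):
            A[ax, j + ax] += p.exchange_rate
            A[j + ax, ax] += p.proton_fraction * p.exchange_rate
    x = np.linalg.solve(A, -b)
    return x[2]


def pooled_t_test(a, b):
    """Equal-variance two-sample t from first principles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    from scipy.special import betainc
    # two-sided p via the regularized incomplete beta function
    p = betainc(df / 2, 0.5, df / (df + t * t))
    return t, df, p
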