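"""Bloch–McConnell simulation of continuous-wave saturation Z-spectra.

The coupled Bloch equations with two-site (water + n solute pools) chemical
exchange are evolved under a continuous-wave saturation pulse of given
amplitude and duration, starting from thermal equilibrium.  The normalized
longitudinal water magnetization at each saturation offset is the Z-spectrum
``S(Δω)/S0``.

The time evolution is computed from the eigendecomposition of the augmented
(homogeneous) system matrix, i.e. a matrix-exponential propagator — not a
steady-state shortcut — so finite saturation times are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

#: gyromagnetic ratio of 1H, Hz per microtesla
GAMMA_HZ_PER_UT = 42.577


@dataclass(frozen=True)
class PoolParameters:
    """Relaxation/exchange parameters of one proton pool.

    Parameters
    ----------
    chemical_shift : float
        Resonance offset from water, ppm.
    exchange_rate : float
        Solute-to-water exchange rate, s^-1 (0 for water itself).
    proton_fraction : float
        Equilibrium magnetization relative to water (1.0 for water;
        solute pools must lie in (0, 0.1]).
    t1, t2 : float
        Longitudinal / transverse relaxation times, s.
    """

    chemical_shift: float
    exchange_rate: float
    proton_fraction: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        vals = (self.chemical_shift, self.exchange_rate,
                self.proton_fraction, self.t1, self.t2)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite pool parameters: {vals}")
        if self.exchange_rate < 0:
            raise ValueError("exchange_rate must be >= 0")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("T1 and T2 must be > 0")
        if self.proton_fraction <= 0:
            raise ValueError("proton_fraction must be > 0")

    def with_fraction(self, proton_fraction: float) -> "PoolParameters":
        return PoolParameters(self.chemical_shift, self.exchange_rate,
                              proton_fraction, self.t1, self.t2)


#: literature-typical water pool at 7 T rodent brain
WATER_POOL = PoolParameters(chemical_shift=0.0, exchange_rate=0.0,
                            proton_fraction=1.0, t1=1.8, t2=0.04)

#: literature-typical glutamate amine pool (+3.0 ppm, fast exchange);
#: the proton fraction is a placeholder, normally set by calibration
GLU_AMINE_POOL = PoolParameters(chemical_shift=3.0, exchange_rate=5500.0,
                                proton_fraction=2e-3, t1=1.0, t2=0.01)


def _system_matrices(pools, water, offsets_ppm, omega1, field_hz_per_ppm):
    """Assemble batched Bloch–McConnell matrices A and drive vectors b.

    Returns ``A`` with shape (n_offsets, d, d) and ``b`` with shape (d,)
    where d = 3 * (1 + n_pools); state ordering is
    [Mx_w, My_w, Mz_w, Mx_1, My_1, Mz_1, ...].
    """
    offsets_ppm = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    n_off = offsets_ppm.size
    all_pools = [water] + list(pools)
    n = len(all_pools)
    d = 3 * n
    A = np.zeros((n_off, d, d))
    b = np.zeros(d)

    # water loses magnetization to every solute pool at rate f_i * k_i
    k_from_water = sum(p.proton_fraction * p.exchange_rate for p in pools)

    two_pi_f = 2.0 * np.pi * field_hz_per_ppm
    for i, p in enumerate(all_pools):
        j = 3 * i
        r1, r2 = 1.0 / p.t1, 1.0 / p.t2
        m0 = 1.0 if i == 0 else p.proton_fraction
        k_out = k_from_water if i == 0 else p.exchange_rate
        # offset of saturation relative to this pool's resonance, rad/s
        delta = (p.chemical_shift - offsets_ppm) * two_pi_f
        A[:, j, j] = -(r2 + k_out)
        A[:, j, j + 1] = -delta
        A[:, j + 1, j] = delta
        A[:, j + 1, j + 1] = -(r2 + k_out)
        A[:, j + 1, j + 2] = omega1
        A[:, j + 2, j + 1] = -omega1
        A[:, j + 2, j + 2] = -(r1 + k_out)
        b[j + 2] = r1 * m0
        if i == 0:
            for jj, q in enumerate(pools):
                c = 3 * (jj + 1)
                for ax in range(3):
                    A[:, j + ax, c + ax] = q.exchange_rate
                    A[:, c + ax, j + ax] = q.proton_fraction * q.exchange_rate
    return A, b


def _equilibrium(pools, water) -> np.ndarray:
    all_pools = [water] + list(pools)
    m0 = np.zeros(3 * len(all_pools))
    for i, p in enumerate(all_pools):
        m0[3 * i + 2] = 1.0 if i == 0 else p.proton_fraction
    return m0


def evolve_saturation(pools, water, offsets_ppm, sat_power_ut, sat_duration_s,
                      field_hz_per_ppm=300.0, b0_shift_ppm=0.0, b1_scale=1.0):
    """Evolve magnetization from equilibrium under CW saturation.

    The saturation is applied at each requested offset; a per-voxel static
    field error shifts the water resonance, so the effective offset in the
    water frame is ``offset - b0_shift_ppm``.  Returns the normalized water
    Mz at ``sat_duration_s`` for every offset, shape (n_offsets,).
    """
    if sat_power_ut < 0:
        raise ValueError("saturation power must be >= 0")
    if sat_duration_s <= 0:
        raise ValueError("saturation duration must be > 0")
    offsets_ppm = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    omega1 = 2.0 * np.pi * GAMMA_HZ_PER_UT * sat_power_ut * b1_scale
    if omega1 == 0.0:
        return np.ones(offsets_ppm.size)
    eff = offsets_ppm - b0_shift_ppm
    A, b = _system_matrices(pools, water, eff, omega1, field_hz_per_ppm)
    m0 = _equilibrium(pools, water)
    mz = _propagate(A, b, m0, sat_duration_s)
    return mz


def _propagate(A, b, m0, t):
    """Water Mz after time t via eigendecomposition of the augmented system.

    The affine ODE dM/dt = A M + b is embedded homogeneously as
    d[M;1]/dt = [[A, b],[0, 0]] [M;1] and propagated through
    V exp(Λ t) V^-1; a dense ``expm`` fallback guards rare ill-conditioned
    eigenvector bases.
    """
    n_off, d, _ = A.shape
    aug = np.zeros((n_off, d + 1, d + 1))
    aug[:, :d, :d] = A
    aug[:, :d, d] = b
    x0 = np.append(m0, 1.0)

    lam, V = np.linalg.eig(aug)
    coef = np.linalg.solve(V, np.broadcast_to(x0, (n_off, d + 1))[..., None])
    xt = (V * np.exp(lam * t)[:, None, :]) @ coef
    mz = np.real(xt[:, 2, 0])

    # residual check: defective/ill-conditioned eigenbases fall back to expm
    recon = np.linalg.norm((V * lam[:, None, :]) @ coef
                           - aug @ (V @ coef), axis=(1, 2))
    bad = ~np.isfinite(mz) | (recon > 1e-6 * max(1.0, float(np.abs(lam).max())))
    for i in np.nonzero(bad)[0]:
        xt_i = scipy.linalg.expm(aug[i] * t) @ x0
        mz[i] = xt_i[2]
    return mz


def simulate_zspectrum(pools, water, schedule, b0_shift=0.0, b1_scale=1.0,
                       offsets=None, sat_duration_ms=None):
    """Simulate a normalized Z-spectrum S(Δω)/S0 for an acquisition schedule.

    Parameters
    ----------
    pools : list of PoolParameters
        Solute pools (may be empty for a pure-water spectrum).
    water : PoolParameters
        The water pool.
    schedule : AcquisitionSchedule
        Provides saturation power/duration, offsets and field strength.
    b0_shift : float
        Static field offset of this voxel, ppm.
    b1_scale : float
        Relative transmit field (actual/nominal B1).
    offsets : array-like, optional
        Override the schedule's CEST offsets (e.g. the WASSR grid).
    sat_duration_ms : float, optional
        Override the schedule's saturation duration.

    Returns
    -------
    ndarray of S/S0 in [0, 1], one value per offset.
    """
    off = schedule.cest_offsets if offsets is None else np.asarray(offsets, float)
    dur = schedule.sat_duration if sat_duration_ms is None else sat_duration_ms
    return evolve_saturation(pools, water, off,
                             sat_power_ut=schedule.sat_power,
                             sat_duration_s=dur / 1000.0,
                             field_hz_per_ppm=schedule.field_strength,
                             b0_shift_ppm=b0_shift, b1_scale=b1_scale)
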