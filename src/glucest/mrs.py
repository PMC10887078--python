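"""Simplified linear-combination quantification of 1H MR spectra.

A metabolite spectrum over the 4.3–0.3 ppm window is modeled as a
nonnegative superposition of basis spectra (sums of pseudo-Voigt lines at
fixed literature positions) plus a smooth polynomial baseline, and fitted
by bounded linear least squares.  Coefficients are converted to μmol/g by
water scaling against the unsuppressed water reference.

This is a deliberately transparent stand-in for full commercial
linear-combination packages: no regularized lineshape estimation, no
macromolecule model, no eddy-current compensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import lsq_linear

#: tissue water concentration used for internal-reference scaling,
#: μmol/g-equivalent (configuration, cancels in forward/inverse use)
WATER_CONCENTRATION = 43300.0

#: default unsuppressed water reference area, arbitrary units
DEFAULT_WATER_AREA = 1.0e6

#: line positions (ppm) and effective proton counts per modeled moiety;
#: configuration data with literature-typical chemical shifts
DEFAULT_METABOLITE_LINES: dict[str, list[tuple[float, float]]] = {
    "NAA": [(2.008, 3.0)],
    "Cr": [(3.027, 3.0), (3.913, 2.0)],
    "Cho": [(3.185, 9.0)],
    "Glu": [(2.040, 2.0), (2.340, 2.0), (3.740, 1.0)],
    "Gln": [(2.110, 2.0), (2.440, 2.0), (3.750, 1.0)],
    "mIns": [(3.520, 4.0), (3.610, 2.0)],
    "Tau": [(3.250, 2.0), (3.420, 2.0)],
}

#: literature-typical rodent-brain concentrations, μmol/g (generator defaults)
DEFAULT_CONCENTRATIONS = {
    "NAA": 8.5, "Cr": 8.0, "Cho": 1.8, "Glu": 7.0, "Gln": 4.5,
    "mIns": 5.5, "Tau": 5.0,
}


@dataclass
class MRSpectrum:
    """A 1D 1H spectrum with its unsuppressed water reference area."""

    ppm_axis: np.ndarray
    intensity: np.ndarray
    water_reference_area: float
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm_axis.shape != self.intensity.shape:
            raise ValueError("ppm axis and intensity lengths differ")
        d = np.diff(self.ppm_axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be monotone")


@dataclass
class BasisSet:
    """Per-metabolite model spectra on a shared ppm grid."""

    names: list
    spectra: np.ndarray  # (n_metabolites, n_points)
    ppm_axis: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("metabolite names must be unique")
        if self.spectra.shape != (len(self.names), self.ppm_axis.size):
            raise ValueError("basis spectra shape mismatch")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown metabolite {name!r}; basis has "
                           f"{self.names}") from None


def _pseudo_voigt(x, center, hwhm, eta=0.5):
    lor = hwhm**2 / ((x - center) ** 2 + hwhm**2)
    sig = hwhm / np.sqrt(2 * np.log(2))
    gau = np.exp(-0.5 * ((x - center) / sig) ** 2)
    return (1 - eta) * lor + eta * gau


def make_basis(names=None, ppm_axis=None, hwhm_ppm: float = 0.02,
               eta: float = 0.5,
               lines: dict | None = None) -> BasisSet:
    """Build a basis of pseudo-Voigt line groups at fixed positions.

    Line amplitudes are proportional to the proton count of each moiety, so
    a unit coefficient corresponds to a fixed amount of metabolite
    regardless of multiplicity.
    """
    if ppm_axis is None:
        ppm_axis = default_ppm_axis()
    if lines is None:
        lines = DEFAULT_METABOLITE_LINES
    if names is None:
        names = list(lines)
    spectra = np.zeros((len(names), ppm_axis.size))
    for i, name in enumerate(names):
        if name not in lines:
            raise KeyError(f"no line table for metabolite {name!r}")
        for pos, protons in lines[name]:
            spectra[i] += protons * _pseudo_voigt(ppm_axis, pos, hwhm_ppm,
                                                  eta)
    return BasisSet(names=list(names), spectra=spectra, ppm_axis=ppm_axis)


def default_ppm_axis(n_points: int = 2048, lo: float = 0.0,
                     hi: float = 5.0) -> np.ndarray:
    """Descending ppm axis (conventional display order)."""
    return np.linspace(hi, lo, n_points)


def synthesize_spectrum(concentrations: dict, basis: BasisSet,
                        noise_sd: float = 0.0,
                        lineshape_broadening_hz: float = 0.0,
                        seed=None, baseline_coeffs=None,
                        water_reference_area: float = DEFAULT_WATER_AREA,
                        water_concentration: float = WATER_CONCENTRATION,
                        field_hz_per_ppm: float = 300.0,
                        acquisition: dict | None = None) -> MRSpectrum:
    """Forward-generate a spectrum from concentrations and a basis.

    Intensity scale is tied to the water reference: one μmol/g contributes
    ``water_reference_area / water_concentration`` units of basis
    amplitude, so the fit's water scaling inverts it exactly.
    """
    for name, c in concentrations.items():
        basis.index(name)
        if c < 0:
            raise ValueError(f"negative concentration for {name}")
    scale = water_reference_area / water_concentration
    y = np.zeros(basis.ppm_axis.size)
    for name, c in concentrations.items():
        y += c * scale * basis.spectra[basis.index(name)]
    if lineshape_broadening_hz > 0:
        step = abs(basis.ppm_axis[1] - basis.ppm_axis[0])
        sigma_ppm = lineshape_broadening_hz / field_hz_per_ppm / 2.355
        y = gaussian_filter1d(y, sigma_ppm / step)
    if baseline_coeffs is not None:
        y = y + np.polyval(baseline_coeffs, basis.ppm_axis) * scale
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, y.size)
    return MRSpectrum(ppm_axis=basis.ppm_axis.copy(), intensity=y,
                      water_reference_area=water_reference_area,
                      acquisition=acquisition or {"tr_ms": 5000.0,
                                                  "te_ms": 16.3})


@dataclass
class LCFitResult:
    """Linear-combination fit output: μmol/g estimates and relative SDs."""

    concentrations: dict
    relative_sd_percent: dict
    coefficients: np.ndarray
    baseline_coefficients: np.ndarray
    residual_rms: float
    window: tuple


def _design(spectrum, basis, baseline_order, window):
    if (spectrum.ppm_axis.size != basis.ppm_axis.size
            or not np.allclose(spectrum.ppm_axis, basis.ppm_axis)):
        raise ValueError("spectrum and basis must share a ppm grid")
    lo, hi = min(window), max(window)
    ax = spectrum.ppm_axis
    if lo < ax.min() - 1e-9 or hi > ax.max() + 1e-9:
        raise ValueError(f"fit window {window} outside axis range "
                         f"[{ax.min():g}, {ax.max():g}]")
    sel = (ax >= lo) & (ax <= hi)
    x = ax[sel]
    # baseline on a normalized coordinate for conditioning
    u = 2 * (x - lo) / (hi - lo) - 1
    bcols = np.vander(u, baseline_order + 1, increasing=True)
    X = np.hstack([basis.spectra[:, sel].T, bcols])
    return X, sel, len(basis.names)


def fit_linear_combination(spectrum: MRSpectrum, basis: BasisSet,
                           baseline_order: int = 2,
                           window: tuple = (0.3, 4.3),
                           water_concentration: float = WATER_CONCENTRATION
                           ) -> LCFitResult:
    """Nonnegative linear-combination fit with polynomial baseline.

    Metabolite coefficients are constrained nonnegative; baseline
    coefficients are free.  Concentrations are obtained by water scaling:
    conc = coeff × water_concentration / water_reference_area.  Relative
    SDs are Cramér–Rao-style, from the linear-model covariance at the
    residual noise level.
    """
    X, sel, n_met = _design(spectrum, basis, baseline_order, window)
    # collinearity screen on the metabolite columns
    B = X[:, :n_met]
    norms = np.linalg.norm(B, axis=0)
    corr = (B.T @ B) / np.outer(norms, norms)
    for i in range(n_met):
        for j in range(i + 1, n_met):
            if corr[i, j] > 1.0 - 1e-6:
                raise ValueError(
                    "singular design: basis spectra of "
                    f"{basis.names[i]!r} and {basis.names[j]!r} are "
                    "collinear")
    y = spectrum.intensity[sel]
    lb = np.r_[np.zeros(n_met), np.full(X.shape[1] - n_met, -np.inf)]
    res = lsq_linear(X, y, bounds=(lb, np.full(X.shape[1], np.inf)),
                     tol=1e-12)
    coef = res.x
    resid = y - X @ coef
    dof = max(y.size - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)

    w = water_concentration / spectrum.water_reference_area
    conc = {n: coef[i] * w for i, n in enumerate(basis.names)}
    rel = {}
    for i, n in enumerate(basis.names):
        sd = np.sqrt(max(cov[i, i], 0.0))
        rel[n] = 100.0 * sd / coef[i] if coef[i] > 0 else np.inf
    return LCFitResult(concentrations=conc, relative_sd_percent=rel,
                       coefficients=coef[:n_met],
                       baseline_coefficients=coef[n_met:],
                       residual_rms=float(np.sqrt(np.mean(resid**2))),
                       window=tuple(window))


def noise_for_relative_sd(basis: BasisSet, concentrations: dict,
                          target_rsd: float = 0.05, metabolite: str = "Glu",
                          baseline_order: int = 2, window: tuple = (0.3, 4.3),
                          water_reference_area: float = DEFAULT_WATER_AREA,
                          water_concentration: float = WATER_CONCENTRATION
                          ) -> float:
    """Additive noise SD giving a target CRLB-style relative SD.

    Solves σ such that the linear-model relative SD of the named
    metabolite's coefficient equals ``target_rsd`` at the given true
    concentrations.
    """
    spec = synthesize_spectrum(concentrations, basis,
                               water_reference_area=water_reference_area,
                               water_concentration=water_concentration)
    X, _, n_met = _design(spec, basis, baseline_order, window)
    inv = np.linalg.pinv(X.T @ X)
    i = basis.index(metabolite)
    amp = concentrations[metabolite] * water_reference_area / water_concentration
    return float(target_rsd * amp / np.sqrt(inv[i, i]))
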