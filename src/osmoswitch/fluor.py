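"""Steady-state fluorescence analysis.

Relative quantum yields against the NATA standard, the intensity-averaged
wavenumber that tracks both position and intensity of tryptophan emission,
SVD deconvolution of wavelength x condition spectra grids (the two-basis
picture: U1 the average spectrum, U2 the Tyr/Trp anti-correlation used as a
relative FRET ruler), the Forster relation, and the freely-jointed-chain
root-mean-square distance bound for the unfolded state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import EmissionSpectrum, SpectraMatrix

__all__ = [
    "SVDDecomposition",
    "FRETPair",
    "FJCChain",
    "quantum_yield",
    "intensity_avg_wavenumber",
    "svd_deconvolve",
    "count_significant_components",
    "fret_efficiency",
    "fret_distance",
    "fjc_rms_distance",
]

NATA_QY_WATER_25C = 0.13  # reference quantum yield of NATA in water at 25 C


@dataclass
class SVDDecomposition:
    """SVD of a wavelength x condition intensity grid.

    ``basis_spectra`` holds the left singular vectors as columns (U1, U2,
    ...), ``amplitudes[k, j]`` is the coefficient of component k at
    condition j (singular value folded in), so the grid reconstructs as
    ``basis_spectra @ amplitudes``.
    """

    wavelengths_nm: np.ndarray
    basis_spectra: np.ndarray
    singular_values: np.ndarray
    amplitudes: np.ndarray
    conditions: list
    sign_convention: str = "basis spectra oriented to non-negative mean"

    def reconstruct(self) -> np.ndarray:
        return self.basis_spectra @ self.amplitudes


@dataclass
class FRETPair:
    """A donor-acceptor pair on the Forster relation E = 1/(1+(r/r0)^6)."""

    r0_A: float
    distance_A: float
    efficiency: float = field(default=None)

    def __post_init__(self):
        if not (self.r0_A > 0 and self.distance_A > 0):
            raise ValueError("distances must be positive")
        e = fret_efficiency(self.distance_A, self.r0_A)
        if self.efficiency is None:
            self.efficiency = e
        elif abs(self.efficiency - e) > 1e-12:
            raise ValueError("stored efficiency inconsistent with distance/r0")


@dataclass(frozen=True)
class FJCChain:
    """Ideal freely-jointed chain: n rigid links of fixed bond length."""

    n_links: int
    bond_length_A: float

    def __post_init__(self):
        if self.n_links < 1 or not self.bond_length_A > 0:
            raise ValueError("need n_links >= 1 and positive bond length")


# ---------------------------------------------------------------------------

def _common_support(a: EmissionSpectrum, b: EmissionSpectrum):
    lo = max(a.wavelengths_nm[0], b.wavelengths_nm[0])
    hi = min(a.wavelengths_nm[-1], b.wavelengths_nm[-1])
    if lo >= hi:
        raise ValueError("spectra have no overlapping wavelength support")
    return lo, hi


def _integrate(spec: EmissionSpectrum, lo: float, hi: float) -> float:
    m = (spec.wavelengths_nm >= lo) & (spec.wavelengths_nm <= hi)
    if m.sum() < 2:
        raise ValueError("fewer than 2 points on the common support")
    return float(np.trapezoid(spec.intensities[m], spec.wavelengths_nm[m]))


def quantum_yield(sample: EmissionSpectrum, sample_absorbance: float,
                  reference: EmissionSpectrum, reference_absorbance: float,
                  qy_reference: float = NATA_QY_WATER_25C) -> float:
    """Relative quantum yield against a reference fluorophore.

    QY = QY_ref * (integral I_sample / integral I_ref) * (A_ref / A_sample),
    trapezoid integrals restricted to the common wavelength support. No
    polarization or refractive-index corrections are applied. Absorbances
    above 0.2 trigger an inner-filter warning.
    """
    for a, label in ((sample_absorbance, "sample"), (reference_absorbance, "reference")):
        if not a > 0:
            raise ValueError(f"{label} absorbance must be positive")
        if a > 0.2:
            warnings.warn(f"{label} absorbance {a} > 0.2: inner-filter effects likely")
    lo, hi = _common_support(sample, reference)
    i_ref = _integrate(reference, lo, hi)
    if i_ref <= 0:
        raise ValueError("reference spectrum integrates to zero")
    i_sam = _integrate(sample, lo, hi)
    return qy_reference * (i_sam / i_ref) * (reference_absorbance / sample_absorbance)


def intensity_avg_wavenumber(spectrum: EmissionSpectrum) -> float:
    """Intensity-averaged wavenumber on the 10^3 cm^-1 scale.

    nu_av = 1e4 * sum(I(lambda)/lambda) / sum(I(lambda)) with lambda in nm,
    evaluated as a discrete sum on the recorded grid (no interpolation).
    Warns when the grid spacing varies by more than 1%, since the discrete
    sum then weights spectral regions unevenly.
    """
    I = spectrum.intensities
    if not np.any(I > 0):
        raise ValueError("all-zero intensities: average wavenumber undefined")
    d = np.diff(spectrum.wavelengths_nm)
    if d.size and (d.max() - d.min()) > 0.01 * d.mean():
        warnings.warn("non-uniform wavelength grid (>1% spacing variation)")
    return float(1e4 * np.sum(I / spectrum.wavelengths_nm) / np.sum(I))


def svd_deconvolve(matrix: SpectraMatrix) -> SVDDecomposition:
    """Full singular value decomposition of a spectra grid.

    Signs are fixed so every basis spectrum has non-negative mean (the
    amplitude vectors are flipped to match), making amplitude trends
    reproducible; the convention is recorded on the result. The
    reconstruction from all components is exact to numerical precision.
    """
    M = matrix.intensities
    if M.shape[1] < 2 or M.shape[0] < 3:
        raise ValueError("need at least 2 conditions and 3 wavelengths")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    flip = np.where(U.mean(axis=0) < 0, -1.0, 1.0)
    U = U * flip
    Vt = Vt * flip[:, None]
    amplitudes = s[:, None] * Vt
    return SVDDecomposition(wavelengths_nm=matrix.wavelengths_nm,
                            basis_spectra=U, singular_values=s,
                            amplitudes=amplitudes,
                            conditions=list(matrix.conditions))


def count_significant_components(dec: SVDDecomposition,
                                 threshold_fraction: float = 0.05) -> int:
    """Number of singular values >= threshold_fraction * largest."""
    s = dec.singular_values
    if s.size == 0:
        return 0
    return int(np.sum(s >= threshold_fraction * s[0]))


# ---------------------------------------------------------------------------

def fret_efficiency(distance_A: float, r0_A: float) -> float:
    """Forster transfer efficiency E = 1 / (1 + (r/r0)^6)."""
    if not (distance_A > 0 and r0_A > 0):
        raise ValueError("distance and r0 must be positive")
    return 1.0 / (1.0 + (distance_A / r0_A) ** 6)


def fret_distance(efficiency: float, r0_A: float) -> float:
    """Invert the Forster relation: r = r0 * ((1-E)/E)^(1/6)."""
    if not r0_A > 0:
        raise ValueError("r0 must be positive")
    if not 0.0 < efficiency < 1.0:
        raise ValueError("efficiency must lie strictly in (0, 1): "
                         "distance is zero or unbounded at the endpoints")
    return r0_A * ((1.0 - efficiency) / efficiency) ** (1.0 / 6.0)


def fjc_rms_distance(chain: FJCChain) -> float:
    """Root-mean-square end-to-end distance of an ideal FJC: sqrt(n) * b."""
    return float(np.sqrt(chain.n_links) * chain.bond_length_A)
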