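"""Core containers shared by the analysis modules.

Every container is a small validated dataclass wrapping numpy arrays.
Units are fixed by convention and written into field names or docstrings:
wavelengths in nm, temperatures in degrees Celsius, times in ns,
concentrations in uM, ionic strengths in mM, energies in kcal/mol,
coordinates in Angstrom.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FixtureConfig",
    "EmissionSpectrum",
    "SpectraMatrix",
    "DecayTrace",
    "MeltCurve",
    "Thermogram",
    "BindingIsotherm",
    "AnisotropyTitration",
    "Ensemble",
]


def _as_float_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D array")
    if not np.all(np.isfinite(a)):
        raise ValueError("array contains non-finite values")
    return a


@dataclass(frozen=True)
class FixtureConfig:
    """Named parameter set describing one experimental condition.

    ``model_params`` holds the generator parameters for that condition
    (equilibrium constants in uM, Hill parameters, lifetimes in ns, band
    centers in nm, melt thermodynamics, ...), possibly nested by stage.
    The same (config, seed) pair always reproduces identical synthetic
    data bit for bit.
    """

    condition_label: str
    ionic_strength_mM: float
    temperature_C: float
    model_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not self.ionic_strength_mM > 0:
            raise ValueError("ionic strength must be positive")
        if not (-20.0 <= self.temperature_C <= 120.0):
            raise ValueError("temperature outside -20..120 C")
        for key, val in _iter_scalars(self.model_params):
            if key.endswith("_uM") and not val > 0:
                raise ValueError(f"concentration parameter {key} must be > 0")

    def param(self, *path, default=None):
        """Look up a (possibly nested) model parameter by key path."""
        node = self.model_params
        for p in path:
            if not isinstance(node, dict) or p not in node:
                if default is not None:
                    return default
                raise KeyError(f"model parameter {'.'.join(path)!r} not set "
                               f"for condition {self.condition_label!r}")
            node = node[p]
        return node


def _iter_scalars(d: dict, prefix=""):
    for k, v in d.items():
        if isinstance(v, dict):
            yield from _iter_scalars(v, prefix + k + ".")
        elif isinstance(v, (int, float)):
            yield prefix + k, v


@dataclass
class EmissionSpectrum:
    """A single fluorescence emission trace I(lambda) with its condition."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    temperature_C: float = 25.0
    ionic_strength_mM: float = 170.0
    excitation_nm: float = 274.0

    def __post_init__(self):
        self.wavelengths_nm = _as_float_array(self.wavelengths_nm)
        self.intensities = _as_float_array(self.intensities)
        if self.wavelengths_nm.size != self.intensities.size:
            raise ValueError("wavelength and intensity arrays differ in length")
        if self.wavelengths_nm.size < 3:
            raise ValueError("need at least 3 spectral points")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class SpectraMatrix:
    """Wavelength x condition intensity grid feeding SVD deconvolution.

    ``conditions`` is an ordered list of (temperature_C, ionic_strength_mM)
    pairs, one per column of ``intensities``.
    """

    wavelengths_nm: np.ndarray
    conditions: list
    intensities: np.ndarray

    def __post_init__(self):
        self.wavelengths_nm = _as_float_array(self.wavelengths_nm)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (wavelength x condition)")
        if self.intensities.shape != (self.wavelengths_nm.size, len(self.conditions)):
            raise ValueError("grid dimensions inconsistent with axes")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensity grid has missing/non-finite cells")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def column(self, j: int) -> EmissionSpectrum:
        t, is_mM = self.conditions[j]
        return EmissionSpectrum(self.wavelengths_nm,
                                np.clip(self.intensities[:, j], 0.0, None),
                                temperature_C=t, ionic_strength_mM=is_mM)


@dataclass
class DecayTrace:
    """TCSPC histogram and its instrument response on a shared uniform grid."""

    time_ns: np.ndarray
    counts: np.ndarray
    irf_counts: np.ndarray

    def __post_init__(self):
        self.time_ns = _as_float_array(self.time_ns)
        self.counts = np.asarray(self.counts)
        self.irf_counts = np.asarray(self.irf_counts)
        for arr, name in ((self.counts, "counts"), (self.irf_counts, "irf_counts")):
            if arr.shape != self.time_ns.shape:
                raise ValueError(f"{name} length differs from the time axis")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"{name} must be integers")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
        self.counts = self.counts.astype(np.int64)
        self.irf_counts = self.irf_counts.astype(np.int64)
        dt = np.diff(self.time_ns)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-8):
            raise ValueError("time bins must be uniform")
        if self.counts.max(initial=0) <= 0:
            raise ValueError("peak count must be positive")

    @property
    def bin_width_ns(self) -> float:
        return float(self.time_ns[1] - self.time_ns[0])


@dataclass
class MeltCurve:
    """Thermal unfolding curve: signal (MRE or normalized amplitude) vs T."""

    temperatures_C: np.ndarray
    signal: np.ndarray
    probe_label: str = ""

    def __post_init__(self):
        self.temperatures_C = _as_float_array(self.temperatures_C)
        self.signal = _as_float_array(self.signal)
        if self.temperatures_C.size != self.signal.size:
            raise ValueError("temperature and signal arrays differ in length")
        if self.temperatures_C.size < 8:
            raise ValueError("need at least 8 points in a melt curve")
        if not np.all(np.diff(self.temperatures_C) > 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class Thermogram:
    """DSC thermogram in molar apparent heat capacity units (kJ/mol/K)."""

    temperatures_C: np.ndarray
    cp_kJ_mol_K: np.ndarray
    protein_conc_uM: float = 60.0
    mw_g_mol: float = 9000.0
    v_bar_mL_g: float = 0.73

    def __post_init__(self):
        self.temperatures_C = _as_float_array(self.temperatures_C)
        self.cp_kJ_mol_K = _as_float_array(self.cp_kJ_mol_K)
        if self.temperatures_C.size != self.cp_kJ_mol_K.size:
            raise ValueError("temperature and Cp arrays differ in length")
        if not self.protein_conc_uM > 0:
            raise ValueError("protein concentration must be positive")
        if not self.mw_g_mol > 0:
            raise ValueError("molecular weight must be positive")

    @classmethod
    def from_raw(cls, temperatures_C, raw_cp_kJ_K, protein_conc_uM,
                 cell_volume_mL, mw_g_mol, v_bar_mL_g=0.73) -> "Thermogram":
        """Convert a raw per-cell signal (kJ/K) to molar units.

        Moles of protein in the cell: conc[uM] * 1e-6 mol/L * V[mL] * 1e-3 L.
        """
        n_mol = protein_conc_uM * 1e-6 * cell_volume_mL * 1e-3
        return cls(temperatures_C, np.asarray(raw_cp_kJ_K, float) / n_mol,
                   protein_conc_uM=protein_conc_uM, mw_g_mol=mw_g_mol,
                   v_bar_mL_g=v_bar_mL_g)


@dataclass
class BindingIsotherm:
    """Titration of receptor (Cnu) with titrant (H-NS): signal vs total titrant."""

    titrant_total_uM: np.ndarray
    signal: np.ndarray
    receptor_total_uM: float = 2.0
    temperature_C: float = 25.0
    ionic_strength_mM: float = 170.0

    def __post_init__(self):
        self.titrant_total_uM = _as_float_array(self.titrant_total_uM)
        self.signal = _as_float_array(self.signal)
        if self.titrant_total_uM.size != self.signal.size:
            raise ValueError("titrant and signal arrays differ in length")
        if self.titrant_total_uM.size < 6:
            raise ValueError("need at least 6 titration points")
        if not np.all(np.diff(self.titrant_total_uM) > 0):
            raise ValueError("titrant totals must be strictly increasing")
        if np.any(self.titrant_total_uM <= 0) or self.receptor_total_uM <= 0:
            raise ValueError("concentrations must be positive")


@dataclass
class AnisotropyTitration:
    """Self-association titration: steady-state anisotropy vs added titrant."""

    titrant_total_uM: np.ndarray
    anisotropy: np.ndarray
    tracer_uM: float = 2.0
    temperature_C: float = 25.0
    ionic_strength_mM: float = 170.0

    def __post_init__(self):
        self.titrant_total_uM = _as_float_array(self.titrant_total_uM)
        self.anisotropy = _as_float_array(self.anisotropy)
        if self.titrant_total_uM.size != self.anisotropy.size:
            raise ValueError("titrant and anisotropy arrays differ in length")
        if np.any(self.titrant_total_uM < 0) or self.tracer_uM <= 0:
            raise ValueError("concentrations must be non-negative (tracer > 0)")


@dataclass
class Ensemble:
    """A conformational ensemble: members share one residue labeling.

    ``members`` is a list of (n_residues, 3) Calpha coordinate arrays in
    Angstrom; ``labels`` is a list of (residue_index, residue_name).
    """

    members: list
    labels: list

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble must contain at least one member")
        n = len(self.labels)
        clean = []
        for m in self.members:
            a = np.asarray(m, dtype=float)
            if a.shape != (n, 3):
                raise ValueError("all members must share the residue labeling")
            if not np.all(np.isfinite(a)):
                raise ValueError("coordinates must be finite")
            clean.append(a)
        self.members = clean

    def index_of(self, residue_index: int) -> int:
        for i, (idx, _name) in enumerate(self.labels):
            if idx == residue_index:
                return i
        raise KeyError(f"residue {residue_index} not in ensemble labeling")
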