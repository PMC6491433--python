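"""Screened charge-charge energetics of a protein versus ionic strength.

The screening model is a Debye-Huckel screened Coulomb sum over point
charges placed on side-chain reference atoms, with a uniform solvent
dielectric:

    E = sum_{i<j} 332.0 q_i q_j exp(-kappa r_ij) / (eps r_ij)   [kcal/mol]

This is a deliberately reduced surrogate for cavity-dielectric
(Tanford-Kirkwood-style) treatments: it keeps the dominant ionic-strength
dependence (the Debye kappa) and drops the boundary-dielectric multipole
machinery, and is labeled as such in its outputs. Per-residue rows with
net unfavorable (positive) energy at the reference ionic strength are
flagged as electrostatically frustrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Avogadro, Boltzmann, elementary_charge, epsilon_0
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "ChargeSite",
    "ChargeSet",
    "ElectrostaticProfile",
    "DEFAULT_PKA",
    "assign_charges",
    "henderson_hasselbalch_charge",
    "debye_kappa",
    "screened_energy",
    "is_scan",
]

COULOMB_KCAL = 332.0  # e^2/(4 pi eps0), kcal*Angstrom/mol/e^2

# default intrinsic pKa values; overridable per call
DEFAULT_PKA = {
    "ASP": 4.0, "GLU": 4.4, "HIS": 6.3, "CYS": 8.3, "TYR": 9.6,
    "LYS": 10.4, "ARG": 12.0, "NTERM": 7.5, "CTERM": 3.8,
}

_ACIDIC = {"ASP", "GLU", "CYS", "TYR", "CTERM"}
_BASIC = {"HIS", "LYS", "ARG", "NTERM"}

# side-chain reference atom carrying the point charge
_REFERENCE_ATOM = {
    "ASP": "CG", "GLU": "CD", "HIS": "NE2", "CYS": "SG", "TYR": "OH",
    "LYS": "NZ", "ARG": "CZ",
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class ChargeSite:
    residue_index: int
    residue_name: str
    coord_A: tuple
    charge_e: float

    def __post_init__(self):
        if not -1.0 <= self.charge_e <= 1.0:
            raise ValueError("per-site charges must lie in [-1, +1] e")
        if not np.all(np.isfinite(self.coord_A)):
            raise ValueError("coordinates must be finite")


@dataclass
class ChargeSet:
    """Point charges on a structure at a given pH."""

    sites: list
    pH: float = 8.0
    pKa_table: dict = field(default_factory=lambda: dict(DEFAULT_PKA))
    temperature_C: float = 25.0

    def coords(self) -> np.ndarray:
        return np.array([s.coord_A for s in self.sites], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([s.charge_e for s in self.sites], dtype=float)

    def net_charge(self) -> float:
        return float(self.charges().sum())


@dataclass
class ElectrostaticProfile:
    """Screened interaction energies over an ionic-strength scan."""

    ionic_strengths_mM: np.ndarray
    debye_kappa_invA: np.ndarray
    total_kcal_mol: np.ndarray
    per_residue_kcal_mol: np.ndarray  # residue x IS
    residue_indices: list
    frustrated: np.ndarray  # boolean per residue at the reference IS
    reference_is_mM: float
    model_label: str = ("screened-Coulomb surrogate (uniform dielectric, "
                        "Debye screening)")

    def __post_init__(self):
        if np.any(np.diff(self.debye_kappa_invA) <= 0):
            raise ValueError("kappa must increase strictly with ionic strength")
        if not np.all(np.isfinite(self.total_kcal_mol)):
            raise ValueError("energies must be finite")


def henderson_hasselbalch_charge(residue_name: str, pH: float,
                                 pKa: float) -> float:
    """Fractional charge of an ionizable group at the given pH."""
    name = residue_name.upper()
    if name in _ACIDIC:
        return -1.0 / (1.0 + 10.0 ** (pKa - pH))
    if name in _BASIC:
        return 1.0 / (1.0 + 10.0 ** (pH - pKa))
    return 0.0


def assign_charges(residues, pH: float = 8.0, pKa_table: dict = None,
                   temperature_C: float = 25.0,
                   include_termini: bool = True) -> ChargeSet:
    """Build a charge set from parsed residues.

    ``residues`` is a sequence of (residue_index, residue_name, atoms)
    with ``atoms`` a mapping atom_name -> (x, y, z) in Angstrom (the
    structure returned by :func:`osmoswitch.io.read_pdb`). One point
    charge per ionizable group is placed on the side-chain reference atom
    (falling back to CA with a warning when it is absent); chain termini
    are included as NTERM/CTERM groups on the backbone N and C atoms.
    Fractional charges follow Henderson-Hasselbalch at the given pH.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    table = dict(DEFAULT_PKA)
    if pKa_table:
        table.update({k.upper(): v for k, v in pKa_table.items()})

    residues = list(residues)
    unknown = sorted({name.upper() for _, name, _ in residues}
                     - _STANDARD_AA)
    if unknown:
        raise ValueError(f"unknown residue types: {', '.join(unknown)}")

    sites = []

    def _place(idx, name, atoms, group, ref_atom):
        q = henderson_hasselbalch_charge(group, pH, table[group])
        if abs(q) < 1e-12:
            return
        if ref_atom in atoms:
            xyz = atoms[ref_atom]
        elif "CA" in atoms:
            warnings.warn(f"residue {idx} {name}: reference atom {ref_atom} "
                          "missing, using CA")
            xyz = atoms["CA"]
        else:
            raise ValueError(f"residue {idx} {name}: no reference atom or CA")
        sites.append(ChargeSite(idx, name, tuple(float(c) for c in xyz), q))

    for idx, name, atoms in residues:
        name = name.upper()
        if name in _REFERENCE_ATOM:
            _place(idx, name, atoms, name, _REFERENCE_ATOM[name])
    if include_termini and residues:
        idx, name, atoms = residues[0]
        _place(idx, name.upper(), atoms, "NTERM", "N")
        idx, name, atoms = residues[-1]
        _place(idx, name.upper(), atoms, "CTERM",
               "OXT" if "OXT" in atoms else "C")

    return ChargeSet(sites=sites, pH=pH, pKa_table=table,
                     temperature_C=temperature_C)


def debye_kappa(ionic_strength_mM: float, temperature_C: float = 25.0,
                dielectric: float = 78.5) -> float:
    """Inverse Debye length in 1/Angstrom.

    kappa^2 = 2 N_A e^2 I / (eps eps0 kB T) with I in mol/m^3; at 25 C and
    eps = 78.5 this reproduces the familiar kappa^-1 ~ 0.304/sqrt(I[M]) nm.
    """
    if not ionic_strength_mM > 0:
        raise ValueError("ionic strength must be positive")
    T = temperature_C + 273.15
    I_mol_m3 = ionic_strength_mM  # mM == mol/m^3
    kappa_sq_m = (2.0 * Avogadro * elementary_charge ** 2 * I_mol_m3 /
                  (dielectric * epsilon_0 * Boltzmann * T))
    return float(np.sqrt(kappa_sq_m) * 1e-10)  # 1/m -> 1/Angstrom


def screened_energy(charges: ChargeSet, kappa_invA: float,
                    dielectric: float = 78.5) -> tuple:
    """Total screened Coulomb energy (kcal/mol) and the per-pair matrix.

    Pairs closer than 2 Angstrom are excluded with a warning; overlapping
    sites (< 0.1 A) raise. The pair matrix is symmetric with zero
    diagonal; the total is half its sum.
    """
    q = charges.charges()
    if q.size < 2:
        return 0.0, np.zeros((q.size, q.size))
    xyz = charges.coords()
    r = squareform(pdist(xyz))
    iu = np.triu_indices(q.size, 1)
    if np.any(r[iu] < 0.1):
        raise ValueError("overlapping charge sites (r < 0.1 A)")
    if np.any(r[iu] < 2.0):
        warnings.warn("pairs closer than 2 A excluded from the energy sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = COULOMB_KCAL * np.outer(q, q) * np.exp(-kappa_invA * r) / (dielectric * r)
    e[~np.isfinite(e)] = 0.0
    np.fill_diagonal(e, 0.0)
    e[r < 2.0] = 0.0
    np.fill_diagonal(e, 0.0)
    return float(e[iu].sum()), e


def is_scan(charges: ChargeSet, ionic_strengths_mM,
            dielectric: float = 78.5, reference_is_mM: float = None
            ) -> ElectrostaticProfile:
    """Scan the screened energetics over ionic strength.

    Per-residue energies are half-sums of the pair terms touching each
    residue (so they add up to the total). Residues whose net energy is
    positive at the reference ionic strength (lowest scanned, unless
    given) are flagged frustrated.
    """
    is_arr = np.sort(np.asarray(ionic_strengths_mM, dtype=float))
    if is_arr.size == 0:
        raise ValueError("empty ionic strength list")
    res_idx = sorted({s.residue_index for s in charges.sites})
    site_res = np.array([res_idx.index(s.residue_index) for s in charges.sites])

    kappas = np.array([debye_kappa(i, charges.temperature_C, dielectric)
                       for i in is_arr])
    totals = np.empty(is_arr.size)
    per_res = np.zeros((len(res_idx), is_arr.size))
    for j, kap in enumerate(kappas):
        total, pair = screened_energy(charges, kap, dielectric)
        totals[j] = total
        half = 0.5 * pair.sum(axis=1)
        for s_i, r_i in enumerate(site_res):
            per_res[r_i, j] += half[s_i]

    ref = float(is_arr[0]) if reference_is_mM is None else float(reference_is_mM)
    j_ref = int(np.argmin(np.abs(is_arr - ref)))
    frustrated = per_res[:, j_ref] > 0

    return ElectrostaticProfile(ionic_strengths_mM=is_arr,
                                debye_kappa_invA=kappas,
                                total_kcal_mol=totals,
                                per_residue_kcal_mol=per_res,
                                residue_indices=res_idx,
                                frustrated=frustrated,
                                reference_is_mM=float(is_arr[j_ref]))
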