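"""Readers and writers for the tabular spectroscopy formats and PDB.

All tabular files are comma-separated with one header line; units are in
the column names (wavelength_nm, temp_C, time_ns, titrant_uM, ...). The
spectra-matrix format has a first ``wavelength_nm`` column and one column
per condition labeled ``T<celsius>_IS<mM>``. PDB coordinates are parsed
with Bio.PDB into the light residue structure the electrostatics module
consumes: a list of (residue_index, residue_name, {atom_name: xyz}).
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from .datatypes import (AnisotropyTitration, BindingIsotherm, DecayTrace,
                        EmissionSpectrum, MeltCurve, SpectraMatrix,
                        Thermogram)

__all__ = [
    "read_spectrum", "write_spectrum",
    "read_spectra_matrix", "write_spectra_matrix",
    "read_melt", "write_melt",
    "read_thermogram", "write_thermogram",
    "read_decay", "write_decay",
    "read_isotherm", "write_isotherm",
    "read_anisotropy", "write_anisotropy",
    "read_pdb", "write_pdb",
]

_COND_RE = re.compile(r"^T(?P<t>-?[0-9.]+)_IS(?P<is>[0-9.]+)$")


def _read_csv(path, required):
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_spectrum(path, **meta) -> EmissionSpectrum:
    df = _read_csv(path, ["wavelength_nm", "intensity"])
    return EmissionSpectrum(df["wavelength_nm"].to_numpy(),
                            df["intensity"].to_numpy(), **meta)


def write_spectrum(spec: EmissionSpectrum, path):
    pd.DataFrame({"wavelength_nm": spec.wavelengths_nm,
                  "intensity": spec.intensities}).to_csv(path, index=False)


def read_spectra_matrix(path) -> SpectraMatrix:
    df = _read_csv(path, ["wavelength_nm"])
    conditions, cols = [], []
    for c in df.columns[1:]:
        m = _COND_RE.match(c)
        if not m:
            raise ValueError(f"condition column {c!r} not of the form T<C>_IS<mM>")
        conditions.append((float(m.group("t")), float(m.group("is"))))
        cols.append(c)
    return SpectraMatrix(df["wavelength_nm"].to_numpy(), conditions,
                         df[cols].to_numpy())


def write_spectra_matrix(matrix: SpectraMatrix, path):
    data = {"wavelength_nm": matrix.wavelengths_nm}
    for j, (t, is_mM) in enumerate(matrix.conditions):
        data[f"T{t:g}_IS{is_mM:g}"] = matrix.intensities[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_melt(path, probe_label="") -> MeltCurve:
    df = _read_csv(path, ["temp_C", "signal_MRE"])
    return MeltCurve(df["temp_C"].to_numpy(), df["signal_MRE"].to_numpy(),
                     probe_label=probe_label)


def write_melt(curve: MeltCurve, path):
    pd.DataFrame({"temp_C": curve.temperatures_C,
                  "signal_MRE": curve.signal}).to_csv(path, index=False)


def read_thermogram(path, **meta) -> Thermogram:
    df = _read_csv(path, ["temp_C", "cp_kJ_mol_K"])
    return Thermogram(df["temp_C"].to_numpy(), df["cp_kJ_mol_K"].to_numpy(),
                      **meta)


def write_thermogram(tg: Thermogram, path):
    pd.DataFrame({"temp_C": tg.temperatures_C,
                  "cp_kJ_mol_K": tg.cp_kJ_mol_K}).to_csv(path, index=False)


def read_decay(path) -> DecayTrace:
    df = _read_csv(path, ["time_ns", "counts", "irf_counts"])
    return DecayTrace(df["time_ns"].to_numpy(),
                      df["counts"].to_numpy(),
                      df["irf_counts"].to_numpy())


def write_decay(trace: DecayTrace, path):
    pd.DataFrame({"time_ns": trace.time_ns, "counts": trace.counts,
                  "irf_counts": trace.irf_counts}).to_csv(path, index=False)


def read_isotherm(path, **meta) -> BindingIsotherm:
    df = _read_csv(path, ["titrant_uM", "signal"])
    return BindingIsotherm(df["titrant_uM"].to_numpy(),
                           df["signal"].to_numpy(), **meta)


def write_isotherm(iso: BindingIsotherm, path):
    pd.DataFrame({"titrant_uM": iso.titrant_total_uM,
                  "signal": iso.signal}).to_csv(path, index=False)


def read_anisotropy(path, **meta) -> AnisotropyTitration:
    df = _read_csv(path, ["titrant_uM", "anisotropy"])
    return AnisotropyTitration(df["titrant_uM"].to_numpy(),
                               df["anisotropy"].to_numpy(), **meta)


def write_anisotropy(tit: AnisotropyTitration, path):
    pd.DataFrame({"titrant_uM": tit.titrant_total_uM,
                  "anisotropy": tit.anisotropy}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PDB

def read_pdb(path, model: int = 0, chain: str = None) -> list:
    """Parse a PDB file into [(residue_index, residue_name, {atom: xyz})].

    Residue numbering is taken from the file (1-based as deposited);
    coordinates are in Angstrom as stored. Waters and heteroatoms are
    skipped.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", path)
    mdl = list(structure)[model]
    residues = []
    for ch in mdl:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            hetflag, resseq, _icode = res.id
            if hetflag.strip():
                continue
            atoms = {a.get_name(): tuple(float(x) for x in a.coord)
                     for a in res}
            residues.append((int(resseq), res.get_resname(), atoms))
    return residues


def write_pdb(labels, coords, path, chain_id: str = "A"):
    """Write a Calpha-only PDB trace.

    ``labels`` is [(residue_index, residue_name)] and ``coords`` the
    matching (n, 3) array in Angstrom. Good enough for round-tripping toy
    ensembles through standard structure tools.
    """
    coords = np.asarray(coords, dtype=float)
    lines = []
    for serial, ((idx, name), (x, y, z)) in enumerate(zip(labels, coords), 1):
        lines.append(
            f"ATOM  {serial:5d}  CA  {name:>3s} {chain_id}{idx:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" C  ")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
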