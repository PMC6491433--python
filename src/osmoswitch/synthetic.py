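"""Seeded generators for every input type the analysis chain consumes.

Each generator emulates the statistical structure the corresponding
analysis assumes — two-basis emission grids with anti-correlated Tyr/Trp
bands near 305/350 nm, Poisson-noise TCSPC decays under a Gaussian IRF,
two-state melts and thermograms, Hill/coupled-equilibrium titrations with
the high-titrant roll-over, monomer-dimer anisotropy curves, and toy
four-helix-bundle coordinate ensembles. Analog signals carry Gaussian
noise; photon counts carry Poisson noise. Identical (parameters, seed)
reproduce identical output bit for bit.
"""

from __future__ import annotations

import warnings

import numpy as np

from .binding import EquilibriumModel, dimer_anisotropy, solve_titration, hill_signal
from .datatypes import (AnisotropyTitration, BindingIsotherm, DecayTrace,
                        Ensemble, FixtureConfig, MeltCurve, SpectraMatrix,
                        Thermogram)
from .melt import excess_heat_capacity, folded_fraction, two_state_signal

__all__ = [
    "simulate_emission_matrix",
    "simulate_decay",
    "simulate_isotherm",
    "simulate_hill_isotherm",
    "simulate_melt",
    "simulate_thermogram",
    "simulate_anisotropy_titration",
    "make_toy_bundle_ensemble",
    "default_titrant_grid",
    "TOY_BUNDLE_SEGMENTS",
]

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def default_titrant_grid(n_points: int = 30, lo_uM: float = 0.03,
                         hi_uM: float = 140.0) -> np.ndarray:
    """Log-spaced titrant grid matching the recorded 30 nM - 140 uM range."""
    return np.geomspace(lo_uM, hi_uM, n_points)


# ---------------------------------------------------------------------------
# Emission spectra grids

def _gaussian_band(wavelengths_nm, center_nm, width_nm):
    # Gaussian in wavenumber; width given on the wavelength scale at center
    nu = 1e7 / np.asarray(wavelengths_nm, dtype=float)
    nu0 = 1e7 / center_nm
    sigma_nu = 1e7 * width_nm / center_nm ** 2
    return np.exp(-0.5 * ((nu - nu0) / sigma_nu) ** 2)


def emission_bases(wavelengths_nm, band_y_nm=305.0, band_w_nm=350.0,
                   width_nm=22.0):
    """Average-spectrum basis B1 and Tyr/Trp difference basis B2.

    B2 is negative near the tyrosine band and positive near the tryptophan
    band; both are unit-normalized.
    """
    gy = _gaussian_band(wavelengths_nm, band_y_nm, width_nm)
    gw = _gaussian_band(wavelengths_nm, band_w_nm, width_nm * 1.4)
    b1 = 0.45 * gy + 1.0 * gw
    b1 = b1 / np.linalg.norm(b1)
    b2 = gw - gy
    b2 = b2 - (b2 @ b1) * b1  # orthogonalize so SVD recovers the trajectories
    return b1, b2 / np.linalg.norm(b2)


def simulate_emission_matrix(config: FixtureConfig, temperatures,
                             wavelengths_nm=None) -> SpectraMatrix:
    """Two-basis emission grid over temperature for one condition.

    Columns are a1(T)*B1 + a2(T)*B2 + Gaussian noise, with the amplitude
    trajectories linear between the configured cold/hot endpoints
    (``emission.a1_cold`` .. ``emission.u2_hot`` in the condition's model
    parameters). Noiseless output with two independent trajectories has
    numerical rank exactly 2.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size < 2:
        raise ValueError("need at least 2 temperatures")
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(285.0, 421.0, 1.0)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if np.any(np.diff(wavelengths_nm) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    em = config.model_params.get("emission", {})
    sigma = float(em.get("noise_sigma", 0.0))
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")

    b1, b2 = emission_bases(wavelengths_nm,
                            em.get("band_y_nm", 305.0),
                            em.get("band_w_nm", 350.0),
                            em.get("band_width_nm", 22.0))
    t_lo, t_hi = temperatures.min(), temperatures.max()
    frac = (temperatures - t_lo) / max(t_hi - t_lo, 1e-12)
    a1 = em.get("a1_cold", 1.0) + (em.get("a1_hot", 0.6) - em.get("a1_cold", 1.0)) * frac
    a2 = em.get("u2_cold", 0.0) + (em.get("u2_hot", 0.0) - em.get("u2_cold", 0.0)) * frac

    grid = np.outer(b1, a1) + np.outer(b2, a2)
    if sigma > 0:
        rng = np.random.default_rng(config.seed)
        grid = grid + rng.normal(0.0, sigma, size=grid.shape)
    conditions = [(float(t), config.ionic_strength_mM) for t in temperatures]
    return SpectraMatrix(wavelengths_nm, conditions, grid)


# ---------------------------------------------------------------------------
# TCSPC decays

def simulate_decay(tau_ns, alpha, irf_fwhm_ns: float, peak_count: int,
                   seed: int = 0, n_bins: int = 4096, t_max_ns: float = 50.0,
                   irf_center_ns: float = None, poisson: bool = True
                   ) -> DecayTrace:
    """Poisson-noise TCSPC histogram of a multi-exponential decay.

    The expected trace is the discrete convolution of a unit-area Gaussian
    IRF (given FWHM, centered early in the window) with
    sum(alpha_i exp(-t/tau_i)), scaled so the maximum expected count equals
    ``peak_count``. The stored IRF is the noiseless rounded Gaussian.
    """
    tau = np.asarray(tau_ns, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if tau.size != a.size:
        raise ValueError("tau and alpha must have the same length")
    if np.any(tau <= 0) or irf_fwhm_ns <= 0 or peak_count <= 0:
        raise ValueError("lifetimes, IRF width, and peak count must be positive")
    if abs(a.sum() - 1.0) > 1e-9:
        raise ValueError("amplitude fractions must sum to 1")

    dt = t_max_ns / n_bins
    t = (np.arange(n_bins) + 0.5) * dt
    sigma = irf_fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t0 = irf_center_ns if irf_center_ns is not None else max(1.0, 5.0 * sigma)
    irf = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    if irf.sum() <= 0:
        raise ValueError("IRF underflows the time grid; widen irf_fwhm_ns "
                         "or refine the binning")
    irf_norm = irf / irf.sum()

    decay = np.zeros_like(t)
    for ti, ai in zip(tau, a):
        decay += ai * np.exp(-t / ti)
    expected = np.convolve(irf_norm, decay)[:n_bins]
    expected *= peak_count / expected.max()

    if poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected)
    else:
        counts = np.round(expected).astype(np.int64)
    irf_counts = np.round(irf / irf.max() * peak_count).astype(np.int64)
    return DecayTrace(t, counts, irf_counts)


# ---------------------------------------------------------------------------
# Binding titrations

def simulate_isotherm(model: EquilibriumModel, totals_uM,
                      per_species_signal: dict = None,
                      noise_sigma: float = 0.0, seed: int = 0,
                      receptor_uM: float = 2.0) -> BindingIsotherm:
    """Titration isotherm of a declared species mixture.

    The per-point signal is the intensity-weighted mean of per-species
    signals (brightness x concentration weights); ``per_species_signal``
    entries (``signal`` or ``(signal, brightness)``) override the model's.
    Noiseless output is deterministic.
    """
    totals = np.asarray(totals_uM, dtype=float)
    if np.any(np.diff(totals) <= 0):
        raise ValueError("titrant totals must be strictly increasing")
    if totals[-1] / totals[0] < 100:
        warnings.warn("titrant grid spans fewer than 2 decades")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")

    if per_species_signal:
        new_species = []
        free_signal = dict(model.free_signal)
        free_brightness = dict(model.free_brightness)
        for sp in model.species:
            if sp.name in per_species_signal:
                v = per_species_signal[sp.name]
                sig, br = v if isinstance(v, tuple) else (v, 1.0)
                sp = type(sp)(sp.name, sp.stoichiometry, sp.beta, sig, br)
            new_species.append(sp)
        for comp in ("Cnu", "H"):
            if comp in per_species_signal:
                v = per_species_signal[comp]
                sig, br = v if isinstance(v, tuple) else (v, 1.0)
                free_signal[comp] = sig
                free_brightness[comp] = br
        model = EquilibriumModel(new_species, free_signal, free_brightness)

    signals, _ = solve_titration(model, receptor_uM, totals)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signals = signals + rng.normal(0.0, noise_sigma, size=signals.size)
    return BindingIsotherm(totals, signals, receptor_total_uM=receptor_uM)


def simulate_hill_isotherm(config: FixtureConfig, titrant_uM=None,
                           receptor_uM: float = 2.0, noise_sigma: float = 0.0,
                           seed: int = None) -> BindingIsotherm:
    """Noisy or noiseless Hill-equation isotherm for a packaged condition.

    Reads ``hill.K_half_uM``, ``hill.n_H``, ``hill.signal_free`` and
    ``hill.signal_bound`` from the condition's model parameters.
    """
    if titrant_uM is None:
        titrant_uM = default_titrant_grid()
    titrant_uM = np.asarray(titrant_uM, dtype=float)
    s = hill_signal(titrant_uM,
                    config.param("hill", "K_half_uM"),
                    config.param("hill", "n_H"),
                    config.param("hill", "signal_free", default=28.4),
                    config.param("hill", "signal_bound", default=29.2))
    if noise_sigma > 0:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        s = s + rng.normal(0.0, noise_sigma, size=s.size)
    return BindingIsotherm(titrant_uM, s, receptor_total_uM=receptor_uM,
                           temperature_C=config.temperature_C,
                           ionic_strength_mM=config.ionic_strength_mM)


# ---------------------------------------------------------------------------
# Melts and thermograms

def simulate_melt(Tm_C: float, dHm_kJ_mol: float, temperatures_C,
                  dCp_kJ_mol_K: float = 0.0,
                  baselines=(-12000.0, 20.0, -2000.0, 5.0),
                  noise_sigma: float = 0.0, seed: int = 0,
                  probe_label: str = "far-UV CD") -> MeltCurve:
    """Two-state melt with population-weighted linear baselines.

    ``baselines`` is (aN, bN, aU, bU): folded/unfolded intercepts and
    slopes in signal units. Warns when Tm falls outside the scanned range
    (the fit will be unconstrained).
    """
    temps = np.asarray(temperatures_C, dtype=float)
    if not dHm_kJ_mol > 0:
        raise ValueError("dHm must be positive")
    if not temps[0] < Tm_C < temps[-1]:
        warnings.warn("Tm outside the scanned temperature range: "
                      "fits will be unconstrained")
    s = two_state_signal(temps, Tm_C, dHm_kJ_mol, dCp_kJ_mol_K, *baselines)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, noise_sigma, size=s.size)
    return MeltCurve(temps, s, probe_label=probe_label)


def simulate_thermogram(Tm_C: float, dHm_kJ_mol: float, temperatures_C,
                        dCp_kJ_mol_K: float = 0.0,
                        baselines=(10.0, 0.05, 12.0, 0.05),
                        noise_sigma: float = 0.0, seed: int = 0,
                        protein_conc_uM: float = 60.0,
                        mw_g_mol: float = 9000.0) -> Thermogram:
    """Apparent molar DSC thermogram: two-state excess Cp on population-
    weighted linear baselines (kJ/mol/K)."""
    temps = np.asarray(temperatures_C, dtype=float)
    if not dHm_kJ_mol > 0:
        raise ValueError("dHm must be positive")
    fN = folded_fraction(temps, Tm_C, dHm_kJ_mol, dCp_kJ_mol_K)
    aN, bN, aU, bU = baselines
    base = fN * (aN + bN * temps) + (1 - fN) * (aU + bU * temps)
    cp = base + excess_heat_capacity(temps, Tm_C, dHm_kJ_mol, dCp_kJ_mol_K)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        cp = cp + rng.normal(0.0, noise_sigma, size=cp.size)
    return Thermogram(temps, cp, protein_conc_uM=protein_conc_uM,
                      mw_g_mol=mw_g_mol)


# ---------------------------------------------------------------------------
# Anisotropy self-titrations

def simulate_anisotropy_titration(K_D_uM: float, r_mono: float, r_oligo: float,
                                  tracer_uM: float = 2.0, titrant_uM=None,
                                  noise_sigma: float = 0.0, seed: int = 0
                                  ) -> AnisotropyTitration:
    """Monomer-dimer anisotropy curve over total protomer tracer+titrant.

    ``K_D_uM`` may be ``numpy.inf`` for the no-association (flat) limit.
    """
    if not (0.0 < r_mono < r_oligo < 0.4):
        raise ValueError("require 0 < r_mono < r_oligo < 0.4")
    if titrant_uM is None:
        titrant_uM = default_titrant_grid()
    titrant_uM = np.asarray(titrant_uM, dtype=float)
    if np.any(titrant_uM < 0) or tracer_uM <= 0:
        raise ValueError("concentrations must be non-negative (tracer > 0)")
    if tracer_uM > 0.1 * titrant_uM.max():
        warnings.warn("tracer not small compared with the titrant range")
    total = tracer_uM + titrant_uM
    if np.isinf(K_D_uM):
        r = np.full(total.size, r_mono)
    else:
        r = dimer_anisotropy(total, K_D_uM, r_mono, r_oligo)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sigma, size=r.size)
    return AnisotropyTitration(titrant_uM, r, tracer_uM=tracer_uM)


# ---------------------------------------------------------------------------
# Toy four-helix bundle ensembles

# helix residue ranges (1-based, inclusive); everything else is loop/tail
TOY_BUNDLE_SEGMENTS = {
    "H1": (4, 15), "H2": (20, 31), "H3": (35, 46), "H4": (58, 69),
}
_N_RESIDUES = 71
_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TWIST = np.deg2rad(100.0)
# xy positions of the four helix axes in the bundle, alternating direction
_AXIS_XY = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]


def _toy_sequence() -> str:
    """Synthetic 71-residue sequence for the toy bundle (invented; carries
    the Tyr40/Trp67/Tyr69 probe layout and a mix of charged residues)."""
    base = "MAEKLDEIRKALEEGKIDVKELAERLGLSESEVNRVLKEYAEKHGDLAEFEKKLSEDPRLAEKVKEWLYK"
    seq = list(base[:_N_RESIDUES].ljust(_N_RESIDUES, "A"))
    seq[39] = "Y"  # Tyr40, third helix
    seq[66] = "W"  # Trp67, fourth helix
    seq[68] = "Y"  # Tyr69, fourth helix
    return "".join(seq)


def toy_bundle_reference() -> np.ndarray:
    """Idealized Calpha trace of the four-helix bundle (A)."""
    coords = np.zeros((_N_RESIDUES, 3))
    for h, (name, (lo, hi)) in enumerate(TOY_BUNDLE_SEGMENTS.items()):
        n = hi - lo + 1
        j = np.arange(n)
        up = 1.0 if h % 2 == 0 else -1.0
        x0, y0 = _AXIS_XY[h]
        z = up * j * _HELIX_RISE
        if up < 0:
            z = z + (n - 1) * _HELIX_RISE  # start at the top, run down
        coords[lo - 1:hi, 0] = x0 + _HELIX_RADIUS * np.cos(j * _HELIX_TWIST)
        coords[lo - 1:hi, 1] = y0 + _HELIX_RADIUS * np.sin(j * _HELIX_TWIST)
        coords[lo - 1:hi, 2] = z
    # loops/tails: linear interpolation between flanking helix ends
    helix_bounds = sorted((lo - 1, hi - 1) for lo, hi in TOY_BUNDLE_SEGMENTS.values())
    in_helix = np.zeros(_N_RESIDUES, dtype=bool)
    for lo, hi in helix_bounds:
        in_helix[lo:hi + 1] = True
    i = 0
    while i < _N_RESIDUES:
        if not in_helix[i]:
            j = i
            while j < _N_RESIDUES and not in_helix[j]:
                j += 1
            left = coords[i - 1] if i > 0 else coords[j] + np.array([-4.0, -4.0, 0.0])
            right = coords[j] if j < _N_RESIDUES else coords[i - 1] + np.array([4.0, 4.0, 0.0])
            n = j - i
            for k in range(n):
                f = (k + 1) / (n + 1)
                bow = np.array([0.0, 0.0, 2.5 * np.sin(np.pi * f)])
                coords[i + k] = (1 - f) * left + f * right + bow
            i = j
        else:
            i += 1
    return coords


def segment_of_residue(residue_index: int) -> str:
    """Segment label (H1..H4 or 'loop') for a 1-based residue index."""
    for name, (lo, hi) in TOY_BUNDLE_SEGMENTS.items():
        if lo <= residue_index <= hi:
            return name
    return "loop"


def make_toy_bundle_ensemble(n_members: int, disorder=0.0,
                             seed: int = 0, step_A: float = 0.8) -> Ensemble:
    """Toy ensemble standing in for simulation snapshots.

    ``disorder`` is either a scalar in [0, 1] applied to every segment or
    a map segment-name -> level (segments H1..H4 and 'loop'). Each member
    perturbs the idealized reference trace by a per-segment cumulative
    random walk whose amplitude scales with the segment's disorder level,
    so the same seed at growing disorder yields strictly nested spreads.
    """
    if n_members < 1:
        raise ValueError("ensemble must have at least one member")
    if np.isscalar(disorder):
        levels = {name: float(disorder) for name in
                  list(TOY_BUNDLE_SEGMENTS) + ["loop"]}
    else:
        levels = {name: 0.0 for name in list(TOY_BUNDLE_SEGMENTS) + ["loop"]}
        levels.update({k: float(v) for k, v in disorder.items()})
    for name, lvl in levels.items():
        if not 0.0 <= lvl <= 1.0:
            raise ValueError(f"disorder level for {name} outside [0, 1]")

    ref = toy_bundle_reference()
    seq = _toy_sequence()
    labels = [(i + 1, AA_1TO3[aa]) for i, aa in enumerate(seq)]
    seg_names = np.array([segment_of_residue(i + 1) for i in range(_N_RESIDUES)])
    level_arr = np.array([levels[s] for s in seg_names])

    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_members):
        eps = rng.normal(0.0, 1.0, size=(_N_RESIDUES, 3))
        walk = np.zeros_like(eps)
        start = 0
        for i in range(1, _N_RESIDUES + 1):
            if i == _N_RESIDUES or seg_names[i] != seg_names[start]:
                walk[start:i] = np.cumsum(eps[start:i], axis=0)
                start = i
        members.append(ref + step_A * level_arr[:, None] * walk)
    return Ensemble(members=members, labels=labels)
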