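"""Hill analysis and coupled hetero/homo-oligomer binding equilibria.

This module carries the machinery behind the salt-driven cooperativity
switch: Hill fits of titration isotherms (with automatic exclusion of the
high-titrant roll-over branch), a mass-action solver for an arbitrary
declared species set over the two components (Cnu and the H-NS N-terminal
domain), the apparent Hill coefficient a species mixture produces, and
monomer-dimer fitting of anisotropy self-titrations.

Conventions
-----------
* Formation (association) constants are stepwise-cumulative: a species with
  stoichiometry (a, b) over (Cnu, H) has concentration
  ``[S] = beta * [Cnu]**a * [H]**b`` with beta in uM**(1-a-b).
  Single-step dissociation constants are reported on the uM scale.
* The Hill fit uses *total* titrant as the independent variable, matching
  the operational fit of isotherms recorded at ~2 uM receptor where the
  fitted midpoints are far above the receptor concentration.
* Observed signals are intensity-weighted means over emitting species:
  ``S = sum(b_s * c_s * S_s) / sum(b_s * c_s)`` with per-species
  brightness b_s. This is how an intensity-averaged wavenumber mixes the
  species actually emitting, and it is what produces the roll-over when a
  weakly emitting homodimer accumulates at high titrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datatypes import AnisotropyTitration, BindingIsotherm

__all__ = [
    "EquilibriumModel",
    "Species",
    "SpeciesDistribution",
    "HillFit",
    "DimerFit",
    "hill_signal",
    "hill_fit",
    "detect_rollover",
    "solve_equilibria",
    "solve_titration",
    "apparent_hill_from_model",
    "monomer_fraction",
    "fit_dimer_anisotropy",
]

COMPONENTS = ("Cnu", "H")


@dataclass(frozen=True)
class Species:
    """One molecular species: name, stoichiometry over (Cnu, H), formation
    constant beta (uM**(1-a-b)), optional signal and brightness."""

    name: str
    stoichiometry: tuple  # (n_cnu, n_h)
    beta: float = 1.0
    signal: float = 0.0
    brightness: float = 0.0

    def __post_init__(self):
        a, b = self.stoichiometry
        if a < 0 or b < 0 or a + b < 1:
            raise ValueError("stoichiometry must be non-negative, at least one unit")
        if not self.beta > 0:
            raise ValueError("formation constants must be positive")
        if self.brightness < 0:
            raise ValueError("brightness must be non-negative")


@dataclass
class EquilibriumModel:
    """A declared set of complexes over the two free components.

    The two free components are implicit species with beta = 1; give them
    signals/brightness through ``free_signal`` / ``free_brightness`` maps
    keyed by component name.
    """

    species: list
    free_signal: dict = field(default_factory=dict)
    free_brightness: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        for comp in self.free_signal:
            if comp not in COMPONENTS:
                raise ValueError(f"unknown component {comp!r}")

    def all_species(self) -> list:
        """Free components followed by declared complexes."""
        out = [
            Species("Cnu", (1, 0), 1.0,
                    self.free_signal.get("Cnu", 0.0),
                    self.free_brightness.get("Cnu", 0.0)),
            Species("H", (0, 1), 1.0,
                    self.free_signal.get("H", 0.0),
                    self.free_brightness.get("H", 0.0)),
        ]
        return out + list(self.species)


@dataclass
class SpeciesDistribution:
    """Solved species concentrations (uM) at one titration point."""

    free_cnu_uM: float
    free_h_uM: float
    concentrations_uM: dict  # name -> uM, includes free components
    total_cnu_uM: float
    total_h_uM: float

    def mass_balance_residual(self, model: EquilibriumModel) -> tuple:
        """Relative closure error of the two component balances."""
        c_sum = h_sum = 0.0
        for sp in model.all_species():
            c = self.concentrations_uM[sp.name]
            c_sum += sp.stoichiometry[0] * c
            h_sum += sp.stoichiometry[1] * c
        rc = abs(c_sum - self.total_cnu_uM) / max(self.total_cnu_uM, 1e-30)
        rh = abs(h_sum - self.total_h_uM) / max(self.total_h_uM, 1e-30)
        return rc, rh


@dataclass
class HillFit:
    """Result of a Hill-equation fit to a binding isotherm."""

    K_half_uM: float
    n_H: float
    signal_free: float
    signal_bound: float
    ci68: dict = field(default_factory=dict)
    fit_range_max_uM: float = np.inf
    excluded_points: int = 0
    residual_norm: float = 0.0

    def __post_init__(self):
        if not (self.K_half_uM > 0 and self.n_H > 0):
            raise ValueError("K_half and n_H must be positive")


@dataclass
class DimerFit:
    """Monomer-dimer equilibrium fit of an anisotropy self-titration.

    K_D is the dissociation constant [M]^2/[D] in uM.
    """

    K_D_uM: float
    r_monomer: float
    r_dimer: float
    ci68: dict = field(default_factory=dict)
    residual_norm: float = 0.0

    def __post_init__(self):
        if not self.K_D_uM > 0:
            raise ValueError("K_D must be positive")
        if not self.r_monomer < self.r_dimer:
            raise ValueError("monomer anisotropy must lie below dimer anisotropy")


# ---------------------------------------------------------------------------
# Hill equation

def hill_signal(titrant_uM, K_half_uM, n_H, signal_free, signal_bound):
    """Hill binding curve evaluated at total titrant concentrations."""
    L = np.asarray(titrant_uM, dtype=float)
    occ = L ** n_H / (K_half_uM ** n_H + L ** n_H)
    return signal_free + (signal_bound - signal_free) * occ


def detect_rollover(iso: BindingIsotherm):
    """Locate the descending high-titrant branch of an isotherm.

    Returns the titrant concentration (uM) of the first point of a
    persistent (>= 2 consecutive points) movement back toward the
    free-state signal after the extremum, or None when the curve
    saturates monotonically. Single-point dips within the local noise
    are ignored.
    """
    s = iso.signal
    if s.size < 6:
        raise ValueError("need at least 6 points")
    direction = np.sign(s[-1] - s[0]) or 1.0
    # work in the binding direction so the extremum is a maximum
    y = direction * s
    i_ext = int(np.argmax(y))
    if i_ext >= s.size - 2:
        return None
    # local noise scale from successive differences on the rising branch
    rise = np.diff(y[: max(i_ext, 2) + 1])
    noise = 1.4826 * np.median(np.abs(rise - np.median(rise))) if rise.size > 2 else 0.0
    tail = y[i_ext:]
    drops = np.diff(tail) < 0
    total_drop = y[i_ext] - tail[-1]
    for k in range(drops.size - 1):
        if drops[k] and drops[k + 1] and (y[i_ext] - tail[k + 2]) > 3 * noise:
            if total_drop > 3 * noise:
                return float(iso.titrant_total_uM[i_ext + k + 1])
    return None


def hill_fit(iso: BindingIsotherm, exclude_rollover: bool = True,
             n_boot: int = 500, seed: int = 0) -> HillFit:
    """Least-squares Hill fit of a binding isotherm.

    The independent variable is total titrant (ligand-excess
    approximation, valid because the ~2 uM receptor sits far below every
    fitted midpoint). Roll-over points past the boundary found by
    :func:`detect_rollover` are excluded by default and counted in the
    returned fit. 68% confidence intervals come from a seeded residual
    bootstrap (``n_boot`` resamples; set 0 to skip).
    """
    L = iso.titrant_total_uM
    s = iso.signal
    fit_max = np.inf
    excluded = 0
    if exclude_rollover:
        boundary = detect_rollover(iso)
        if boundary is not None:
            keep = L < boundary
            excluded = int(np.sum(~keep))
            fit_max = float(boundary)
            L, s = L[keep], s[keep]
    if L.size < 6:
        raise ValueError("fewer than 6 usable points after roll-over exclusion")

    def model(p, x):
        logK, n, sf, sb = p
        return hill_signal(x, np.exp(logK), n, sf, sb)

    def resid(p, x=L, y=s):
        return model(p, x) - y

    span = s.max() - s.min()
    half = s[0] + 0.5 * (s[-1] - s[0])
    k0 = L[np.argmin(np.abs(s - half))]
    p0 = np.array([np.log(k0), 1.0, s[0], s[-1]])
    sol = least_squares(resid, p0, bounds=([np.log(L[0] * 1e-3), 0.05, -np.inf, -np.inf],
                                           [np.log(L[-1] * 1e3), 10.0, np.inf, np.inf]))
    logK, n, sf, sb = sol.x
    K = float(np.exp(logK))
    if K > L[-1]:
        warnings.warn("K poorly constrained: no saturation within the titration range")

    ci = {}
    if n_boot > 0 and span > 0:
        rng = np.random.default_rng(seed)
        r = resid(sol.x)
        yhat = model(sol.x, L)
        draws = np.empty((n_boot, 2))
        for b in range(n_boot):
            yb = yhat + rng.choice(r, size=r.size, replace=True)
            try:
                sb_ = least_squares(resid, sol.x, args=(L, yb),
                                    bounds=([np.log(L[0] * 1e-3), 0.05, -np.inf, -np.inf],
                                            [np.log(L[-1] * 1e3), 10.0, np.inf, np.inf]))
                draws[b] = np.exp(sb_.x[0]), sb_.x[1]
            except Exception:
                draws[b] = np.nan, np.nan
        lo, hi = np.nanpercentile(draws, [16, 84], axis=0)
        ci = {"K_half_uM": (float(lo[0]), float(hi[0])),
              "n_H": (float(lo[1]), float(hi[1]))}

    return HillFit(K_half_uM=K, n_H=float(n), signal_free=float(sf),
                   signal_bound=float(sb), ci68=ci, fit_range_max_uM=fit_max,
                   excluded_points=excluded,
                   residual_norm=float(np.linalg.norm(sol.fun)))


# ---------------------------------------------------------------------------
# Coupled equilibria

def _species_conc(model, c_free, h_free):
    out = {}
    for sp in model.all_species():
        a, b = sp.stoichiometry
        out[sp.name] = sp.beta * c_free ** a * h_free ** b
    return out


def solve_equilibria(model: EquilibriumModel, total_cnu_uM: float,
                     total_h_uM: float, tol: float = 1e-10,
                     max_iter: int = 200) -> SpeciesDistribution:
    """Solve the two-component mass balance by damped Newton iteration.

    Works on log free concentrations, so iterates stay positive; the
    analytic Jacobian in log space is diagonal-dominant and the damping
    (step halving on residual increase) makes convergence robust over the
    strongly cooperative fixtures. Tolerance is relative closure of both
    component balances.
    """
    if total_cnu_uM < 0 or total_h_uM < 0:
        raise ValueError("totals must be non-negative")
    totals = np.array([max(total_cnu_uM, 1e-30), max(total_h_uM, 1e-30)])
    species = model.all_species()
    stoich = np.array([sp.stoichiometry for sp in species], dtype=float)
    betas = np.array([sp.beta for sp in species])

    def balances(logx):
        conc = betas * np.exp(stoich @ logx)
        return stoich.T @ conc, conc

    logx = np.log(totals)  # start from the dilute guess: free = total
    tot, conc = balances(logx)
    res = np.log(tot / totals)
    for _ in range(max_iter):
        if np.max(np.abs(tot - totals) / totals) < tol:
            break
        # Jacobian of log-balance wrt log free concentrations
        J = (stoich.T * conc) @ stoich / tot[:, None]
        try:
            step = np.linalg.solve(J, res)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular Jacobian in equilibrium solve")
        lam = 1.0
        norm0 = np.linalg.norm(res)
        for _ in range(60):
            trial = logx - lam * step
            tot_t, conc_t = balances(trial)
            res_t = np.log(tot_t / totals)
            if np.linalg.norm(res_t) < norm0:
                break
            lam *= 0.5
        logx, tot, conc, res = trial, tot_t, conc_t, res_t
    else:
        raise RuntimeError(
            f"equilibrium solver did not converge in {max_iter} iterations; "
            f"residuals {np.abs(tot - totals) / totals}")

    conc_map = {sp.name: float(c) for sp, c in zip(species, conc)}
    return SpeciesDistribution(free_cnu_uM=float(np.exp(logx[0])),
                               free_h_uM=float(np.exp(logx[1])),
                               concentrations_uM=conc_map,
                               total_cnu_uM=total_cnu_uM,
                               total_h_uM=total_h_uM)


def _observed_signal(model, dist):
    num = den = 0.0
    for sp in model.all_species():
        w = sp.brightness * dist.concentrations_uM[sp.name]
        num += w * sp.signal
        den += w
    if den <= 0:
        raise ValueError("no emitting species: signal undefined")
    return num / den


def solve_titration(model: EquilibriumModel, receptor_uM: float,
                    titrant_uM) -> tuple:
    """Solve the model along a titration grid.

    Returns (signals, distributions) with one intensity-weighted signal
    and one :class:`SpeciesDistribution` per grid point.
    """
    titrant_uM = np.asarray(titrant_uM, dtype=float)
    dists, signals = [], np.empty(titrant_uM.size)
    for i, h_tot in enumerate(titrant_uM):
        d = solve_equilibria(model, receptor_uM, float(h_tot))
        dists.append(d)
        signals[i] = _observed_signal(model, d)
    return signals, dists


def apparent_hill_from_model(model: EquilibriumModel, titrant_uM,
                             receptor_uM: float = 2.0,
                             exclude_rollover: bool = True,
                             n_boot: int = 0) -> HillFit:
    """Apparent Hill parameters produced by a declared species mixture.

    Generates the noiseless model isotherm (intensity-weighted signal on
    the given grid) and runs :func:`hill_fit` on it, so the returned
    n_H/K_half are exactly what the operational Hill analysis would report
    for that mixture.
    """
    signals, _ = solve_titration(model, receptor_uM, titrant_uM)
    iso = BindingIsotherm(np.asarray(titrant_uM, float), signals,
                          receptor_total_uM=receptor_uM)
    return hill_fit(iso, exclude_rollover=exclude_rollover, n_boot=n_boot)


# ---------------------------------------------------------------------------
# Monomer-dimer anisotropy

def monomer_fraction(total_protomer_uM, K_D_uM):
    """Fraction of protomers free, from m + 2 m^2 / K_D = C (exact root)."""
    C = np.asarray(total_protomer_uM, dtype=float)
    m = (-K_D_uM + np.sqrt(K_D_uM ** 2 + 8.0 * K_D_uM * C)) / 4.0
    return np.where(C > 0, m / np.where(C > 0, C, 1.0), 1.0)


def dimer_anisotropy(total_protomer_uM, K_D_uM, r_mono, r_dimer):
    """Intensity-weighted anisotropy assuming equal monomer/dimer brightness."""
    fm = monomer_fraction(total_protomer_uM, K_D_uM)
    return fm * r_mono + (1.0 - fm) * r_dimer


def fit_dimer_anisotropy(tit: AnisotropyTitration, tracer_uM: float = None,
                         n_boot: int = 500, seed: int = 0) -> DimerFit:
    """Fit a monomer-dimer equilibrium to an anisotropy self-titration.

    The mass balance runs over total protomer = tracer + titrant. Flat
    profiles (signal range under 3x the local noise scale) raise, mirroring
    the no-association limit where K_D is unbounded.
    """
    if tracer_uM is None:
        tracer_uM = tit.tracer_uM
    if tracer_uM <= 0:
        raise ValueError("tracer concentration must be positive")
    if tit.titrant_total_uM.size < 6:
        raise ValueError("need at least 6 points")
    C = tit.titrant_total_uM + tracer_uM
    r = tit.anisotropy
    noise = 1.4826 * np.median(np.abs(np.diff(r))) / np.sqrt(2)
    if (r.max() - r.min()) <= max(3 * noise, 1e-4):
        raise ValueError("no association detected: anisotropy profile is flat")

    def resid(p, y=r):
        logK, rm, rd = p
        return dimer_anisotropy(C, np.exp(logK), rm, rd) - y

    p0 = np.array([np.log(np.median(C)), r.min(), r.max()])
    bounds = ([np.log(C.min() * 1e-3), 0.0, 0.0],
              [np.log(C.max() * 1e4), 0.4, 0.4])
    sol = least_squares(resid, p0, bounds=bounds)
    logK, rm, rd = sol.x

    ci = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        res = resid(sol.x)
        yhat = res + r
        draws = np.empty(n_boot)
        for b in range(n_boot):
            yb = yhat + rng.choice(res, size=res.size, replace=True)
            try:
                s = least_squares(resid, sol.x, args=(yb,), bounds=bounds)
                draws[b] = np.exp(s.x[0])
            except Exception:
                draws[b] = np.nan
        lo, hi = np.nanpercentile(draws, [16, 84])
        ci = {"K_D_uM": (float(lo), float(hi))}

    return DimerFit(K_D_uM=float(np.exp(logK)), r_monomer=float(rm),
                    r_dimer=float(rd), ci68=ci,
                    residual_norm=float(np.linalg.norm(sol.fun)))
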