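"""Two-state thermal unfolding analysis of CD melts and DSC thermograms.

The folded population comes from the Gibbs-Helmholtz free energy
dG_unf(T) = dHm (1 - T/Tm) + dCp [(T - Tm) - T ln(T/Tm)] (T absolute),
so f_N(Tm) = 1/2 by construction. Melt curves are modeled as
population-weighted linear baselines; DSC peaks as the two-state excess
heat capacity on linear baselines. Apparent DSC signals convert to
absolute molar heat capacity with the buffer-displacement term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datatypes import MeltCurve, Thermogram

__all__ = [
    "TwoStateFit",
    "R_KJ_MOL_K",
    "folded_fraction",
    "two_state_signal",
    "excess_heat_capacity",
    "fit_two_state_melt",
    "delta_tm",
    "dsc_absolute_cp",
    "tm_from_thermogram",
]

R_KJ_MOL_K = 8.314462618e-3  # gas constant, kJ/mol/K
T0_K = 273.15


def folded_fraction(temps_C, Tm_C, dHm_kJ_mol, dCp_kJ_mol_K=0.0):
    """Two-state folded population from the Gibbs-Helmholtz free energy."""
    T = np.asarray(temps_C, dtype=float) + T0_K
    Tm = Tm_C + T0_K
    dG = dHm_kJ_mol * (1.0 - T / Tm) + dCp_kJ_mol_K * ((T - Tm) - T * np.log(T / Tm))
    # dG is the unfolding free energy; K_unf = exp(-dG/RT)
    return 1.0 / (1.0 + np.exp(-dG / (R_KJ_MOL_K * T)))


def two_state_signal(temps_C, Tm_C, dHm, dCp, aN, bN, aU, bU):
    """Population-weighted linear baselines."""
    t = np.asarray(temps_C, dtype=float)
    fN = folded_fraction(t, Tm_C, dHm, dCp)
    return fN * (aN + bN * t) + (1.0 - fN) * (aU + bU * t)


def excess_heat_capacity(temps_C, Tm_C, dHm_kJ_mol, dCp_kJ_mol_K=0.0):
    """Two-state (van 't Hoff) excess heat capacity in kJ/mol/K.

    C_exc = dH(T)^2/(R T^2) * fN * fU + dCp * fU with
    dH(T) = dHm + dCp (T - Tm).
    """
    T = np.asarray(temps_C, dtype=float) + T0_K
    fN = folded_fraction(temps_C, Tm_C, dHm_kJ_mol, dCp_kJ_mol_K)
    fU = 1.0 - fN
    dH = dHm_kJ_mol + dCp_kJ_mol_K * (T - (Tm_C + T0_K))
    return dH ** 2 / (R_KJ_MOL_K * T ** 2) * fN * fU + dCp_kJ_mol_K * fU


@dataclass
class TwoStateFit:
    """Fitted two-state melt parameters with linearized covariance."""

    Tm_C: float
    dHm_kJ_mol: float
    dCp_kJ_mol_K: float
    baseline_folded: tuple  # (intercept, slope)
    baseline_unfolded: tuple
    residual_norm: float
    covariance: np.ndarray = field(default=None, repr=False)
    param_names: tuple = ()
    probe_label: str = ""

    def __post_init__(self):
        if not self.dHm_kJ_mol > 0:
            raise ValueError("dHm must be positive")
        if not np.isfinite(self.residual_norm):
            raise ValueError("residual norm must be finite")

    @property
    def tm_stderr_C(self) -> float:
        if self.covariance is None:
            return np.nan
        i = self.param_names.index("Tm_C")
        return float(np.sqrt(self.covariance[i, i]))


def _init_guess(curve: MeltCurve):
    t, s = curve.temperatures_C, curve.signal
    ds = np.gradient(s, t)
    # smooth the derivative a little before locating the transition
    k = max(1, t.size // 20)
    kern = np.ones(2 * k + 1) / (2 * k + 1)
    ds_s = np.convolve(ds, kern, mode="same")
    i_tr = int(np.argmax(np.abs(ds_s)))
    Tm0 = float(t[i_tr])
    # width heuristic: a two-state transition has ~90% of its amplitude over
    # ~ 4.4 R Tm^2 / dHm kelvin
    amp = s.max() - s.min()
    if amp <= 0:
        raise ValueError("unconstrained Tm: flat melt curve")
    width = max(amp / max(abs(ds_s[i_tr]), 1e-12), 1.0)
    dHm0 = float(np.clip(4.4 * R_KJ_MOL_K * (Tm0 + T0_K) ** 2 / width, 50.0, 1500.0))
    n = max(3, t.size // 5)
    bN = np.polyfit(t[:n], s[:n], 1)
    bU = np.polyfit(t[-n:], s[-n:], 1)
    return Tm0, dHm0, (bN[1], bN[0]), (bU[1], bU[0])


def fit_two_state_melt(curve: MeltCurve, fix_dCp: bool = True,
                       init: dict = None) -> TwoStateFit:
    """Least-squares two-state fit of a thermal melt.

    dCp is fixed to zero by default: CD melts rarely constrain it, and the
    baseline slopes absorb most of its signature. Initialization takes Tm
    from the extremum of the smoothed derivative and dHm from a transition-
    width heuristic; pass ``init`` to override any of
    {Tm_C, dHm_kJ_mol, dCp_kJ_mol_K}.
    """
    t, s = curve.temperatures_C, curve.signal
    noise = 1.4826 * np.median(np.abs(np.diff(s))) / np.sqrt(2)
    if (s.max() - s.min()) < 3 * noise:
        raise ValueError("unconstrained Tm: no transition within the scanned range")
    Tm0, dHm0, (aN0, bN0), (aU0, bU0) = _init_guess(curve)
    init = init or {}
    Tm0 = init.get("Tm_C", Tm0)
    dHm0 = init.get("dHm_kJ_mol", dHm0)
    dCp0 = init.get("dCp_kJ_mol_K", 0.0)

    names = ["Tm_C", "dHm_kJ_mol", "aN", "bN", "aU", "bU"]
    p0 = [Tm0, dHm0, aN0, bN0, aU0, bU0]
    lo = [t[0], 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [t[-1], 5000.0, np.inf, np.inf, np.inf, np.inf]
    if not fix_dCp:
        names.insert(2, "dCp_kJ_mol_K")
        p0.insert(2, dCp0)
        lo.insert(2, -50.0)
        hi.insert(2, 50.0)

    def unpack(p):
        if fix_dCp:
            Tm, dHm, aN, bN, aU, bU = p
            dCp = 0.0
        else:
            Tm, dHm, dCp, aN, bN, aU, bU = p
        return Tm, dHm, dCp, aN, bN, aU, bU

    def resid(p):
        return two_state_signal(t, *unpack(p)) - s

    sol = least_squares(resid, p0, bounds=(lo, hi))
    if not sol.success:
        raise RuntimeError("melt fit did not converge; try supplying init "
                           "estimates for Tm_C and dHm_kJ_mol")
    Tm, dHm, dCp, aN, bN, aU, bU = unpack(sol.x)

    # linearized covariance: sigma^2 (J^T J)^-1 with sigma^2 from residuals
    dof = max(t.size - sol.x.size, 1)
    sigma2 = 2 * sol.cost / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        raise RuntimeError("singular Jacobian: melt fit unconstrained; narrow "
                           "the baselines or supply init values")

    return TwoStateFit(Tm_C=float(Tm), dHm_kJ_mol=float(dHm),
                       dCp_kJ_mol_K=float(dCp),
                       baseline_folded=(float(aN), float(bN)),
                       baseline_unfolded=(float(aU), float(bU)),
                       residual_norm=float(np.linalg.norm(sol.fun)),
                       covariance=cov, param_names=tuple(names),
                       probe_label=curve.probe_label)


def delta_tm(fit_a: TwoStateFit, fit_b: TwoStateFit) -> tuple:
    """Tm difference a - b (C) with its propagated standard error.

    Used both for probe-to-probe comparisons (global CD vs local
    lifetime-amplitude melts) and concentration-to-concentration shifts.
    """
    d = fit_a.Tm_C - fit_b.Tm_C
    se = float(np.sqrt(np.nansum([fit_a.tm_stderr_C ** 2, fit_b.tm_stderr_C ** 2])))
    return float(d), se


def dsc_absolute_cp(thermogram: Thermogram, buffer_cp_kJ_g_K=4.1813e-3,
                    buffer_density_g_mL: float = 0.9970) -> np.ndarray:
    """Convert an apparent (buffer-referenced) DSC signal to absolute molar
    heat capacity.

    Cp_abs(T) = Mw * v_bar * rho_buf * cp_buf(T) + Cp_app(T), where the
    first term is the heat capacity of the buffer volume displaced by one
    mole of protein and Cp_app is the molar apparent signal stored on the
    thermogram. ``buffer_cp_kJ_g_K`` may be a scalar or an array over the
    thermogram temperatures (defaults to water at 25 C). The additive sign
    convention for the apparent term is recorded in this docstring: buffer-
    referenced signals are negative-offset, so the sum is absolute.
    """
    if not thermogram.v_bar_mL_g > 0:
        raise ValueError("partial specific volume required")
    cp_buf = np.broadcast_to(np.asarray(buffer_cp_kJ_g_K, dtype=float),
                             thermogram.temperatures_C.shape)
    displacement = thermogram.mw_g_mol * thermogram.v_bar_mL_g * \
        buffer_density_g_mL * cp_buf
    absolute = displacement + thermogram.cp_kJ_mol_K
    if np.any(absolute < 0):
        warnings.warn("negative absolute Cp: check the sign convention of the "
                      "apparent signal")
    return absolute


def tm_from_thermogram(temperatures_C, cp_kJ_mol_K) -> float:
    """Temperature of the excess-heat-capacity maximum.

    A straight baseline through the curve endpoints is subtracted, the
    dominant peak located, and the maximum refined by parabolic
    interpolation over the 5 surrounding points. Raises when no peak exists
    or when a secondary peak rivals the dominant one (>50% of its height at
    >5 C separation).
    """
    from scipy.signal import find_peaks

    t = np.asarray(temperatures_C, dtype=float)
    cp = np.asarray(cp_kJ_mol_K, dtype=float)
    base = cp[0] + (cp[-1] - cp[0]) * (t - t[0]) / (t[-1] - t[0])
    exc = cp - base
    i = int(np.argmax(exc))
    scale = max(np.ptp(cp), np.max(np.abs(cp)), 1e-30)
    if i in (0, t.size - 1) or exc[i] <= 1e-9 * scale:
        raise ValueError("no interior excess-Cp peak found (monotone curve?)")
    noise = 1.4826 * np.median(np.abs(np.diff(exc))) / np.sqrt(2)
    if exc[i] < 5 * noise:
        raise ValueError("no significant excess-Cp peak above the noise")
    # guard against multiple comparable peaks
    peaks, _ = find_peaks(exc, prominence=0.5 * exc[i])
    if peaks.size > 1:
        where = ", ".join(f"{t[p]:.1f}" for p in peaks)
        raise ValueError(f"multiple comparable peaks near {where} C")
    k = slice(max(i - 2, 0), min(i + 3, t.size))
    coef = np.polyfit(t[k], exc[k], 2)
    if coef[0] >= 0:
        return float(t[i])
    return float(-coef[1] / (2 * coef[0]))
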