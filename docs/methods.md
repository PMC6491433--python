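# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Two-state thermal unfolding

Melt curves are fit to a population-weighted two-baseline model

    S(T) = f_N(T)·(a_N + b_N T) + (1 − f_N(T))·(a_U + b_U T),

with the folded fraction from the Gibbs–Helmholtz unfolding free energy

    ΔG(T) = ΔH_m (1 − T/T_m) + ΔC_p [(T − T_m) − T ln(T/T_m)],

evaluated in kelvin internally (all interfaces report °C, which is how
melting temperatures are conventionally quoted). ΔC_p is fixed to zero by
default: CD melts rarely constrain it, the baseline slopes absorb most of
its signature, and floating it mainly inflates the T_m covariance. DSC
fits may float it.

Initialization is automatic — T_m from the extremum of the smoothed
derivative, ΔH_m from a transition-width heuristic (≈ 4.4·R·T_m²/width) —
which converges over the full fixture grid (T_m 45–75 °C, ΔH_m 150–300
kJ/mol) without user input. Parameter uncertainties come from the
linearized covariance σ²(JᵀJ)⁻¹; `delta_tm` propagates them in
quadrature for probe-to-probe (global CD vs local lifetime-amplitude) and
concentration-to-concentration T_m differences.

DSC signals convert to absolute molar heat capacity as

    C_p(T) = M_w · v̄ · ρ_buf · c_p,buf(T) + C_p,app(T),

i.e. the heat capacity of the buffer volume displaced by one mole of
protein plus the (molar) buffer-referenced apparent signal. The buffer
heat capacity is taken per gram (default: water, 4.1813·10⁻³ kJ/g/K)
with its density as a separate factor, which keeps the displacement term
dimensionally clean. The additive convention for the apparent term is
part of the function contract; negative absolute C_p triggers a warning
as the usual symptom of a flipped convention. `tm_from_thermogram`
subtracts a straight endpoint baseline, requires a single dominant peak
(secondary peaks above 50% prominence raise an error listing candidates),
and refines the maximum by parabolic interpolation over 5 points. For the
two-state excess C_p at ΔC_p = 0 the peak sits within 1 °C of T_m (the
ΔH²/RT² prefactor skews it slightly low), which is the agreed tolerance
for melt-vs-DSC consistency checks.

## Steady-state fluorescence

Relative quantum yields follow the standard comparison
QY = QY_ref · (∫I_s/∫I_ref) · (A_ref/A_s) with trapezoid integrals over
the common wavelength support only (recorded windows differ between
274 nm and 295 nm excitation). No polarization or refractive-index
corrections are applied; absorbances above 0.2 warn about inner-filter
effects. The NATA reference value 0.13 (water, 25 °C) is the module
default.

The intensity-averaged wavenumber ν̄_av = 10⁴·Σ I(λ)λ⁻¹ / Σ I(λ) is a
discrete sum on the recorded grid with no interpolation — the statistic
is defined on the measured points — and warns when the grid spacing
varies by more than 1%, since the sum then weights spectral regions
unevenly. Its value is always bracketed by the grid's extreme
wavenumbers.

SVD deconvolution runs on the raw wavelength × condition grid. Signs are
fixed so every basis spectrum has non-negative mean, with amplitude rows
flipped to match; the convention is recorded on the result because the
absolute sign of the second component (and hence whether its amplitude is
"more" or "less" negative) is otherwise arbitrary. Component counting
uses a singular-value threshold of 5% of the largest. For the two-basis
synthetic grids, the second component crosses zero between the tyrosine
(~305 nm) and tryptophan (~350 nm) bands, and its per-condition amplitude
tracks the relative Tyr/Trp emission — the quantity used as a *relative*
FRET ruler. No attempt is made to calibrate amplitudes into ångströms.

The Förster relation E = 1/(1+(r/r₀)⁶) and its exact algebraic inverse
are provided (r₀ = 12 Å for the Tyr–Trp pair; the folded Tyr40–Trp67
separation is ~11 Å, which is why this pair dominates the FRET response).
The freely-jointed-chain RMS end-to-end distance √n·b exposes the link
count and bond length as explicit inputs rather than assuming a
per-residue parameterization.

## TCSPC reconvolution

The decay model is scale·[IRF ⊛ Σ αᵢ e^(−t/τᵢ)] + background on the
measured bin grid, with the IRF area-normalized and an optional sub-bin
shift applied by linear interpolation. Residuals carry Poisson weights
1/√max(counts, 1) — standard TCSPC practice; the floor of one count
prevents division by zero. The fit window runs from the IRF rise (1% of
the IRF peak) to the last bin with ≥ 10 counts. Reduced χ² is reported
with dof = n_bins − n_params. Because the observed-count (Neyman)
weighting slightly overweights downward fluctuations at low counts, the
calibration of reduced χ² at the true model sits near 1.05–1.10 rather
than exactly 1; this is inherent to the weighting convention and well
inside the < 1.5 adequacy criterion used for bi-exponential fits.

Initialization uses a tail log-slope estimate with three starts (0.5×,
1×, 2×); lifetimes within 1% of each other trigger an
"overparameterized" warning. Amplitude fractions are recovered by
normalizing non-negative component amplitudes, so they close to 1 by
construction.

Across a temperature series, the long-lifetime amplitude (the folded-like
component) is assembled into a melting curve with component identity
assigned by lifetime magnitude — stable here because the lifetimes
themselves are salt-insensitive; a τ-ratio below 1.5 warns that the
assignment is ambiguous. The curve's midpoint comes from a 4-parameter
logistic fit. The lifetime-derived midpoint can sit far below the CD T_m
(the packaged low-salt condition realizes a 12 °C gap), which is the
signature of helix 4 detaching before global unfolding.

## Screened electrostatics

The ionic-strength dependence of native charge–charge interactions is
modeled as a screened Coulomb sum over point charges,

    E = Σ_{i<j} 332.0 q_i q_j exp(−κ r_ij) / (ε r_ij)  kcal/mol,

with a uniform solvent dielectric (default 78.5 at 25 °C) and the Debye
constant κ = √(2 N_A e² I / ε ε₀ k_B T) (κ⁻¹ ≈ 9.6 Å at 0.1 M). This is
a deliberate surrogate for cavity-dielectric (Tanford–Kirkwood) models:
it keeps the dominant salt dependence while dropping the boundary
multipole series, and its outputs are labeled accordingly. Energies are
model-relative; only the salt *trend* is meaningful. Note that while the
magnitude of every pair term is strictly decreasing in ionic strength,
the magnitude of a mixed-sign *total* need not be monotone in general;
for the charge sets analyzed here (the toy bundle, the H-NS N-terminal
domain, alternating-line toys) the total stabilization weakens
monotonically with salt, mirroring the expected trend.

Charges are assigned one per ionizable group on a side-chain reference
atom (CG/CD/NE2/SG/OH/NZ/CZ; termini on backbone N and C), with fractional
values from Henderson–Hasselbalch at the given pH and a default intrinsic
pKa table (Asp 4.0, Glu 4.4, His 6.3, Cys 8.3, Tyr 9.6, Lys 10.4, Arg
12.0, N-term 7.5, C-term 3.8) that can be overridden. No environmental
pKa shifts are computed. Pairs closer than 2 Å are excluded (warned);
overlaps below 0.1 Å are an error. Per-residue energies are half-sums of
the touching pair terms (so they add to the total), and residues with net
unfavorable energy at the reference ionic strength are flagged as
electrostatically frustrated.

Ensemble descriptors — convex-hull volume, per-residue contact
probability (fraction of other Cα within a cutoff, averaged over
members), and pairwise Cα distance distributions — are the quantities
used to characterize heterogeneity in simulation snapshots.

## Binding analysis

Hill fits use S = S_free + (S_bound − S_free)·Lⁿ/(K_½ⁿ + Lⁿ) with L the
*total* titrant. The ligand-excess approximation is justified because
the ~2 μM receptor sits far below every fitted midpoint; the exact
solver is available for models where it does not. Roll-over points —
a persistent (≥ 2 consecutive points, above the local noise scale)
movement back toward the free-state signal after the extremum — are
detected, excluded by default, and counted on the returned fit. 68%
confidence intervals come from a seeded residual bootstrap (500 resamples
by default).

The coupled-equilibrium solver takes a declared species list over the two
components with cumulative formation constants β (μM^(1−a−b) for
stoichiometry (a, b)), and solves both mass balances by damped Newton
iteration on log free concentrations (analytic Jacobian, relative
tolerance 10⁻¹⁰, max 200 iterations). Dissociation-scale constants are
quoted in μM throughout.

Observed titration signals are intensity-weighted means over species:
S = Σ b_s c_s S_s / Σ b_s c_s with per-species brightness b_s. This is
how a ν̄_av-type statistic actually mixes emitting species, and it is
what produces the high-titrant roll-over: once a weakly emitting H-NS
homodimer accumulates, it drags the average back toward the free-state
value even though the receptor stays bound. A mixture containing only a
1:1 species reproduces the Hill form with n_H = 1 exactly; adding a
positively coupled second binding step raises the apparent n_H.

Anisotropy self-titrations are fit to the monomer–dimer equilibrium
K_D = [M]²/[D] over total protomer (tracer + titrant), with
intensity-weighted anisotropy r = f_M r_mono + (1 − f_M) r_dimer under
the equal-brightness assumption (flagged; it makes the curve's midpoint
fall exactly at total protomer = K_D). Flat profiles — the no-association
limit seen for fully unfolded material — raise rather than returning an
unbounded K_D.

## Synthetic data and the condition registry

The generators emulate the statistical structure each analysis assumes:
Gaussian noise for analog channels (CD, spectra, anisotropy), Poisson
counts for photon detection, a Gaussian IRF for TCSPC (stored noiseless,
which keeps the χ² calibration clean), two Gaussian-in-wavenumber basis
bands at ~305/~350 nm for emission grids (the difference basis is
orthogonalized against the average-spectrum basis so SVD amplitudes map
directly onto the generator trajectories), and an idealized four-helix
Cα bundle with per-segment cumulative-random-walk disorder for
ensembles. Every generator draws from a single seeded `default_rng`, so
identical (parameters, seed) reproduce output bit for bit, and growing
disorder at a fixed seed yields strictly nested spreads.

`data/conditions.yaml` is the single source of truth for the six
headline (IS, T) conditions. Binding parameters at the labeled
conditions are: n_H = 1.4 (14.5 mM, 5 °C) and 1.8 (14.5 mM, 37 °C) with
unit coefficients at 170/500 mM; K_½ = 100 μM at 500 mM/310 K with the
170 mM midpoint four-fold stronger (25 μM). Midpoints that are not
quoted anywhere (the 14.5 mM and 5 °C conditions) were chosen once —
1 μM and 10 μM at 14.5 mM, realizing the order-of-magnitude weakening
with temperature and a roughly two-orders-of-magnitude span across all
conditions; 2.5 and 10 μM at 5 °C for the higher-salt conditions — and
are registry values, not fit results. The H-NS dimer fixture uses
K_D = 150 μM (inside the 100–150 μM range), r_mono = 0.06,
r_dimer = 0.14. Decay fixtures use the salt-insensitive 5 ns/1 ns
lifetime pair at 10⁴ peak counts. Measurement noise magnitudes are free
parameters of the fixtures (instrument-dependent and not otherwise
specified); defaults are noiseless so that round-trip tests probe the
estimators, with noise studies seeded explicitly.

What the generators do *not* emulate: real spectral band shapes and their
temperature drift, correlated baseline drifts, scattering artifacts,
inner-filter effects, detector afterpulsing, or genuine conformational
ensembles (the toy bundle is a labeled synthetic stand-in, not a
simulation snapshot). Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated statistical assumptions,
not the behavior of any real instrument or force field.

## Problem sizes

Default sizes keep the whole chain quick while matching the recorded
protocols where they matter: 30-point titrations spanning 0.03–140 μM,
4096-bin decays over 50 ns at 10⁴ peak counts (1024 bins in repeated
calibration studies), 3 °C-spaced emission grids over 5–95 °C, 1 °C melt
curves, and 50-seed noise studies. The full test suite runs in well
under a minute; the acceptance script in a few seconds.

## Known limitations

- Multi-state melts, scan-rate corrections, and structural C_p baselines
  are out of scope; so are Poisson–Boltzmann electrostatics, pKa shifts,
  and any reproduction of simulation energies.
- The Hill fit's total-titrant approximation biases n_H upward by ~0.2%
  at receptor/K ≈ 1/50; use the exact solver route when the receptor is
  not negligible.
- The species set behind fractional Hill coefficients is user-declared;
  the solver reports whatever mixture it is given and cannot infer the
  true oligomer distribution.
- Reduced χ² from Neyman-weighted TCSPC fits is biased high by a few
  percent at low counts, as noted above.
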