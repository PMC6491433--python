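# osmoswitch

Analysis toolkit for salt-tunable protein structure and binding
cooperativity, built around the osmosensory pair Cnu (a four-helix
Hha-family regulator from enterobacteria) and the N-terminal domain of the
transcription repressor H-NS. Cnu senses solvent ionic strength (IS): with
decreasing salt its native ensemble becomes heterogeneous and swollen
(helix 4 detaches early), and its binding to H-NS switches from a simple
1:1 equilibrium (Hill coefficient n_H ≈ 1 at 170–500 mM IS) to apparent
positive cooperativity (n_H 1.4 → 1.8 at 14.5 mM IS), with a competing
H-NS homodimer producing a signal roll-over at high titrant.

The package implements the full measurement-analysis chain for this kind
of study, plus seeded generators that emulate every raw input so each
stage is testable by parameter recovery:

| module | what it does |
|---|---|
| `osmoswitch.synthetic` | seeded generators: two-basis emission grids, Poisson TCSPC decays, two-state melts/thermograms, Hill and coupled-equilibrium titrations, monomer–dimer anisotropy curves, toy four-helix-bundle ensembles |
| `osmoswitch.melt` | two-state Gibbs–Helmholtz melt fits (T_m, ΔH_m), ΔT_m between probes/concentrations, DSC absolute-heat-capacity conversion, T_m from excess-C_p peaks |
| `osmoswitch.fluor` | relative quantum yields vs the NATA standard (0.13 in water at 25 °C), intensity-averaged wavenumber ν̄_av = 10⁴·ΣI(λ)λ⁻¹/ΣI(λ), SVD spectral deconvolution (U1 average spectrum / U2 Tyr–Trp anti-correlation), Förster relation E = 1/(1+(r/r₀)⁶), freely-jointed-chain √n·b distance bound |
| `osmoswitch.lifetime` | TCSPC reconvolution fitting (1–3 exponentials, Poisson weights, sub-bin IRF shift), long-lifetime amplitude melting curves and their logistic inflection points |
| `osmoswitch.electrostatics` / `osmoswitch.ensembles` | Henderson–Hasselbalch charge assignment on PDB structures, Debye-screened Coulomb energy scans vs ionic strength with per-residue frustration flags, convex-hull volume / contact probability / Cα-distance descriptors for conformational ensembles |
| `osmoswitch.binding` | Hill fits with automatic roll-over exclusion and bootstrap 68% CIs, a damped-Newton mass-action solver for declared hetero/homo-oligomer species sets, apparent n_H of species mixtures, monomer–dimer anisotropy fitting (K_D = [M]²/[D]) |

## Worked example

Generate a low-salt, 37 °C titration from the packaged condition registry
(1% signal noise), fit the Hill equation, and fit a bi-exponential decay
at the standard 10⁴ peak counts:

```python
import numpy as np
from osmoswitch import binding, fixtures, synthetic, lifetime

cfg = fixtures.condition("IS14.5_T37", seed=7)
iso = synthetic.simulate_hill_isotherm(cfg, noise_sigma=0.01)
fit = binding.hill_fit(iso, seed=7)
print(fit.n_H, fit.K_half_uM, fit.ci68)

trace = synthetic.simulate_decay([5.0, 1.0], [0.6, 0.4], irf_fwhm_ns=0.5,
                                 peak_count=10_000, seed=7)
lf = lifetime.reconvolution_fit(trace, n_exp=2)
print(lf.taus_ns, lf.amplitudes, lf.reduced_chi_square)
```

prints (formatted):

```
n_H      = 1.84  (68% CI 1.80-1.88)
K_half   = 10.3 uM  (68% CI 10.1-10.4)
taus     = [4.97 0.98] ns, amplitudes = [0.61 0.39]
red chi2 = 1.05
```

The Hill fit recovers the condition's cooperative coefficient (1.8) and
midpoint (10 μM) within the noise; the reconvolution fit recovers both
lifetimes and the 60/40 amplitude split with reduced χ² ≈ 1, well under
the 1.5 adequacy threshold used for bi-exponential decays.

The same analyses are scriptable from the shell:

```bash
osmoswitch simulate isotherm --condition IS500_T310K --out iso.csv
osmoswitch fit-hill iso.csv
osmoswitch tk-scan structure.pdb --ph 8.0 --is 14.5,170,500 --out scan.csv
```

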