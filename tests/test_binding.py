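"""Hill fits, roll-over detection, coupled equilibria, dimer anisotropy."""

import numpy as np
import pytest

from osmoswitch import binding, synthetic
from osmoswitch.binding import (EquilibriumModel, Species,
                                apparent_hill_from_model, detect_rollover,
                                fit_dimer_anisotropy, hill_fit, hill_signal,
                                solve_equilibria)
from osmoswitch.datatypes import AnisotropyTitration, BindingIsotherm


def _hill_iso(K=100.0, n=1.0, grid=None, sf=28.4, sb=29.2):
    grid = synthetic.default_titrant_grid() if grid is None else grid
    return BindingIsotherm(grid, hill_signal(grid, K, n, sf, sb))


class TestHillFit:
    def test_one_to_one_noiseless_recovery(self):
        fit = hill_fit(_hill_iso(K=100.0, n=1.0), n_boot=0)
        assert fit.n_H == pytest.approx(1.0, abs=1e-4)
        assert fit.K_half_uM == pytest.approx(100.0, rel=1e-4)

    def test_cooperative_noiseless_recovery_below_half_percent(self):
        fit = hill_fit(_hill_iso(K=10.0, n=1.8), n_boot=0)
        assert fit.n_H == pytest.approx(1.8, rel=0.005)
        assert fit.K_half_uM == pytest.approx(10.0, rel=0.005)

    def test_signal_at_midpoint(self):
        s = hill_signal(np.array([10.0]), 10.0, 1.4, 28.4, 29.2)[0]
        assert s == pytest.approx((28.4 + 29.2) / 2)

    def test_bootstrap_ci_brackets_estimates(self):
        rng = np.random.default_rng(1)
        grid = synthetic.default_titrant_grid()
        noisy = hill_signal(grid, 10.0, 1.4, 28.4, 29.2) + \
            rng.normal(0, 0.01, grid.size)
        fit = hill_fit(BindingIsotherm(grid, noisy), n_boot=100, seed=2)
        lo, hi = fit.ci68["n_H"]
        assert lo < fit.n_H < hi

    def test_no_saturation_warns(self):
        grid = np.geomspace(0.03, 5.0, 12)
        iso = _hill_iso(K=500.0, n=1.0, grid=grid)
        with pytest.warns(UserWarning, match="poorly constrained"):
            hill_fit(iso, n_boot=0)


class TestRollover:
    def test_monotone_curve_has_none(self):
        assert detect_rollover(_hill_iso()) is None

    def test_single_point_dip_ignored(self):
        grid = synthetic.default_titrant_grid()
        s = hill_signal(grid, 5.0, 1.0, 28.4, 29.2)
        s[-3] -= 0.05  # isolated dip, not a persistent descent
        assert detect_rollover(BindingIsotherm(grid, s)) is None

    def test_homodimer_fixture_boundary_in_descending_branch(self):
        model = EquilibriumModel(
            [Species("CnuH", (1, 1), 1.0 / 5.0, signal=29.2, brightness=1.0),
             Species("H2", (0, 2), 1.0 / 50.0, signal=28.3, brightness=0.05)],
            free_signal={"Cnu": 28.4, "H": 28.3},
            free_brightness={"Cnu": 1.0, "H": 0.005})
        iso = synthetic.simulate_isotherm(model, synthetic.default_titrant_grid())
        boundary = detect_rollover(iso)
        assert boundary is not None
        i_max = np.argmax(iso.signal)
        assert boundary > iso.titrant_total_uM[i_max - 1]
        fit = hill_fit(iso, n_boot=0)
        assert fit.excluded_points > 0
        assert np.isfinite(fit.fit_range_max_uM)


class TestSolveEquilibria:
    def test_one_to_one_matches_quadratic_closed_form(self):
        K = 100.0
        model = EquilibriumModel([Species("CnuH", (1, 1), 1.0 / K)])
        d = solve_equilibria(model, 2.0, 100.0)
        R, L = 2.0, 100.0
        bound = ((R + L + K) - np.sqrt((R + L + K) ** 2 - 4 * R * L)) / 2.0
        assert d.concentrations_uM["CnuH"] == pytest.approx(bound, rel=1e-8)
        assert d.concentrations_uM["CnuH"] / 2.0 == pytest.approx(0.495, abs=0.005)

    def test_pure_dimer_half_protomers_at_kd(self):
        KD = 80.0
        model = EquilibriumModel([Species("H2", (0, 2), 1.0 / KD)])
        d = solve_equilibria(model, 1e-12, KD)
        assert 2 * d.concentrations_uM["H2"] / KD == pytest.approx(0.5, rel=1e-6)

    def test_dilute_limit_free_equals_total(self):
        model = EquilibriumModel([Species("CnuH", (1, 1), 1.0 / 10.0)])
        d = solve_equilibria(model, 1e-8, 1e-8)
        assert d.free_cnu_uM == pytest.approx(1e-8, rel=1e-4)
        assert d.free_h_uM == pytest.approx(1e-8, rel=1e-4)

    def test_oracle_equivalence_random_draws(self, rng):
        # closed-form 1:1 quadratic as the independent oracle
        for _ in range(100):
            K = 10 ** rng.uniform(-1, 3)
            R = 10 ** rng.uniform(-1, 1)
            L = 10 ** rng.uniform(-2, 3)
            model = EquilibriumModel([Species("CnuH", (1, 1), 1.0 / K)])
            d = solve_equilibria(model, R, L)
            bound = ((R + L + K) - np.sqrt((R + L + K) ** 2 - 4 * R * L)) / 2.0
            assert d.concentrations_uM["CnuH"] == pytest.approx(bound, rel=1e-8,
                                                                abs=1e-12)

    def test_mass_balance_closure(self):
        model = EquilibriumModel(
            [Species("CnuH", (1, 1), 1.0 / 5.0),
             Species("CnuH2", (1, 2), 0.05),
             Species("H2", (0, 2), 1.0 / 150.0)])
        for h in (0.03, 1.0, 30.0, 140.0):
            d = solve_equilibria(model, 2.0, h)
            rc, rh = d.mass_balance_residual(model)
            assert rc < 1e-6 and rh < 1e-6


class TestApparentHill:
    @pytest.mark.parametrize("K", [0.1, 1.0, 10.0, 100.0, 1000.0])
    def test_single_site_model_gives_unit_coefficient(self, K):
        model = EquilibriumModel(
            [Species("CnuH", (1, 1), 1.0 / K, signal=1.0, brightness=1.0)],
            free_signal={"Cnu": 0.0}, free_brightness={"Cnu": 1.0})
        grid = np.geomspace(K * 1e-2, K * 1e2, 30)
        fit = apparent_hill_from_model(model, grid, receptor_uM=K * 1e-3)
        assert fit.n_H == pytest.approx(1.0, abs=0.005)

    def test_positive_coupling_raises_coefficient(self):
        model = EquilibriumModel(
            [Species("CnuH", (1, 1), 1.0 / 10.0, signal=29.0, brightness=1.0),
             Species("CnuH2", (1, 2), 0.05, signal=29.2, brightness=1.0)],
            free_signal={"Cnu": 28.4}, free_brightness={"Cnu": 1.0})
        fit = apparent_hill_from_model(model, synthetic.default_titrant_grid())
        assert fit.n_H > 1.1

    def test_second_coupled_step_never_decreases_coefficient(self, rng):
        grid = synthetic.default_titrant_grid()
        for _ in range(8):
            K1 = 10 ** rng.uniform(0, 1.5)
            base = EquilibriumModel(
                [Species("CnuH", (1, 1), 1.0 / K1, signal=1.0, brightness=1.0)],
                free_signal={"Cnu": 0.0}, free_brightness={"Cnu": 1.0})
            coupled = EquilibriumModel(
                base.species +
                [Species("CnuH2", (1, 2), (1.0 / K1) * 10 ** rng.uniform(-2, -0.5),
                         signal=1.0, brightness=1.0)],
                free_signal={"Cnu": 0.0}, free_brightness={"Cnu": 1.0})
            n0 = apparent_hill_from_model(base, grid, receptor_uM=0.01).n_H
            n1 = apparent_hill_from_model(coupled, grid, receptor_uM=0.01).n_H
            assert n1 >= n0 - 0.005

    def test_homodimer_produces_rollover_and_exclusion(self):
        model = EquilibriumModel(
            [Species("CnuH", (1, 1), 1.0 / 5.0, signal=29.2, brightness=1.0),
             Species("H2", (0, 2), 1.0 / 30.0, signal=28.3, brightness=0.08)],
            free_signal={"Cnu": 28.4, "H": 28.3},
            free_brightness={"Cnu": 1.0, "H": 0.005})
        fit = apparent_hill_from_model(model, synthetic.default_titrant_grid())
        assert fit.excluded_points > 0


class TestDimerAnisotropy:
    def test_noiseless_roundtrip(self):
        tit = synthetic.simulate_anisotropy_titration(
            150.0, 0.06, 0.14, tracer_uM=2.0,
            titrant_uM=np.geomspace(0.03, 300.0, 25))
        fit = fit_dimer_anisotropy(tit, n_boot=0)
        assert fit.K_D_uM == pytest.approx(150.0, rel=1e-3)
        assert fit.r_monomer == pytest.approx(0.06, abs=1e-4)
        assert fit.r_dimer == pytest.approx(0.14, abs=1e-4)

    def test_flat_profile_rejected(self):
        tit = synthetic.simulate_anisotropy_titration(np.inf, 0.06, 0.14,
                                                      tracer_uM=2.0)
        with pytest.raises(ValueError, match="no association"):
            fit_dimer_anisotropy(tit, n_boot=0)

    def test_anisotropy_midpoint_at_fitted_kd(self):
        tit = synthetic.simulate_anisotropy_titration(
            120.0, 0.06, 0.14, tracer_uM=2.0,
            titrant_uM=np.geomspace(0.03, 400.0, 25))
        fit = fit_dimer_anisotropy(tit, n_boot=0)
        r_at_kd = binding.dimer_anisotropy(fit.K_D_uM, fit.K_D_uM,
                                           fit.r_monomer, fit.r_dimer)
        assert r_at_kd == pytest.approx((fit.r_monomer + fit.r_dimer) / 2,
                                        abs=1e-6)

    def test_bootstrap_ci_present(self):
        rng = np.random.default_rng(3)
        grid = np.geomspace(0.03, 300.0, 25)
        tit = synthetic.simulate_anisotropy_titration(
            150.0, 0.06, 0.14, tracer_uM=2.0, titrant_uM=grid,
            noise_sigma=0.002, seed=9)
        fit = fit_dimer_anisotropy(tit, n_boot=50, seed=4)
        lo, hi = fit.ci68["K_D_uM"]
        assert lo < hi
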