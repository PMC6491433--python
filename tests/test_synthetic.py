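"""Generators: statistical structure, reproducibility, round-trips."""

import numpy as np
import pytest

from osmoswitch import binding, ensembles, fixtures, lifetime, melt, synthetic
from osmoswitch.binding import EquilibriumModel, Species
from osmoswitch.datatypes import FixtureConfig


def _config(**emission):
    return FixtureConfig("test", 170.0, 25.0, model_params={"emission": emission},
                         seed=3)


class TestEmissionMatrix:
    def test_single_basis_matrix_has_rank_one(self):
        cfg = _config(noise_sigma=0.0, u2_cold=0.0, u2_hot=0.0,
                      a1_cold=1.0, a1_hot=0.5)
        m = synthetic.simulate_emission_matrix(cfg, np.arange(5, 96, 5.0))
        s = np.linalg.svd(m.intensities, compute_uv=False)
        assert s[1] < 1e-8 * s[0]

    def test_two_independent_trajectories_give_rank_two(self):
        cfg = _config(noise_sigma=0.0, u2_cold=-0.05, u2_hot=-0.30,
                      a1_cold=1.0, a1_hot=0.5)
        m = synthetic.simulate_emission_matrix(cfg, np.arange(5, 96, 5.0))
        s = np.linalg.svd(m.intensities, compute_uv=False)
        assert s[1] > 1e-3 * s[0]
        assert s[2] < 1e-8 * s[0]

    def test_bit_reproducible(self):
        cfg = _config(noise_sigma=0.05)
        a = synthetic.simulate_emission_matrix(cfg, [5.0, 25.0, 45.0])
        b = synthetic.simulate_emission_matrix(cfg, [5.0, 25.0, 45.0])
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_rejects_bad_inputs(self):
        cfg = _config(noise_sigma=-0.1)
        with pytest.raises(ValueError):
            synthetic.simulate_emission_matrix(cfg, [5.0, 25.0])
        with pytest.raises(ValueError):
            synthetic.simulate_emission_matrix(_config(), [5.0, 25.0],
                                               wavelengths_nm=[350, 340, 330])
        with pytest.raises(ValueError):
            synthetic.simulate_emission_matrix(_config(), [5.0])


class TestDecay:
    def test_delta_irf_limit_is_pure_exponential(self):
        tr = synthetic.simulate_decay([5.0], [1.0], irf_fwhm_ns=0.01,
                                      peak_count=100_000, seed=0,
                                      poisson=False, n_bins=2048,
                                      t_max_ns=40.0, irf_center_ns=0.05)
        t = tr.time_ns
        sel = (tr.counts > 50) & (t > 0.5)
        slope = np.polyfit(t[sel], np.log(tr.counts[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(5.0, rel=5e-3)

    def test_expected_trace_matches_independent_convolution(self):
        # oracle: build the convolved expectation from first principles and
        # check the unit-area kernel conserves the summed intensity
        n_bins, t_max, fwhm, t0 = 4096, 80.0, 0.8, 1.0
        tr = synthetic.simulate_decay([3.0], [1.0], irf_fwhm_ns=fwhm,
                                      peak_count=10_000, seed=0,
                                      poisson=False, n_bins=n_bins,
                                      t_max_ns=t_max, irf_center_ns=t0)
        t = tr.time_ns
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        irf = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        decay = np.exp(-t / 3.0)
        conv = np.convolve(irf / irf.sum(), decay)[:n_bins]
        # conservation (decay dead well before the window edge)
        assert conv.sum() == pytest.approx(decay.sum(), rel=1e-6)
        expected = conv * 10_000 / conv.max()
        np.testing.assert_allclose(tr.counts, np.round(expected), atol=1.0)

    def test_roundtrip_recovers_lifetimes_within_5_percent(self, standard_decay):
        fit = lifetime.reconvolution_fit(standard_decay, n_exp=2)
        assert fit.taus_ns[0] == pytest.approx(5.0, rel=0.05)
        assert fit.taus_ns[1] == pytest.approx(1.0, rel=0.05)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            synthetic.simulate_decay([-1.0], [1.0], 0.5, 1000)
        with pytest.raises(ValueError):
            synthetic.simulate_decay([5.0], [1.0], 0.0, 1000)
        with pytest.raises(ValueError):
            synthetic.simulate_decay([5.0], [0.7], 0.5, 1000)


class TestIsotherm:
    def test_degenerate_signal_map_gives_flat_curve(self, titrant_grid):
        model = EquilibriumModel(
            [Species("CnuH", (1, 1), 1.0 / 50.0, signal=29.0, brightness=1.0)],
            free_signal={"Cnu": 29.0}, free_brightness={"Cnu": 1.0})
        iso = synthetic.simulate_isotherm(model, titrant_grid)
        np.testing.assert_allclose(iso.signal, 29.0, rtol=1e-12)

    def test_one_to_one_midpoint_at_K(self):
        # receptor far below K: half the receptor is bound at titrant = K
        model = EquilibriumModel(
            [Species("CnuH", (1, 1), 1.0 / 100.0, signal=1.0, brightness=1.0)],
            free_signal={"Cnu": 0.0}, free_brightness={"Cnu": 1.0})
        grid = np.geomspace(0.03, 1e4, 40)
        iso = synthetic.simulate_isotherm(model, grid, receptor_uM=0.01)
        mid = np.interp(100.0, iso.titrant_total_uM, iso.signal)
        assert mid == pytest.approx(0.5, abs=0.01)

    def test_strong_homodimer_produces_rollover(self, titrant_grid):
        model = EquilibriumModel(
            [Species("CnuH", (1, 1), 1.0 / 5.0, signal=29.2, brightness=1.0),
             Species("H2", (0, 2), 1.0 / 50.0, signal=28.3, brightness=0.05)],
            free_signal={"Cnu": 28.4, "H": 28.3},
            free_brightness={"Cnu": 1.0, "H": 0.005})
        iso = synthetic.simulate_isotherm(model, titrant_grid)
        i_max = np.argmax(iso.signal)
        assert i_max < iso.signal.size - 2
        assert iso.signal[-1] < iso.signal[i_max]


class TestMeltAndThermogram:
    def test_folded_fraction_is_half_at_tm(self):
        assert melt.folded_fraction(60.0, 60.0, 200.0) == pytest.approx(0.5)

    def test_noiseless_melt_roundtrip(self):
        curve = synthetic.simulate_melt(60.0, 200.0, np.arange(20, 96, 1.0))
        fit = melt.fit_two_state_melt(curve)
        assert fit.Tm_C == pytest.approx(60.0, abs=0.1)

    def test_excess_cp_peak_near_tm(self):
        t = np.arange(30, 96, 0.1)
        cp = melt.excess_heat_capacity(t, 65.0, 250.0, dCp_kJ_mol_K=0.0)
        assert t[np.argmax(cp)] == pytest.approx(65.0, abs=1.0)

    def test_tm_outside_range_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            synthetic.simulate_melt(95.0, 200.0, np.arange(20, 60, 1.0))


class TestAnisotropy:
    def test_no_association_limit_is_flat_at_r_mono(self):
        tit = synthetic.simulate_anisotropy_titration(np.inf, 0.06, 0.14,
                                                      tracer_uM=0.5)
        np.testing.assert_allclose(tit.anisotropy, 0.06)

    def test_midpoint_at_total_equal_kd(self):
        # m + 2 m^2/KD = KD has root m = KD/2: half the protomers dimeric
        r = binding.dimer_anisotropy(150.0, 150.0, 0.06, 0.14)
        assert r == pytest.approx(0.10, abs=1e-12)

    def test_noiseless_roundtrip_within_1_percent(self):
        tit = synthetic.simulate_anisotropy_titration(
            150.0, 0.06, 0.14, tracer_uM=2.0,
            titrant_uM=np.geomspace(0.03, 300.0, 25))
        fit = binding.fit_dimer_anisotropy(tit, tracer_uM=2.0, n_boot=0)
        assert fit.K_D_uM == pytest.approx(150.0, rel=0.01)

    def test_rejects_bad_anisotropy_ordering(self):
        with pytest.raises(ValueError):
            synthetic.simulate_anisotropy_titration(100.0, 0.2, 0.1)


class TestToyBundle:
    def test_zero_disorder_gives_identical_members(self):
        ens = synthetic.make_toy_bundle_ensemble(5, 0.0, seed=1)
        for m in ens.members[1:]:
            np.testing.assert_array_equal(m, ens.members[0])

    def test_h4_disorder_broadens_probe_pair_distance(self):
        rigid = synthetic.make_toy_bundle_ensemble(20, 0.0, seed=2)
        loose = synthetic.make_toy_bundle_ensemble(20, {"H4": 1.0}, seed=2)
        v0 = ensembles.distance_distribution(rigid, 40, 67).var()
        v1 = ensembles.distance_distribution(loose, 40, 67).var()
        assert v1 > v0

    def test_hull_volume_monotone_in_global_disorder(self):
        vols = []
        for d in (0.0, 0.5, 1.0):
            ens = synthetic.make_toy_bundle_ensemble(15, d, seed=3)
            vols.append(np.mean([ensembles.ensemble_volume(m)
                                 for m in ens.members]))
        assert vols[0] < vols[1] < vols[2]

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_toy_bundle_ensemble(0, 0.0)

    def test_reference_probe_pair_near_folded_distance(self):
        # the Tyr40-Trp67 analog sits close to the 11 A folded separation
        ens = synthetic.make_toy_bundle_ensemble(1, 0.0, seed=0)
        d = ensembles.distance_distribution(ens, 40, 67)[0]
        assert 8.0 < d < 14.0


def test_condition_registry_covers_headline_conditions(conditions):
    labels = set(conditions)
    assert {"IS14.5_T5", "IS14.5_T37", "IS170_T310K", "IS500_T310K"} <= labels
    for cfg in conditions.values():
        assert cfg.param("hill", "K_half_uM") > 0
        assert cfg.param("hill", "n_H") > 0


def test_fixture_config_validation():
    with pytest.raises(ValueError):
        FixtureConfig("x", -1.0, 25.0)
    with pytest.raises(ValueError):
        FixtureConfig("x", 100.0, 200.0)
    with pytest.raises(ValueError):
        FixtureConfig("x", 100.0, 25.0, model_params={"K_uM": -5.0})
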