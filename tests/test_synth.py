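"""Generator contracts: trapezoid curves, Gaussian patterns, AM synthesis."""

import numpy as np
import pytest

from fosemg.core import GridSpec, InvalidArgumentError, ProtocolSpec
from fosemg.preprocess import lowpass_envelope
from fosemg.synth import (
    lever_force,
    make_activation_curves,
    make_activation_patterns,
    simulate_study,
    split_load,
    synthesize_force,
    synthesize_hdsemg,
)


class TestActivationCurves:
    def test_exact_trapezoid_without_jitter(self):
        protocol = ProtocolSpec(target_level=0.4)
        curves = make_activation_curves(protocol, 2, shape_jitter=0.0, seed=0)
        assert curves.shape == (2, 6000)
        t = protocol.times
        # ramp midpoint (t = 1.5 s) reaches half the target
        mid = np.searchsorted(t, 1.5)
        assert curves[0, mid] == pytest.approx(0.2, abs=1e-9)
        # plateau is constant at the target
        plateau = curves[:, t >= 3.0]
        assert np.allclose(plateau, 0.4)
        assert curves[0, 0] == 0.0

    def test_jitter_bounded_by_fraction_of_target(self):
        protocol = ProtocolSpec(target_level=0.4)
        ideal = make_activation_curves(protocol, 3, 0.0, seed=7)
        jittered = make_activation_curves(protocol, 3, 0.1, seed=7)
        dev = np.max(np.abs(jittered - ideal)) / protocol.target_level
        assert dev <= 0.1 + 1e-12
        assert np.all(jittered >= 0)

    def test_deterministic_given_seed(self):
        protocol = ProtocolSpec()
        a = make_activation_curves(protocol, 2, 0.2, seed=3)
        b = make_activation_curves(protocol, 2, 0.2, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_plateau_drift_reaches_target_fraction(self):
        protocol = ProtocolSpec(target_level=0.5)
        curves = make_activation_curves(protocol, 1, 0.0, 0, plateau_drifts=[-0.4])
        assert curves[0, -1] == pytest.approx(0.5 * 0.6, abs=1e-3)
        assert curves[0, protocol.n_samples // 2] == pytest.approx(0.5, rel=1e-2)

    @pytest.mark.parametrize("bad", [0, -1])
    def test_invalid_component_count(self, bad):
        with pytest.raises(InvalidArgumentError):
            make_activation_curves(ProtocolSpec(), bad)

    def test_invalid_jitter(self):
        with pytest.raises(InvalidArgumentError):
            make_activation_curves(ProtocolSpec(), 1, shape_jitter=1.0)


class TestActivationPatterns:
    def test_peak_at_center_after_reshape(self, grid):
        centers = [(1, 2), (2, 5)]
        pats = make_activation_patterns(grid, 2, centers, width=1.0)
        for k, (r, c) in enumerate(centers):
            img = pats[:, k].reshape(grid.n_rows, grid.n_cols)
            assert np.unravel_index(np.argmax(img), img.shape) == (r, c)
            assert img[r, c] == pytest.approx(1.0)

    def test_zero_width_gives_indicator_plus_floor(self, grid):
        pats = make_activation_patterns(grid, 1, [(2, 3)], width=0.0, floor=0.02)
        col = pats[:, 0]
        peak = grid.channel_index(2, 3)
        assert col[peak] == pytest.approx(1.0)
        others = np.delete(col, peak)
        assert np.allclose(others, 0.02)

    def test_opposite_corners_weakly_correlated(self, grid):
        pats = make_activation_patterns(grid, 2, [(0, 0), (3, 7)], width=1.0)
        r = np.corrcoef(pats[:, 0], pats[:, 1])[0, 1]
        assert abs(r) < 0.2

    def test_center_outside_grid_rejected(self, grid):
        with pytest.raises(InvalidArgumentError):
            make_activation_patterns(grid, 1, [(5, 2)], width=1.0)


class TestSynthesizeHdsemg:
    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthesize_hdsemg(np.ones((32, 2)), np.ones((3, 100)))

    def test_zero_curves_yield_pure_noise(self):
        curves = np.zeros((1, 2000))
        pats = np.ones((32, 1))
        s = synthesize_hdsemg(pats, curves, noise_sd=0.1, seed=5)
        assert np.std(s.data) == pytest.approx(0.1, rel=0.05)
        s0 = synthesize_hdsemg(pats, curves, noise_sd=0.0, seed=5)
        assert np.allclose(s0.data, 0.0)

    def test_linearity_in_pattern_column(self):
        curves = np.full((1, 2000), 0.5)
        pats = np.linspace(0.2, 1.0, 32)[:, None]
        a = synthesize_hdsemg(pats, curves, noise_sd=0.0, seed=9)
        b = synthesize_hdsemg(2 * pats, curves, noise_sd=0.0, seed=9)
        np.testing.assert_allclose(b.data, 2 * a.data, rtol=1e-12)

    def test_single_component_channels_share_carrier(self):
        curves = np.ones((1, 3000))
        pats = np.ones((32, 1))
        s = synthesize_hdsemg(pats, curves, noise_sd=0.0, seed=2)
        np.testing.assert_allclose(s.data, np.tile(s.data[0], (32, 1)))
        # rectified+filtered channel tracks the directly filtered |carrier|
        env = lowpass_envelope(np.abs(s.data[0]), 1000.0)
        direct = lowpass_envelope(np.abs(s.data[0].copy()), 1000.0)
        np.testing.assert_allclose(env, direct)

    def test_demodulation_recovers_weighted_curve_sum(self, grid):
        protocol = ProtocolSpec()
        curves = make_activation_curves(protocol, 2, 0.0, 0, onset_delays=[0.0, 1.5])
        pats = make_activation_patterns(grid, 2, [(1, 2), (2, 5)], width=1.5)
        s = synthesize_hdsemg(pats, curves, noise_sd=0.0, seed=4)
        env = lowpass_envelope(np.abs(s.data), protocol.sampling_rate)
        target = pats @ curves
        for c in range(0, 32, 5):
            r = np.corrcoef(env[c], target[c])[0, 1]
            assert r >= 0.95

    def test_reproducible_bit_identical(self):
        curves = np.full((2, 1000), 0.3)
        pats = np.random.default_rng(0).uniform(0.1, 1, (32, 2))
        a = synthesize_hdsemg(pats, curves, noise_sd=0.05, seed=77)
        b = synthesize_hdsemg(pats, curves, noise_sd=0.05, seed=77)
        np.testing.assert_array_equal(a.data, b.data)


class TestSynthesizeForce:
    def test_bias_only_constant(self):
        h = np.linspace(0, 1, 100)
        y = synthesize_force(h, h, {"bias": 0.5})
        assert np.allclose(y, 0.5)

    def test_identity_coefficient(self):
        h_bi = np.linspace(0, 1, 50)
        h_tr = np.zeros(50)
        np.testing.assert_allclose(synthesize_force(h_bi, h_tr, {"H_BI": 1.0}), h_bi)

    def test_matches_direct_recomputation(self, rng):
        h_bi = rng.uniform(0, 1, 200)
        h_tr = rng.uniform(0, 1, 200)
        y = synthesize_force(h_bi, h_tr, {"H_BI": 0.5, "H_TR^2": 0.3})
        np.testing.assert_allclose(y, 0.5 * h_bi + 0.3 * h_tr**2, rtol=1e-12)

    def test_unknown_name_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthesize_force(np.ones(10), np.ones(10), {"H_BI^5": 1.0})


class TestLeverForce:
    @pytest.mark.parametrize(
        "f, le, lw, expected",
        [(10.0, 1.0, 1.0, -10.0), (0.0, 2.0, 3.0, 0.0), (6.0, 2.0, 3.0, -4.0)],
    )
    def test_moment_balance(self, f, le, lw, expected):
        assert lever_force(f, le, lw) == pytest.approx(expected)

    def test_zero_wrist_arm_rejected(self):
        with pytest.raises(InvalidArgumentError):
            lever_force(1.0, 1.0, 0.0)


class TestStudySimulation:
    def test_load_shares_sum_to_drive(self, rng):
        drive = np.linspace(0, 1, 500)
        comps = split_load(drive, 3, rng, (0.25, 0.75), 0.25)
        np.testing.assert_allclose(comps.sum(axis=0), drive, atol=1e-12)
        assert np.all(comps >= 0)

    def test_session_reproducible_and_consistent(self):
        protocol = ProtocolSpec(trial_duration=2.0, ramp_duration=1.0, n_repetitions=2)
        a = simulate_study(protocol=protocol, seed=5)
        b = simulate_study(protocol=protocol, seed=5)
        assert len(a.repetitions) == 2
        np.testing.assert_array_equal(a.repetitions[0].agonist.data, b.repetitions[0].agonist.data)
        np.testing.assert_array_equal(a.repetitions[1].force, b.repetitions[1].force)
        rep = a.repetitions[0]
        assert rep.agonist.data.shape == (32, protocol.n_samples)
        assert rep.h_bi_true.max() == pytest.approx(1.0)
        # noiseless check of the force composition on the true drives
        direct = synthesize_force(rep.h_bi_true, rep.h_tr_true, a.force_coeffs)
        assert np.sqrt(np.mean((direct - rep.force) ** 2)) < 0.05
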