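"""Fast-orthogonal-search contracts: pools, greedy selection, OLS equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fosemg.core import InvalidArgumentError
from fosemg.fos import (
    FosModel,
    basis_function,
    build_candidate_pool,
    build_candidate_pool_single,
    fos_fit,
    fos_predict,
    mse_reduction,
    sigm,
)

from conftest import smooth_positive_signal


def ols_fitted(columns: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent least-squares oracle: projection of y onto the columns."""
    coef, *_ = np.linalg.lstsq(columns.T, y, rcond=None)
    return columns.T @ coef


class TestCandidatePools:
    def test_dual_pool_has_fourteen_functions(self, rng):
        pool = build_candidate_pool(rng.uniform(0, 1, 100), rng.uniform(0, 1, 100))
        assert len(pool) == 14
        assert pool.names[0] == "bias"
        assert len(set(pool.names)) == 14

    def test_single_pool_has_six_functions(self, rng):
        pool = build_candidate_pool_single(rng.uniform(0, 1, 100))
        assert len(pool) == 6
        assert set(pool.names) == {"bias", "H", "H^2", "H^3", "sqrt(H)", "sigm(H)"}

    def test_equal_inputs_collapse_product_to_square(self, rng):
        h = rng.uniform(0, 1, 80)
        pool = build_candidate_pool(h, h)
        names = list(pool.names)
        np.testing.assert_allclose(
            pool.columns[names.index("H_BI*H_TR")],
            pool.columns[names.index("H_BI^2")],
        )

    def test_zero_antagonist_zeroes_product_sqrt(self, rng):
        pool = build_candidate_pool(rng.uniform(0, 1, 50), np.zeros(50))
        col = pool.columns[list(pool.names).index("sqrt(H_BI*H_TR)")]
        np.testing.assert_array_equal(col, np.zeros(50))

    def test_unit_interval_power_ordering(self, rng):
        h = rng.uniform(0, 1, 200)
        pool = build_candidate_pool_single(h)
        names = list(pool.names)
        h1 = pool.columns[names.index("H")]
        h2 = pool.columns[names.index("H^2")]
        h3 = pool.columns[names.index("H^3")]
        assert np.all(h3 <= h2 + 1e-15) and np.all(h2 <= h1 + 1e-15)

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_candidate_pool(np.array([-0.1, 0.5]), np.array([0.2, 0.3]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_candidate_pool(np.ones(5), np.ones(6))


class TestSigmoid:
    @given(st.floats(-30, 30), st.floats(-30, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        assert 0.0 < sigm(np.array(lo)) <= sigm(np.array(hi)) < 1.0


class TestFosFit:
    def test_constant_target_selects_bias_exactly(self, rng):
        h_bi = smooth_positive_signal(rng, 500)
        h_tr = smooth_positive_signal(rng, 500)
        pool = build_candidate_pool(h_bi, h_tr)
        model = fos_fit(np.full(500, 3.0), pool, max_functions=5)
        assert model.names == ("bias",)
        np.testing.assert_allclose(model.a, [3.0])
        assert model.training_rmsd_path[-1] < 1e-10

    def test_fitted_values_match_ols_oracle(self, rng):
        h_bi = smooth_positive_signal(rng, 400)
        h_tr = smooth_positive_signal(rng, 400)
        pool = build_candidate_pool(h_bi, h_tr)
        y = rng.standard_normal(400)
        model = fos_fit(y, pool, max_functions=6, rmsd_reduction_threshold=0.0)
        idx = [list(pool.names).index(n) for n in model.names]
        fitted = fos_predict(model, h_bi, h_tr)
        oracle = ols_fitted(pool.columns[idx], y)
        np.testing.assert_allclose(fitted, oracle, rtol=1e-8, atol=1e-10)

    def test_noiseless_pool_force_reaches_zero_rmsd(self, rng):
        h_bi = smooth_positive_signal(rng, 1000)
        h_tr = smooth_positive_signal(rng, 1000)
        pool = build_candidate_pool(h_bi, h_tr)
        names = list(pool.names)
        y = (
            0.4 * pool.columns[names.index("H_BI")]
            + 0.3 * pool.columns[names.index("H_TR^2")]
            + 0.1 * pool.columns[names.index("sqrt(H_BI)")]
        )
        model = fos_fit(y, pool)
        assert model.training_rmsd_path[-1] <= 1e-6

    def test_rmsd_path_strictly_decreasing_by_threshold(self, rng):
        h_bi = smooth_positive_signal(rng, 600)
        h_tr = smooth_positive_signal(rng, 600)
        pool = build_candidate_pool(h_bi, h_tr)
        y = 0.5 * h_bi + 0.2 * np.sqrt(h_tr) + 0.02 * rng.standard_normal(600)
        model = fos_fit(y, pool, max_functions=10, rmsd_reduction_threshold=0.2)
        path = model.training_rmsd_path
        assert np.all(np.diff(path) < 0)
        start = np.sqrt(np.mean(y**2)) * 100.0
        drops = -np.diff(np.concatenate([[start], path]))
        assert np.all(drops >= 0.2 - 1e-9)

    def test_duplicate_candidates_skipped_and_tie_broken_by_index(self, rng):
        h = smooth_positive_signal(rng, 300)
        pool = build_candidate_pool(h, h)  # H_BI and H_TR columns identical
        y = 2.0 * h
        model = fos_fit(y, pool, max_functions=14, rmsd_reduction_threshold=0.0)
        names = model.names
        assert "H_BI" in names and "H_TR" not in names  # lower index wins the tie
        assert model.diagnostics["terminated"] in ("all_collinear", "max_functions")

    def test_empty_pool_rejected(self, rng):
        h = smooth_positive_signal(rng, 100)
        pool = build_candidate_pool(h, h)
        with pytest.raises(InvalidArgumentError):
            fos_fit(np.ones(50), pool)  # length mismatch
        with pytest.raises(InvalidArgumentError):
            fos_fit(np.ones(100), pool, max_functions=0)


class TestMseReduction:
    def test_candidate_in_span_gives_zero(self, rng):
        q = rng.standard_normal(200)
        assert mse_reduction(2.5 * q, [q], rng.standard_normal(200)) == 0.0

    def test_self_projection_explains_everything(self, rng):
        y = rng.standard_normal(200)
        red = mse_reduction(y, [], y)
        assert red == pytest.approx(np.mean(y**2))

    def test_matches_refit_oracle(self, rng):
        cols = rng.standard_normal((4, 300))
        y = rng.standard_normal(300)
        # orthogonalize the first three sequentially as the selected set
        Q = []
        for c in cols[:3]:
            q = c.copy()
            for qr in Q:
                q -= (np.mean(q * qr) / np.mean(qr * qr)) * qr
            Q.append(q)
        fitted_before = ols_fitted(cols[:3], y)
        resid = y - fitted_before
        red = mse_reduction(cols[3], Q, resid)
        mse_before = np.mean(resid**2)
        mse_after = np.mean((y - ols_fitted(cols, y)) ** 2)
        assert red == pytest.approx(mse_before - mse_after, rel=1e-8, abs=1e-12)


class TestFosPredict:
    def test_training_inputs_reproduce_fitted_values(self, rng):
        h_bi = smooth_positive_signal(rng, 400)
        h_tr = smooth_positive_signal(rng, 400)
        pool = build_candidate_pool(h_bi, h_tr)
        y = 0.7 * h_bi + 0.1 + 0.01 * rng.standard_normal(400)
        model = fos_fit(y, pool)
        idx = [list(pool.names).index(n) for n in model.names]
        np.testing.assert_allclose(
            fos_predict(model, h_bi, h_tr), ols_fitted(pool.columns[idx], y), rtol=1e-8
        )

    def test_hand_built_model_arithmetic(self):
        model = FosModel(
            selected=[basis_function("bias"), basis_function("H_BI")],
            g=np.array([1.0, 2.0]),
            a=np.array([1.0, 2.0]),
            alpha=np.zeros((2, 2)),
            training_rmsd_path=np.array([0.0]),
            pool_kind="dual",
        )
        out = fos_predict(model, np.array([0.0, 0.5, 1.0]), np.zeros(3))
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])

    def test_single_pool_model_predicts_from_one_signal(self, rng):
        h = smooth_positive_signal(rng, 300)
        pool = build_candidate_pool_single(h)
        y = 0.3 * h + 0.2 * h**2
        model = fos_fit(y, pool)
        np.testing.assert_allclose(fos_predict(model, h), y, atol=1e-8)
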