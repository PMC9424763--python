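import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mc2s import (
    McrConfig,
    NoElbowError,
    compute_lof,
    elbow_region,
    mcr_als,
    nnls_solve,
    normalize_rows,
    project_reference,
    scan_k,
    aggregate_lof,
    simplisma_init,
)
from mc2s.mcr_core import LofCurve, initial_spectra

from conftest import matched_components, concentration_pearson


# mean-LOF-per-K table aggregated over the real MCARS cell datasets
# (percent; K = 1..15)
TABLE_MEAN_LOF = [0.481, 0.369, 0.262, 0.243, 0.214, 0.202, 0.20, 0.192,
                  0.193, 0.189, 0.186, 0.186, 0.186, 0.175, 0.175]


class TestComputeLof:
    def test_exact_factorization_is_zero(self):
        rng = np.random.default_rng(0)
        C = rng.random((6, 2))
        S = rng.random((2, 4))
        assert compute_lof(C @ S, C, S) == pytest.approx(0.0, abs=1e-12)

    def test_zero_model_gives_one(self):
        D = np.random.default_rng(1).random((5, 3))
        C = np.zeros((5, 2))
        S = np.zeros((2, 3))
        assert compute_lof(D, C, S) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        D = np.array([[2.0, 0.0], [0.0, 1.0]])
        C = np.array([[1.0], [0.0]])
        S = np.array([[2.0, 0.0]])
        assert compute_lof(D, C, S) == pytest.approx(np.sqrt(1 / 5))
        assert compute_lof(D, C, S, definition="plain") == pytest.approx(1 / 5)

    def test_all_zero_data_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            compute_lof(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros((1, 2)))


class TestNnlsSolve:
    def test_identity_system_returns_rhs(self):
        B = np.random.default_rng(0).random((4, 3))
        np.testing.assert_allclose(nnls_solve(np.eye(4), B), B, atol=1e-12)

    def test_inactive_constraint_matches_least_squares(self):
        A = np.array([[1.0], [1.0]])
        x = nnls_solve(A, np.array([1.0, 2.0]))
        assert x == pytest.approx([1.5])

    def test_fully_active_constraint_clamps_to_zero(self):
        A = np.array([[1.0], [1.0]])
        x = nnls_solve(A, np.array([-1.0, -2.0]))
        assert x == pytest.approx([0.0])

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            nnls_solve(np.zeros((2, 2)), np.ones(2))


class TestNormalizeRows:
    def test_examples_and_zero_row(self):
        C = np.array([[2.0, 2.0], [0.0, 0.0]])
        out = normalize_rows(C)
        np.testing.assert_allclose(out[0], [0.5, 0.5])
        np.testing.assert_array_equal(out[1], [0.0, 0.0])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            normalize_rows(np.array([[1.0, -0.5]]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 10), k=st.integers(1, 5))
    def test_nonzero_rows_sum_to_one(self, seed, m, k):
        C = np.random.default_rng(seed).random((m, k))
        C[C < 0.2] = 0.0
        out = normalize_rows(C)
        sums = out.sum(axis=1)
        nz = C.sum(axis=1) > 0
        np.testing.assert_allclose(sums[nz], 1.0, atol=1e-12)
        assert np.all(sums[~nz] == 0.0)


class TestSimplisma:
    def test_k1_matches_exhaustive_purity_scan(self):
        rng = np.random.default_rng(5)
        D = rng.random((20, 8))
        alpha = 0.05
        mu, sigma = D.mean(0), D.std(0)
        expected = int(np.argmax(sigma / (mu + alpha * mu.max())))
        _, idx = simplisma_init(D, 1, alpha)
        assert idx[0] == expected

    def test_single_source_columns_are_selected(self):
        # three sources, each loading exactly one distinct column strongly
        rng = np.random.default_rng(7)
        C = rng.random((50, 3))
        S = np.full((3, 6), 0.05)
        S[0, 1] = 1.0
        S[1, 4] = 1.0
        S[2, 2] = 1.0
        D = C @ S
        _, idx = simplisma_init(D, 3)
        assert set(idx) == {1, 4, 2}

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant|pure"):
            simplisma_init(np.ones((10, 4)), 2)

    def test_returns_nonnegative_spectra(self):
        D = np.random.default_rng(9).random((30, 10))
        S0, idx = simplisma_init(D, 3)
        assert S0.shape == (3, 10)
        assert np.all(S0 >= 0)
        assert len(set(idx.tolist())) == 3


class TestMcrAls:
    def test_noiseless_phantom_recovered(self, rank3_phantom):
        D, truth = rank3_phantom
        dec = mcr_als(D, McrConfig(K=3))
        assert dec.lof < 1e-3
        cos, perm = matched_components(dec.S_T, truth.S_true)
        assert np.all(cos > 0.99)

    def test_noise_floor_tracked_at_two_percent(self, rank3_noisy_phantom):
        D, truth = rank3_noisy_phantom
        D_clean = truth.C_true @ truth.S_true
        injected = np.sqrt(((D.values - D_clean) ** 2).sum()
                           / (D.values ** 2).sum())
        dec = mcr_als(D, McrConfig(K=3))
        assert dec.lof == pytest.approx(injected, rel=0.20)

    def test_invalid_k_rejected(self, rank3_phantom):
        D, _ = rank3_phantom
        with pytest.raises(ValueError):
            McrConfig(K=0)
        with pytest.raises(ValueError, match="exceeds"):
            mcr_als(D.values[:4, :3], McrConfig(K=5))

    def test_factors_nonnegative_and_rows_normalized(self, rank3_noisy_phantom):
        D, _ = rank3_noisy_phantom
        dec = mcr_als(D, McrConfig(K=3))
        assert np.all(dec.C >= 0)
        assert np.all(dec.S_T >= 0)
        sums = dec.C.sum(axis=1)
        np.testing.assert_allclose(sums[sums > 0], 1.0, atol=1e-9)

    def test_deterministic_bit_identical(self, rank3_noisy_phantom):
        D, _ = rank3_noisy_phantom
        d1 = mcr_als(D, McrConfig(K=3))
        d2 = mcr_als(D, McrConfig(K=3))
        assert np.array_equal(d1.C, d2.C)
        assert np.array_equal(d1.S_T, d2.S_T)
        assert d1.lof_history == d2.lof_history

    def test_final_lof_beats_one_pass_initialization(self, rank3_noisy_phantom):
        D, _ = rank3_noisy_phantom
        cfg = McrConfig(K=3)
        S0 = initial_spectra(D.values, cfg)
        C0 = normalize_rows(nnls_solve(S0.T, D.values.T).T)
        one_pass = compute_lof(D.values, C0, S0)
        dec = mcr_als(D, cfg)
        assert dec.lof <= one_pass + 1e-12


class TestProjectedGradientEquivalence:
    """ALS with exact NNLS subproblems vs a plain projected-gradient descent."""

    @staticmethod
    def projected_gradient(D, K, seed, n_iter=30_000):
        rng = np.random.default_rng(seed)
        M, N = D.shape
        C = normalize_rows(rng.random((M, K)))
        S = rng.random((K, N)) * D.max()
        for _ in range(n_iter):
            lr_c = 1.0 / max(np.linalg.norm(S @ S.T, 2), 1e-12)
            C = np.clip(C - lr_c * (C @ S - D) @ S.T, 0.0, None)
            C = normalize_rows(C)
            lr_s = 1.0 / max(np.linalg.norm(C.T @ C, 2), 1e-12)
            S = np.clip(S - lr_s * C.T @ (C @ S - D), 0.0, None)
        return compute_lof(D, C, S)

    def test_small_instance_equivalence(self):
        # exact bilinear 6x5 rank-2 data: both routes must reach LOF ~ 0
        rng = np.random.default_rng(42)
        C_true = normalize_rows(rng.random((6, 2)))
        S_true = rng.random((2, 5))
        D = C_true @ S_true
        als = mcr_als(D, McrConfig(K=2, max_iter=200, tol=1e-12)).lof
        pg = min(self.projected_gradient(D, 2, seed) for seed in range(5))
        assert abs(als - pg) < 1e-6

    def test_als_at_least_as_good_on_noisy_data(self):
        rng = np.random.default_rng(43)
        D = np.clip(rng.random((6, 5)) + 0.1, 0, None)
        als = mcr_als(D, McrConfig(K=2, max_iter=200, tol=1e-12)).lof
        pg = min(self.projected_gradient(D, 2, seed) for seed in range(5))
        assert als <= pg + 1e-6


class TestScanKAndAggregate:
    def test_lof_non_increasing_in_k_on_rank3(self, rank3_phantom):
        D, _ = rank3_phantom
        curve = scan_k(D, range(1, 6), McrConfig(K=1, max_iter=30))
        diffs = np.diff(curve.lof)
        assert np.all(diffs <= 1e-6)

    def test_single_dataset_sigma_is_zero(self):
        c = LofCurve(ks=[1, 2, 3], lof=[0.5, 0.3, 0.2])
        ks, mu, sigma = aggregate_lof([c])
        np.testing.assert_array_equal(sigma, 0.0)
        np.testing.assert_allclose(mu, c.lof)

    def test_identical_datasets_mean_equals_single_curve(self):
        c = LofCurve(ks=[1, 2], lof=[0.4, 0.1])
        _, mu, sigma = aggregate_lof([c, c])
        np.testing.assert_allclose(mu, c.lof)
        np.testing.assert_array_equal(sigma, 0.0)

    def test_mismatching_grids_rejected(self):
        a = LofCurve(ks=[1, 2], lof=[0.4, 0.1])
        b = LofCurve(ks=[1, 3], lof=[0.4, 0.1])
        with pytest.raises(ValueError):
            aggregate_lof([a, b])


class TestElbowRegion:
    def test_published_mean_lof_table_brackets_4_to_6(self):
        lo, hi = elbow_region(range(1, 16), TABLE_MEAN_LOF)
        assert (lo, hi) == (4, 6)

    def test_single_large_drop_matches_distance_oracle(self):
        ks = [1, 2, 3, 4, 5]
        y = [1.0, 0.9, 0.1, 0.08, 0.06]
        # oracle: chord from (1, 1) to (5, 0.06); the largest below-chord
        # distance falls at K=3 and no neighbor is within 90% of it
        chord = np.interp(ks, [1, 5], [1.0, 0.06])
        dist = chord - np.array(y)
        k_star = ks[int(np.argmax(dist))]
        assert elbow_region(ks, y) == (k_star, k_star)

    def test_exactly_linear_curve_flags_no_elbow(self):
        with pytest.raises(NoElbowError):
            elbow_region(range(1, 8), np.linspace(1.0, 0.3, 7))

    def test_increasing_curve_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            elbow_region([1, 2, 3, 4], [0.1, 0.5, 0.4, 0.3])


class TestProjectReference:
    def test_recovers_known_concentrations(self):
        rng = np.random.default_rng(3)
        S_ref = rng.random((3, 20)) + 0.1
        C_ref = normalize_rows(rng.random((30, 3)))
        D = C_ref @ S_ref
        C = project_reference(D, S_ref)
        np.testing.assert_allclose(C, C_ref, atol=1e-6)

    def test_channel_basis_gives_normalized_intensities(self):
        D = np.random.default_rng(4).random((10, 3))
        C = project_reference(D, np.eye(3))
        np.testing.assert_allclose(C, D / D.sum(1, keepdims=True), atol=1e-10)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            project_reference(np.ones((4, 5)), np.ones((2, 6)))
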