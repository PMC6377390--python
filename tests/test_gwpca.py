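import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gwclhs import (
    GridSpec,
    bandwidth_cv,
    bisquare_weight,
    gw_std,
    gwpca_fit,
    local_eigen,
    local_scores,
    local_weighted_cov,
    make_stack,
    make_two_regime_stack,
    select_components,
    stack_to_table,
    standardize,
    winning_variable,
)
from gwclhs.gwpca import (
    BandwidthTooSmallError,
    GWPCAResult,
    KernelSpec,
    StandardizationParams,
    UNIFORM,
)

from .conftest import toy_table


class TestBisquare:
    def test_closed_forms(self):
        assert bisquare_weight(0.0, 2.0) == 1.0
        assert bisquare_weight(2.0, 2.0) == 0.0
        assert bisquare_weight(1.0, 2.0) == 0.5625

    def test_compact_support(self):
        assert bisquare_weight(5.0, 2.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bisquare_weight(1.0, 0.0)
        with pytest.raises(ValueError):
            bisquare_weight(-1.0, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(d=st.floats(0, 10), b1=st.floats(0.1, 10), b2=st.floats(0.1, 10))
    def test_enlarging_bandwidth_never_decreases_weight(self, d, b1, b2):
        lo, hi = sorted([b1, b2])
        assert bisquare_weight(d, hi) >= bisquare_weight(d, lo)


class TestStandardize:
    def test_two_point_closed_form(self):
        t = toy_table(np.array([[1.0], [3.0]]))
        Z, params = standardize(t)
        assert np.allclose(Z.ravel(), [-0.70710678, 0.70710678])
        assert params.sd[0] == pytest.approx(np.sqrt(2))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = toy_table(rng.normal(size=(50, 2)))
        Z1, _ = standardize(t)
        Z2, _ = standardize(toy_table(Z1))
        assert np.allclose(Z1, Z2, atol=1e-12)

    def test_constant_column_named(self):
        t = toy_table(np.column_stack([np.ones(5), np.arange(5.0)]))
        with pytest.raises(ValueError, match="'a'"):
            standardize(t)


class TestLocalWeightedCov:
    def test_uniform_weights_reduce_to_population_cov(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        cov = local_weighted_cov(X, np.ones(30))
        assert np.allclose(cov, np.cov(X.T, ddof=0))

    def test_single_row_weight_gives_zero_matrix(self):
        X = np.arange(12.0).reshape(4, 3)
        w = np.array([0.0, 1.0, 0.0, 0.0])
        assert np.allclose(local_weighted_cov(X, w), 0.0)

    def test_two_point_variance(self):
        cov = local_weighted_cov(np.array([[-1.0], [1.0]]), np.array([1.0, 1.0]))
        assert cov[0, 0] == pytest.approx(1.0)

    def test_zero_weights_error(self):
        with pytest.raises(ValueError, match="empty neighborhood"):
            local_weighted_cov(np.ones((3, 1)), np.zeros(3))


class TestGwStd:
    def test_unnormalized_as_printed(self):
        assert gw_std(np.array([1.0, 3.0]), np.array([1.0, 1.0])) == pytest.approx(np.sqrt(2))

    def test_constant_values_give_zero(self):
        assert gw_std(np.full(5, 2.0), np.random.default_rng(0).random(5)) == 0.0

    def test_normalized_uniform_equals_population_sd(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        assert gw_std(x, np.ones_like(x), normalized=True) == pytest.approx(x.std())


class TestLocalEigen:
    def test_identity(self):
        vals, vecs = local_eigen(np.eye(3))
        assert np.allclose(vals, 1.0)
        assert np.allclose(vecs @ vecs.T, np.eye(3), atol=1e-12)

    def test_rank_one_closed_form(self):
        vals, vecs = local_eigen(np.ones((2, 2)))
        assert np.allclose(vals, [2.0, 0.0], atol=1e-12)
        assert np.allclose(vecs[:, 0], [0.70710678, 0.70710678])

    def test_random_2x2_matches_characteristic_roots(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c = rng.normal(size=3)
            M = np.array([[a, c], [c, b]])
            tr, det = a + b, a * b - c * c
            disc = np.sqrt(tr**2 - 4 * det)
            expected = np.array([(tr + disc) / 2, (tr - disc) / 2])
            vals, _ = local_eigen(M)
            # characteristic-polynomial oracle (quadratic formula)
            assert np.allclose(vals, np.where(np.abs(expected) < 1e-10, 0, expected), atol=1e-10)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            local_eigen(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_sign_convention_largest_element_positive(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(4, 4))
        _, vecs = local_eigen(A @ A.T)
        for m in range(4):
            i = np.argmax(np.abs(vecs[:, m]))
            assert vecs[i, m] > 0


class TestGwpcaFit:
    def test_uniform_weights_equal_global_pca(self, homogeneous_table):
        from sklearn.decomposition import PCA

        res = gwpca_fit(homogeneous_table, KernelSpec(family=UNIFORM))
        Z, _ = standardize(homogeneous_table)
        pca = PCA().fit(Z)
        V = pca.components_.T
        for m in range(V.shape[1]):
            i = np.argmax(np.abs(V[:, m]))
            if V[i, m] < 0:
                V[:, m] = -V[:, m]
        assert np.abs(res.eigenvalues - pca.explained_variance_).max() < 1e-8
        assert np.abs(res.loadings - V).max() < 1e-8
        S = local_scores(res, homogeneous_table, Z.shape[1])
        assert np.abs(S - Z @ V).max() < 1e-8

    def test_eigenvalues_sum_to_p_everywhere(self, homogeneous_table):
        res = gwpca_fit(homogeneous_table, KernelSpec(bandwidth=800.0))
        p = len(homogeneous_table.continuous_names)
        assert np.abs(res.eigenvalues.sum(axis=1) - p).max() < 1e-8
        assert np.all(np.diff(res.eigenvalues, axis=1) <= 1e-12)

    def test_repeated_fits_bit_identical(self, homogeneous_table):
        a = gwpca_fit(homogeneous_table, KernelSpec(bandwidth=800.0))
        b = gwpca_fit(homogeneous_table, KernelSpec(bandwidth=800.0))
        assert np.array_equal(a.loadings, b.loadings)

    def test_bandwidth_too_small_names_location(self, homogeneous_table):
        with pytest.raises(BandwidthTooSmallError, match="cell_id"):
            gwpca_fit(homogeneous_table, KernelSpec(bandwidth=110.0))

    def test_two_regime_recovery(self, grid40):
        stack, truth = make_two_regime_stack(grid40, p=4, seed=1)
        table = stack_to_table(stack)
        bw = 800.0
        res = gwpca_fit(table, KernelSpec(bandwidth=bw))
        x, _ = grid40.cell_centers(res.cell_ids)
        split_x = grid40.x_origin + truth.split_col * grid40.cell_size
        lead = res.loadings[:, :, 0]
        for direction, sel in (
            (truth.west_direction, x < split_x - 2 * bw),
            (truth.east_direction, x > split_x + 2 * bw),
        ):
            cos = np.abs(lead[sel] @ direction)
            assert np.mean(cos > 0.9) >= 0.9


class TestComponentSelection:
    @staticmethod
    def _result(eigenvalues):
        eigenvalues = np.asarray(eigenvalues, float)
        n, p = eigenvalues.shape
        return GWPCAResult(
            cell_ids=np.arange(n), eigenvalues=eigenvalues,
            loadings=np.broadcast_to(np.eye(p), (n, p, p)).copy(),
            kernel=KernelSpec(), grid=GridSpec(1, n, 1.0, 0.0, 1.0),
            standardization=StandardizationParams(
                names=tuple(f"v{j}" for j in range(p)), mean=np.zeros(p), sd=np.ones(p)),
        )

    def test_boundary_eigenvalue_one_is_retained(self):
        res = self._result(np.ones((10, 4)))
        assert select_components(res) == 4

    def test_perfectly_correlated_pair_keeps_one(self):
        t = toy_table(np.column_stack([np.arange(20.0), 2 * np.arange(20.0)]))
        res = gwpca_fit(t, KernelSpec(family=UNIFORM))
        assert np.allclose(res.eigenvalues[0], [2.0, 0.0], atol=1e-10)
        assert select_components(res) == 1

    def test_dominant_common_factor_keeps_one(self, grid40):
        # pairwise correlation 0.9 across p=3 -> population eigenvalues 2.8, 0.1, 0.1
        stack = make_stack(grid40, n_continuous=3, range_=0.0, common=0.9, seed=8)
        res = gwpca_fit(stack_to_table(stack), KernelSpec(family=UNIFORM))
        assert select_components(res) == 1

    def test_no_qualifying_component_warns_and_keeps_one(self):
        res = self._result(np.full((5, 3), 0.9))
        with pytest.warns(UserWarning):
            assert select_components(res) == 1


class TestScoresAndWinners:
    def test_full_rank_scores_preserve_norm(self, homogeneous_table):
        res = gwpca_fit(homogeneous_table, KernelSpec(bandwidth=1500.0))
        Z, _ = standardize(homogeneous_table)
        S = local_scores(res, homogeneous_table, Z.shape[1])
        assert np.abs(np.linalg.norm(S, axis=1) - np.linalg.norm(Z, axis=1)).max() < 1e-8

    def test_score_layers_roughly_centered(self):
        grid = GridSpec(20, 20, 100.0, 0.0, 2000.0)
        means = []
        for seed in range(10):
            t = stack_to_table(make_stack(grid, n_continuous=3, seed=seed))
            res = gwpca_fit(t, KernelSpec(bandwidth=900.0))
            S = local_scores(res, t, 1)
            means.append(S.mean())
        assert abs(np.mean(means)) < 0.1

    def test_winning_variable_codes_in_range(self, homogeneous_table):
        res = gwpca_fit(homogeneous_table, KernelSpec(bandwidth=800.0))
        win = winning_variable(res)
        codes = win.values[~win.missing]
        assert set(np.unique(codes)) <= set(range(len(homogeneous_table.continuous_names)))

    def test_two_regime_hub_wins_its_half(self, grid40):
        stack, truth = make_two_regime_stack(grid40, p=4, seed=2)
        res = gwpca_fit(stack_to_table(stack), KernelSpec(bandwidth=800.0))
        win = winning_variable(res).values
        margin = 8  # 2 bandwidths from the split
        assert np.mean(win[:, : truth.split_col - margin] == 0) >= 0.9
        assert np.mean(win[:, truth.split_col + margin :] == 1) >= 0.9


class TestBandwidthCV:
    def test_deterministic_and_order_invariant(self, grid40):
        t = stack_to_table(make_stack(grid40, n_continuous=4, range_=0.0, common=0.6, seed=1))
        cands = [600.0, 1200.0, 2400.0]
        a = bandwidth_cv(t, k=1, candidates=cands, seed=7)
        b = bandwidth_cv(t, k=1, candidates=cands[::-1], seed=7)
        assert a.selected == b.selected
        assert np.array_equal(a.scores, b.scores)

    def test_homogeneous_stack_selects_largest(self):
        grid = GridSpec(30, 30, 100.0, 0.0, 3000.0)
        t = stack_to_table(make_stack(grid, n_continuous=4, range_=0.0, common=0.6, seed=2))
        cv = bandwidth_cv(t, k=1, candidates=[400.0, 800.0, 1500.0, 3000.0],
                          subsample_frac=1.0, seed=2)
        assert cv.selected == 3000.0
        assert cv.scores[0] > cv.scores[-1]

    def test_two_regime_selects_local_bandwidth(self, grid40):
        stack, _ = make_two_regime_stack(grid40, p=4, seed=1)
        cv = bandwidth_cv(stack_to_table(stack), k=1, subsample_frac=0.25,
                          candidates=[500.0, 1000.0, 2000.0, 4000.0], seed=1)
        assert cv.selected < 4000.0  # domain width

    def test_starved_candidate_scores_inf(self, grid40):
        t = stack_to_table(make_stack(grid40, n_continuous=4, seed=3))
        with pytest.warns(UserWarning, match="too small"):
            cv = bandwidth_cv(t, k=1, candidates=[120.0, 1200.0], seed=0)
        assert np.isinf(cv.scores[0]) and cv.selected == 1200.0
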