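import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from sgae.graph import (
    DegenerateBatchError,
    build_adjacency,
    make_batch_graph,
    normalize_adjacency,
    offdiag_nonzero_fraction,
    pairwise_distance,
    quantile_threshold,
    sharpen_adjacency,
    solve_bandwidth,
    underflow_constant,
)


def _dense(W):
    return np.asarray(W.todense()) if sp.issparse(W) else np.asarray(W)


class TestPairwiseDistance:
    def test_3_4_5_triangle(self):
        d = pairwise_distance(np.array([[0.0, 0], [3, 4]]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_metric_axioms(self):
        pts = np.random.default_rng(0).normal(size=(12, 3))
        d = pairwise_distance(pts)
        assert np.all(np.diag(d) == 0)
        np.testing.assert_allclose(d, d.T)

    def test_matches_double_loop_oracle(self):
        pts = np.random.default_rng(1).normal(size=(10, 5))
        d = pairwise_distance(pts)
        oracle = np.zeros((10, 10))
        for u in range(10):
            for v in range(10):
                oracle[u, v] = np.sqrt(((pts[u] - pts[v]) ** 2).sum())
        np.testing.assert_allclose(d, oracle, atol=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="batch too small"):
            pairwise_distance(np.array([[1.0, 2.0]]))


class TestUnderflowConstant:
    @pytest.mark.parametrize("precision,expected", [("single", -104), ("double", -746)])
    def test_probed_values_on_ieee_hardware(self, precision, expected):
        assert underflow_constant(precision) == expected

    @pytest.mark.parametrize("precision,dtype", [("single", np.float32), ("double", np.float64)])
    def test_defining_property(self, precision, dtype):
        m = underflow_constant(precision)
        assert np.exp(dtype(m)) == 0
        assert np.exp(dtype(m + 1)) > 0


class TestQuantileThreshold:
    def test_textbook_median(self):
        # off-diagonal population 1..100 each appearing twice (symmetry)
        n = 101
        D = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        vals = D[~np.eye(n, dtype=bool)]
        assert quantile_threshold(D, 0.5) == pytest.approx(np.median(vals))

    def test_small_tau_approaches_min(self):
        pts = np.random.default_rng(2).normal(size=(20, 2))
        D = pairwise_distance(pts)
        off = D[~np.eye(20, dtype=bool)]
        assert quantile_threshold(D, 1e-9) == pytest.approx(off.min(), rel=1e-6)

    def test_matches_sorting_oracle(self):
        pts = np.random.default_rng(3).normal(size=(50, 4))
        D = pairwise_distance(pts)
        off = np.sort(D[~np.eye(50, dtype=bool)])
        # linear-interpolation quantile computed by hand
        h = 0.07 * (off.size - 1)
        lo, frac = int(np.floor(h)), h - np.floor(h)
        expected = off[lo] * (1 - frac) + off[min(lo + 1, off.size - 1)] * frac
        assert quantile_threshold(D, 0.07) == pytest.approx(expected, rel=1e-12)

    def test_duplicate_points_degenerate(self):
        D = np.zeros((4, 4))
        with pytest.raises(DegenerateBatchError):
            quantile_threshold(D, 0.5)

    def test_include_diagonal_mode_differs(self):
        pts = np.random.default_rng(4).normal(size=(10, 2))
        D = pairwise_distance(pts)
        assert quantile_threshold(D, 0.5, include_diagonal=True) < quantile_threshold(D, 0.5)


class TestSolveBandwidth:
    def test_closed_form(self):
        l = solve_bandwidth(2.0, -104)
        assert l == pytest.approx(np.sqrt(4 / 208))
        assert -(2.0**2) / (2 * l * l) == pytest.approx(-104)

    def test_unit_bandwidth_identity(self):
        m = -50
        assert solve_bandwidth(np.sqrt(-2 * m), m) == pytest.approx(1.0)

    def test_scale_equivariance(self):
        assert solve_bandwidth(6.0, -104) == pytest.approx(2 * solve_bandwidth(3.0, -104))

    def test_zero_quantile_rejected(self):
        with pytest.raises(DegenerateBatchError):
            solve_bandwidth(0.0, -104)


class TestBuildAdjacency:
    def test_zero_distance_gives_unit_weight(self):
        D = np.array([[0.0, 0.0], [0.0, 0.0]])
        W = build_adjacency(D, l=1.0)
        np.testing.assert_array_equal(_dense(W), np.ones((2, 2)))

    def test_threshold_distance_is_exact_zero(self):
        pts = np.random.default_rng(5).normal(size=(30, 2))
        D = pairwise_distance(pts)
        d_tau = quantile_threshold(D, 0.07)
        # plant an entry exactly at the threshold
        D[0, 1] = D[1, 0] = d_tau
        l = solve_bandwidth(d_tau, underflow_constant("single"))
        W = _dense(build_adjacency(D, l, precision="single", d_tau=d_tau))
        assert W[0, 1] == 0.0
        inside = (D < d_tau) & ~np.eye(30, dtype=bool)
        assert np.all(W[inside] > 0)
        assert np.all(W[~inside & ~np.eye(30, dtype=bool)] == 0)

    def test_tau_sparsity_200_random_points(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(size=(200, 2))
        D = pairwise_distance(pts)
        d_tau = quantile_threshold(D, 0.07)
        l = solve_bandwidth(d_tau, underflow_constant("single"))
        W = build_adjacency(D, l, precision="single", d_tau=d_tau)
        assert 0.06 <= offdiag_nonzero_fraction(W) <= 0.08

    def test_kernel_monotone_in_distance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 3))
        D = pairwise_distance(pts)
        d_tau = quantile_threshold(D, 0.3)
        l = solve_bandwidth(d_tau, underflow_constant("double"))
        W = _dense(build_adjacency(D, l, precision="double", d_tau=d_tau))
        order = np.argsort(D[0])
        w_sorted = W[0, order]
        assert np.all(np.diff(w_sorted) <= 1e-300)

    def test_sparse_above_dense_below_cutoff(self):
        D = pairwise_distance(np.random.default_rng(8).normal(size=(65, 2)))
        assert sp.issparse(build_adjacency(D, 1.0))
        D = pairwise_distance(np.random.default_rng(8).normal(size=(10, 2)))
        assert isinstance(build_adjacency(D, 1.0), np.ndarray)


class TestMakeBatchGraph:
    def test_identical_inputs_identical_views(self):
        x = np.random.default_rng(9).normal(size=(30, 2))
        g = make_batch_graph(x, x)
        np.testing.assert_array_equal(_dense(g.W_e), _dense(g.W_p))
        assert g.l_e == g.l_p

    def test_duplicate_locations_degenerate(self):
        pcs = np.random.default_rng(10).normal(size=(10, 3))
        coords = np.ones((10, 2))
        with pytest.raises(DegenerateBatchError, match="spatial"):
            make_batch_graph(pcs, coords)

    def test_sparsity_invariant_both_views(self):
        rng = np.random.default_rng(11)
        g = make_batch_graph(rng.normal(size=(500, 50)), rng.uniform(size=(500, 2)))
        for W in (g.W_e, g.W_p):
            assert offdiag_nonzero_fraction(W) == pytest.approx(0.07, abs=0.005)

    def test_coordinate_scale_leaves_weights_unchanged(self):
        rng = np.random.default_rng(12)
        pcs, coords = rng.normal(size=(60, 5)), rng.uniform(size=(60, 2))
        g1 = make_batch_graph(pcs, coords)
        g2 = make_batch_graph(pcs, coords * 37.5)
        assert g2.l_p == pytest.approx(37.5 * g1.l_p)
        np.testing.assert_allclose(_dense(g2.W_p), _dense(g1.W_p), rtol=1e-5, atol=1e-30)

    def test_diagonal_is_exactly_one(self):
        rng = np.random.default_rng(13)
        g = make_batch_graph(rng.normal(size=(80, 4)), rng.uniform(size=(80, 2)))
        np.testing.assert_array_equal(_dense(g.W_e).diagonal(), np.ones(80))


class TestNormalizeAdjacency:
    def test_identity_fixed_point(self):
        np.testing.assert_array_equal(normalize_adjacency(np.eye(3), "sym_degree"), np.eye(3))

    def test_hand_computed_2x2(self):
        W = np.ones((2, 2))
        np.testing.assert_allclose(normalize_adjacency(W, "sym_degree"), np.full((2, 2), 0.5))

    def test_none_is_passthrough(self):
        W = np.random.default_rng(14).random((5, 5))
        assert normalize_adjacency(W, "none") is W

    def test_sym_degree_spectral_radius(self):
        rng = np.random.default_rng(15)
        W = rng.random((20, 20))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        Wn = normalize_adjacency(W, "sym_degree")
        assert np.max(np.abs(np.linalg.eigvalsh(Wn))) <= 1 + 1e-10

    def test_sparse_matches_dense(self):
        rng = np.random.default_rng(16)
        W = rng.random((10, 10))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        dense = normalize_adjacency(W, "sym_degree")
        sparse = normalize_adjacency(sp.csr_matrix(W), "sym_degree")
        np.testing.assert_allclose(_dense(sparse), dense, atol=1e-12)


class TestSharpenAdjacency:
    def test_identity_maps_to_2I(self):
        np.testing.assert_array_equal(sharpen_adjacency(np.eye(4)), 2 * np.eye(4))

    def test_complement_identity_and_involution(self):
        rng = np.random.default_rng(17)
        W = rng.random((8, 8))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)  # adjacency diagonal is exactly 1
        S = sharpen_adjacency(W)
        np.testing.assert_array_equal(W + S, 3 * np.eye(8))
        np.testing.assert_array_equal(sharpen_adjacency(S), W)

    def test_sparse_input(self):
        W = sp.identity(5, format="csr")
        np.testing.assert_array_equal(_dense(sharpen_adjacency(W)), 2 * np.eye(5))


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=5, max_value=40))
def test_tau_sparsity_property(seed, n):
    """For distinct distances the nonzero fraction deviates from tau by at most
    the quantile interpolation granularity 2/(n(n-1))."""
    rng = np.random.default_rng(seed)
    tau = float(rng.uniform(0.05, 0.5))
    pts = rng.normal(size=(n, 3))
    D = pairwise_distance(pts)
    d_tau = quantile_threshold(D, tau)
    l = solve_bandwidth(d_tau, underflow_constant("double"))
    W = build_adjacency(D, l, precision="double", d_tau=d_tau)
    frac = offdiag_nonzero_fraction(W)
    assert abs(frac - tau) <= 2.0 / (n * (n - 1)) + 1e-12
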