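"""Dimensionality estimation, eigenmaps, normalisation, alignment, averaging."""

import numpy as np
import pytest
from scipy import sparse
from scipy.stats import spearmanr

from connectopy.connectopic_mapping import (
    ConnectopicMap,
    align_map,
    align_to_reference,
    common_dimension,
    estimate_intrinsic_dimension,
    group_average,
    laplacian_eigenmaps,
    normalize_map,
)
from connectopy.similarity_graph import NeighbourGraph, graph_laplacian


def dense_generalized_eig_oracle(lap, deg):
    """Independent route: symmetric standard problem via D^{-1/2} scaling."""
    d = np.diag(deg)
    s = 1.0 / np.sqrt(d)
    m = (lap * s[None, :]) * s[:, None]
    m = (m + m.T) / 2
    vals, vecs = np.linalg.eigh(m)
    return vals, vecs * s[:, None]


def random_connected_graph(rng, n):
    w = np.zeros((n, n))
    perm = rng.permutation(n)  # spanning path guarantees connectivity
    for a, b in zip(perm, perm[1:]):
        w[a, b] = w[b, a] = rng.uniform(0.2, 1.0)
    extra = rng.random((n, n)) < 0.15
    vals = rng.uniform(0.1, 1.0, size=(n, n))
    w = np.maximum(w, np.triu(extra * vals, 1))
    w = np.maximum(w, w.T)
    return NeighbourGraph(weights=sparse.csr_matrix(w), k_used=1)


class TestIntrinsicDimension:
    def test_plane_in_five_dimensions(self):
        rng = np.random.default_rng(0)
        basis = np.linalg.qr(rng.normal(size=(5, 2)))[0]
        points = rng.uniform(size=(1000, 2)) @ basis.T
        est = estimate_intrinsic_dimension(points, 8, 20)
        assert 1.6 <= est <= 2.4

    def test_noisy_line(self):
        rng = np.random.default_rng(1)
        points = np.linspace(0, 10, 1000)[:, None] * np.ones((1, 4))
        points += rng.normal(0, 0.01, size=points.shape)
        est = estimate_intrinsic_dimension(points, 8, 20)
        assert 0.8 <= est <= 1.5

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        points = rng.normal(size=(300, 3))
        a = estimate_intrinsic_dimension(points, 5, 10)
        b = estimate_intrinsic_dimension(1e4 * points, 5, 10)
        assert a == pytest.approx(b, abs=1e-12)

    def test_duplicate_points_warn(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(50, 3))
        points[10] = points[11]
        with pytest.warns(RuntimeWarning, match="duplicate"):
            est = estimate_intrinsic_dimension(points, 3, 5)
        assert est > 0

    def test_all_duplicates_rejected(self):
        with pytest.raises(ValueError):
            estimate_intrinsic_dimension(np.ones((30, 3)), 3, 5)


class TestCommonDimension:
    @pytest.mark.parametrize(
        "estimates, expected",
        [([3.4, 3.1, 4.0], 3), ([0.7], 1), ([3.0, 3.0], 3), ([1.2, 9.9], 1)],
    )
    def test_floor_of_minimum(self, estimates, expected):
        assert common_dimension(estimates) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            common_dimension([])


class TestLaplacianEigenmaps:
    def test_path_graph_fiedler_vector_monotone(self):
        w = np.diag(np.ones(4), 1)
        w = w + w.T
        g = NeighbourGraph(weights=sparse.csr_matrix(w), k_used=1)
        lap, deg = graph_laplacian(g)
        vecs, vals = laplacian_eigenmaps(lap, deg, 1)
        diffs = np.diff(vecs[:, 0])
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_matches_dense_oracle_up_to_sign(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(8, 50))
            g = random_connected_graph(rng, n)
            lap, deg = graph_laplacian(g)
            m = min(4, n - 2)
            vecs, vals = laplacian_eigenmaps(lap, deg, m)
            ovals, ovecs = dense_generalized_eig_oracle(lap, deg)
            np.testing.assert_allclose(vals, ovals[1 : m + 1], atol=1e-8)
            for j in range(m):
                o = ovecs[:, j + 1]
                o = o / np.linalg.norm(o) * np.linalg.norm(vecs[:, j])
                err = min(
                    np.abs(vecs[:, j] - o).max(), np.abs(vecs[:, j] + o).max()
                )
                assert err < 1e-6

    def test_d_orthogonality(self):
        rng = np.random.default_rng(7)
        g = random_connected_graph(rng, 30)
        lap, deg = graph_laplacian(g)
        vecs, _ = laplacian_eigenmaps(lap, deg, 5)
        gram = vecs.T @ deg @ vecs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_eigenvalues_strictly_positive_and_sorted(self):
        rng = np.random.default_rng(8)
        g = random_connected_graph(rng, 25)
        lap, deg = graph_laplacian(g)
        _, vals = laplacian_eigenmaps(lap, deg, 5)
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) >= 0)

    def test_m_out_of_range_rejected(self):
        g = random_connected_graph(np.random.default_rng(9), 10)
        lap, deg = graph_laplacian(g)
        with pytest.raises(ValueError):
            laplacian_eigenmaps(lap, deg, 10)


class TestNormalizeMap:
    def test_affine_endpoints_and_midpoint(self):
        np.testing.assert_allclose(
            normalize_map([0.2, 0.5, 0.8]), [1.0, 5.5, 10.0]
        )

    def test_two_points(self):
        np.testing.assert_allclose(normalize_map([-1.0, 1.0]), [1.0, 10.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        once = normalize_map(v)
        np.testing.assert_allclose(normalize_map(once), once, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_map([3.0, 3.0, 3.0])


class TestAlignment:
    def test_perfect_anticorrelation_flipped_back(self):
        ref = normalize_map(np.arange(20.0))
        target = 11.0 - ref
        np.testing.assert_allclose(align_to_reference(ref, target), ref, atol=1e-12)

    def test_identical_map_unchanged(self):
        ref = normalize_map(np.arange(20.0))
        np.testing.assert_allclose(align_to_reference(ref, ref), ref)

    def test_correlation_above_threshold_passes_through(self):
        # construct a target with r ≈ 0.8 to the reference
        rng = np.random.default_rng(1)
        base = np.arange(100.0)
        noisy = base + rng.normal(0, 20, size=100)
        ref = normalize_map(base)
        target = normalize_map(noisy)
        r = np.corrcoef(ref, target)[0, 1]
        assert 0.75 <= r < 0.9
        np.testing.assert_allclose(align_to_reference(ref, target), target)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            align_to_reference(np.ones(5), normalize_map(np.arange(5.0)))


def _map_from(values, m=1):
    values = np.column_stack([normalize_map(values[:, j]) for j in range(m)])
    return ConnectopicMap(values=values, eigenvalues=np.arange(1, m + 1, dtype=float))


class TestGroupAverage:
    def test_identical_maps_average_to_themselves(self):
        rng = np.random.default_rng(0)
        m = _map_from(rng.normal(size=(40, 2)), m=2)
        grp = group_average([m, m, m])
        np.testing.assert_allclose(grp.values, m.values, atol=1e-12)

    def test_map_and_exact_flip_average_is_degenerate(self):
        rng = np.random.default_rng(1)
        m = _map_from(rng.normal(size=(40, 1)))
        flipped = ConnectopicMap(values=11.0 - m.values, eigenvalues=m.eigenvalues)
        with pytest.raises(ValueError, match="constant"):
            group_average([m, flipped])

    def test_averaging_noisy_copies_beats_individuals(self):
        rng = np.random.default_rng(2)
        truth = np.linspace(0, 1, 200)
        maps = [
            _map_from((truth + rng.normal(0, 0.5, size=200))[:, None]) for _ in range(10)
        ]
        grp = group_average(maps)
        rho_group = abs(spearmanr(grp.mode(0), truth).statistic)
        rho_each = [abs(spearmanr(m.mode(0), truth).statistic) for m in maps]
        assert rho_group > np.median(rho_each)

    def test_sign_flip_invariance_through_alignment(self):
        """Flipping any subject's eigenvector sign must not change the group map."""
        rng = np.random.default_rng(3)
        truth = np.linspace(0, 1, 100)
        maps = [
            _map_from((truth + rng.normal(0, 0.1, size=100))[:, None])
            for _ in range(5)
        ]
        ref = maps[0]
        grp1 = group_average([align_map(ref, m) for m in maps])
        flipped = [
            ConnectopicMap(values=11.0 - m.values, eigenvalues=m.eigenvalues)
            if i in (1, 3)
            else m
            for i, m in enumerate(maps)
        ]
        grp2 = group_average([align_map(ref, m) for m in flipped])
        np.testing.assert_allclose(grp1.values, grp2.values, atol=1e-10)
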