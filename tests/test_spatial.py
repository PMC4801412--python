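"""Spatial weights, Moran's I, correlograms, PCNM and filter selection."""

import numpy as np
import pytest

import betascape as bs
from betascape.exceptions import InvalidSpecError, UndefinedStatisticError
from betascape.spatial import (
    SpatialWeights,
    moran_permutation_pvalue,
    pairwise_distances,
)
from conftest import brute_force_morans_i


class TestQueenWeights:
    def test_2x2_all_land_has_12_links(self):
        g = bs.build_grid(0, 0, 2, 2, 1.0)
        w = bs.queen_weights(g)
        assert w.matrix.nnz == 12  # each of 4 cells adjacent to the other 3

    def test_1x3_strip_degrees(self):
        g = bs.build_grid(0, 0, 1, 3, 1.0)
        w = bs.queen_weights(g)
        deg = np.asarray(w.matrix.sum(axis=1)).ravel()
        assert deg.tolist() == [1, 2, 1]

    def test_random_mask_symmetric_zero_diagonal(self, rng):
        mask = rng.random((6, 6)) < 0.7
        mask[0, 0] = mask[0, 1] = True  # ensure at least one adjacency
        g = bs.build_grid(0, 0, 6, 6, 1.0, mask)
        w = bs.queen_weights(g)
        assert (abs(w.matrix - w.matrix.T)).nnz == 0
        assert not w.matrix.diagonal().any()

    def test_too_few_land_cells(self):
        g = bs.build_grid(0, 0, 2, 2, 1.0, np.eye(2, dtype=bool) * [[1, 0], [0, 0]])
        with pytest.raises(InvalidSpecError):
            bs.queen_weights(g)


class TestMoransI:
    def _rook_2x2(self):
        W = np.array(
            [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]], dtype=float
        )
        return SpatialWeights(n=4, matrix=W, scheme="rook")

    def test_checkerboard_is_minus_one(self):
        # cells in row-major order: (+1, -1, -1, +1)
        w = self._rook_2x2()
        x = np.array([1.0, -1.0, -1.0, 1.0])
        assert bs.morans_i(x, w) == pytest.approx(-1.0)

    def test_constant_field_raises(self):
        w = self._rook_2x2()
        with pytest.raises(UndefinedStatisticError):
            bs.morans_i(np.ones(4), w)

    def test_matches_dense_double_sum_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 20))
            W = rng.random((n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            x = rng.normal(size=n)
            w = SpatialWeights(n=n, matrix=W, scheme="queen")
            assert bs.morans_i(x, w) == pytest.approx(
                brute_force_morans_i(x, W), abs=1e-12
            )

    def test_missing_values_restrict_weights(self, rng):
        g = bs.build_grid(0, 0, 5, 5, 1.0)
        w = bs.queen_weights(g)
        vals = rng.normal(size=g.n_land)
        missing = np.zeros(g.n_land, bool)
        missing[[0, 7]] = True
        f = bs.CellField(g, vals, missing=missing)
        keep = ~missing
        sub = w.restrict(keep)
        assert bs.morans_i(f, w) == pytest.approx(bs.morans_i(vals[keep], sub))


class TestCorrelogram:
    def test_1x3_strip_two_classes(self):
        g = bs.build_grid(0, 0, 1, 3, 1.0)
        f = bs.CellField(g, np.array([1.0, 5.0, 2.0]))
        rows = bs.correlogram(f, g, n_classes=2, n_permutations=19, seed=0, metric="degrees")
        # classes partition (0, 2]: the two d=1 pairs, then the d=2 pair
        assert [r.n_pairs for r in rows] == [2, 1]

    def test_gradient_sign_pattern(self, rng):
        """A strong gradient field shows positive autocorrelation in the
        first class and negative in the largest-distance classes."""
        g = bs.build_grid(0, 0, 10, 10, 1.0)
        vals = g.land_rc.sum(axis=1).astype(float) + rng.normal(0, 0.1, g.n_land)
        f = bs.CellField(g, vals)
        rows = bs.correlogram(f, g, n_classes=5, n_permutations=99, seed=1)
        assert rows[0].morans_i > 0
        assert rows[-1].morans_i < 0

    def test_deterministic_given_seed(self, rng):
        g = bs.build_grid(0, 0, 6, 6, 1.0)
        f = bs.CellField(g, rng.normal(size=g.n_land))
        r1 = bs.correlogram(f, g, n_classes=3, n_permutations=99, seed=42)
        r2 = bs.correlogram(f, g, n_classes=3, n_permutations=99, seed=42)
        assert [(r.morans_i, r.p_value) for r in r1] == [(r.morans_i, r.p_value) for r in r2]


def prim_mst_longest_edge(D):
    """O(n^2) Prim oracle returning the longest MST edge."""
    n = len(D)
    in_tree = [0]
    best = 0.0
    dist = D[0].copy()
    dist[0] = np.inf
    for _ in range(n - 1):
        j = int(np.argmin(dist))
        best = max(best, dist[j])
        dist[j] = np.inf
        for k in range(n):
            if dist[k] != np.inf:
                dist[k] = min(dist[k], D[j, k])
        in_tree.append(j)
    return best


class TestMstTruncation:
    def test_regular_transect_spacing(self):
        coords = np.column_stack([np.zeros(10), np.arange(10) * 2.0])
        assert bs.mst_truncation(coords, metric="degrees") == pytest.approx(2.0)

    def test_two_clusters_bridge_edge(self):
        lon = np.r_[np.arange(5) * 0.1, 50 + np.arange(5) * 0.1]
        coords = np.column_stack([np.zeros(10), lon])
        assert bs.mst_truncation(coords, metric="degrees") == pytest.approx(50 - 0.4)

    def test_matches_prim_oracle(self, rng):
        for _ in range(10):
            coords = rng.uniform(0, 10, size=(int(rng.integers(5, 25)), 2))
            D = pairwise_distances(coords, "degrees")
            assert bs.mst_truncation(coords, metric="degrees") == pytest.approx(
                prim_mst_longest_edge(D)
            )


class TestPcnm:
    def test_columns_centered_and_orthogonal(self, rng):
        coords = rng.uniform(0, 5, size=(25, 2))
        fs = bs.pcnm(coords, metric="degrees")
        V = fs.eigenvectors
        assert np.abs(V.mean(axis=0)).max() < 1e-10
        G = V.T @ V
        assert np.abs(G - np.eye(fs.k)).max() < 1e-8

    def test_eigenvalues_non_increasing_and_positive(self, rng):
        coords = rng.uniform(0, 5, size=(20, 2))
        fs = bs.pcnm(coords, metric="degrees")
        assert (np.diff(fs.eigenvalues) <= 1e-9).all()
        assert (fs.eigenvalues > 0).all()

    def test_transect_leading_eigenvector_is_broad_arch(self):
        """On a regular transect the leading eigenvector is the broadest
        spatial wave, a half-period-cosine-like arch (|r| = 0.868 against
        the pure cosine; the truncated matrix flattens the ends relative
        to an untruncated PCoA, whose score would correlate at 0.99)."""
        n = 50
        coords = np.column_stack([np.zeros(n), np.arange(n, dtype=float)])
        fs = bs.pcnm(coords, metric="degrees")
        cosine = np.cos(np.pi * (np.arange(n) + 0.5) / n)
        r = np.corrcoef(fs.eigenvectors[:, 0], cosine)[0, 1]
        assert abs(r) > 0.85
        # and no retained eigenvector beats it: the arch is the leading scale
        rs = [
            abs(np.corrcoef(fs.eigenvectors[:, j], cosine)[0, 1]) for j in range(fs.k)
        ]
        assert int(np.argmax(rs)) == 0

    def test_small_case_matches_dense_eigensolver(self, rng):
        coords = rng.uniform(0, 3, size=(6, 2))
        t = bs.mst_truncation(coords, metric="degrees")
        fs = bs.pcnm(coords, t=t, metric="degrees")
        # independent oracle: rebuild the Gower matrix and use eigh directly
        D = pairwise_distances(coords, "degrees")
        D = np.where(D > t, 4 * t, D)
        np.fill_diagonal(D, 0)
        A = -0.5 * D**2
        J = np.eye(6) - np.ones((6, 6)) / 6
        G = J @ A @ J
        vals, vecs = np.linalg.eigh(G)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        keep = vals > 1e-9 * vals.max()
        assert np.allclose(fs.eigenvalues, vals[keep], atol=1e-8)
        for j in range(fs.k):
            r = abs(np.corrcoef(fs.eigenvectors[:, j], vecs[:, j])[0, 1])
            assert r > 1 - 1e-8

    def test_gower_reconstruction(self, rng):
        coords = rng.uniform(0, 4, size=(18, 2))
        t = bs.mst_truncation(coords, metric="degrees")
        fs = bs.pcnm(coords, t=t, metric="degrees")
        D = pairwise_distances(coords, "degrees")
        D = np.where(D > t, 4 * t, D)
        np.fill_diagonal(D, 0)
        A = -0.5 * D**2
        n = len(coords)
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ A @ J
        vals, vecs = np.linalg.eigh(G)
        pos = vals > 1e-9 * vals.max()
        G_pos = vecs[:, pos] @ np.diag(vals[pos]) @ vecs[:, pos].T
        recon = fs.eigenvectors @ np.diag(fs.eigenvalues) @ fs.eigenvectors.T
        assert np.abs(recon - G_pos).max() / np.abs(G_pos).max() < 1e-6

    def test_too_few_cells(self):
        with pytest.raises(InvalidSpecError):
            bs.pcnm(np.zeros((2, 2)), metric="degrees")


class TestSelectFilters:
    def _setup(self, n=50):
        grid = bs.build_grid(0, 0, 1, n, 1.0)
        coords = grid.land_centers()
        fs = bs.pcnm(coords, metric="degrees")
        w = bs.queen_weights(grid)
        return fs, w

    def test_white_noise_selects_nothing_much(self, rng):
        fs, w = self._setup()
        y = rng.normal(size=50)
        sel = bs.select_filters(y, fs, w, seed=0)
        assert len(sel.indices) <= 2
        # residual essentially the raw (centered) response
        assert np.corrcoef(sel.residuals, y - y.mean())[0, 1] > 0.9

    def test_recovers_planted_eigenvector(self, rng):
        fs, w = self._setup()
        y = 3.0 * fs.eigenvectors[:, 0] + rng.normal(0, 0.2, 50)
        sel = bs.select_filters(y, fs, w, seed=0, n_permutations=199)
        assert sel.indices[0] == 0
        assert sel.final_p_value is not None and sel.final_p_value >= 0.05

    def test_moran_path_non_increasing_in_magnitude(self, rng):
        fs, w = self._setup()
        y = 2.0 * fs.eigenvectors[:, 1] + rng.normal(0, 0.5, 50)
        sel = bs.select_filters(y, fs, w, seed=3)
        mags = [abs(v) for v in sel.moran_path]
        assert all(m2 <= m1 + 1e-12 for m1, m2 in zip(mags, mags[1:]))

    def test_deterministic_given_seed(self, rng):
        fs, w = self._setup()
        y = fs.eigenvectors[:, 2] + rng.normal(0, 0.5, 50)
        s1 = bs.select_filters(y, fs, w, seed=7)
        s2 = bs.select_filters(y, fs, w, seed=7)
        assert s1.indices == s2.indices and s1.final_p_value == s2.final_p_value


class TestMoranPermutationCalibration:
    def test_pvalue_uniformity_smoke(self, rng):
        """Type-I behavior of the two-sided permutation p at alpha=0.2 on a
        quick white-noise batch (the full calibration at alpha=0.05 with
        999 permutations runs in the acceptance suite)."""
        g = bs.build_grid(0, 0, 5, 5, 1.0)
        w = bs.queen_weights(g)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            p = moran_permutation_pvalue(rng.normal(size=g.n_land), w, 99, rng)
            hits += p <= 0.2
        assert 0.1 <= hits / n_rep <= 0.3
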