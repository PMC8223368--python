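"""Moran's I and Getis-Ord Gi* against brute-force oracles."""

import numpy as np
import pytest

from spatepi.cluster_stats import (classify_hotspots, getis_ord_gistar,
                                   moran_permutation, morans_i)
from spatepi.weights import SpatialWeights, build_weights


def brute_force_moran(y, W):
    """O(n^2) double-sum evaluation of the Moran's I formula."""
    y = np.asarray(y, float)
    n = y.size
    M = W.to_sparse().toarray()
    yb = y.mean()
    num = sum(M[i, j] * (y[i] - yb) * (y[j] - yb)
              for i in range(n) for j in range(n))
    return n * num / (M.sum() * ((y - yb) ** 2).sum())


def rook_grid_weights(rows, cols):
    ids = np.arange(rows * cols)
    nbrs, wts = [], []
    for r in range(rows):
        for c in range(cols):
            nb = []
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    nb.append(rr * cols + cc)
            nbrs.append(np.array(nb))
            wts.append(np.ones(len(nb)))
    return SpatialWeights(ids, nbrs, wts)


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        W = rook_grid_weights(2, 2)
        y = np.array([1.0, -1.0, -1.0, 1.0])
        res = morans_i(y, W)
        assert res.I == pytest.approx(-1.0, abs=1e-12)
        assert res.expected_I == pytest.approx(-1 / 3)

    def test_expected_value_closed_form(self):
        # n = 617 locations gives E[I] = -1/616
        assert morans_i(
            np.arange(10, dtype=float), rook_grid_weights(2, 5)
        ).expected_I == pytest.approx(-1 / 9)
        assert -1 / (617 - 1) == pytest.approx(-0.0016234, abs=5e-7)

    def test_linear_gradient_positive_autocorrelation(self):
        lon = np.arange(10, dtype=float) * 0.01
        lat = np.zeros(10)
        W = build_weights(lon, lat, method="distance_band",
                          param=1.2)  # ~1.11 km spacing
        res = morans_i(lon, W)
        assert res.I > 0
        assert res.I == pytest.approx(brute_force_moran(lon, W), abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        lon, lat = rng.uniform(0, 3, n), rng.uniform(0, 3, n)
        W = build_weights(lon, lat, method="knn", param=4,
                          row_standardize=seed % 2 == 0)
        y = rng.normal(size=n)
        assert morans_i(y, W).I == pytest.approx(brute_force_moran(y, W),
                                                 abs=1e-10)

    def test_location_and_scale_invariance(self, random_points):
        lon, lat = random_points
        W = build_weights(lon, lat, method="knn", param=4)
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(lon))
        base = morans_i(y, W)
        shifted = morans_i(y + 100.0, W)
        scaled = morans_i(3.5 * y, W)
        assert shifted.I == pytest.approx(base.I, abs=1e-10)
        assert scaled.I == pytest.approx(base.I, abs=1e-10)
        assert shifted.z == pytest.approx(base.z, abs=1e-8)

    def test_constant_values_raise(self):
        W = rook_grid_weights(2, 2)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(4), W)

    def test_n_mismatch_raises(self):
        with pytest.raises(ValueError):
            morans_i(np.arange(5, dtype=float), rook_grid_weights(2, 2))


class TestMoranPermutation:
    def test_rank_formula_extreme(self):
        # strong gradient: observed I should beat all 999 permutations
        lon = np.arange(20, dtype=float) * 0.01
        lat = np.zeros(20)
        W = build_weights(lon, lat, method="knn", param=2)
        p = moran_permutation(lon, W, n_perm=999, seed=0)
        assert p == pytest.approx(0.001)

    def test_seeded_reproducibility(self, random_points):
        lon, lat = random_points
        W = build_weights(lon, lat, method="knn", param=4)
        y = np.random.default_rng(1).normal(size=len(lon))
        p1 = moran_permutation(y, W, n_perm=99, seed=42)
        p2 = moran_permutation(y, W, n_perm=99, seed=42)
        assert p1 == p2

    def test_permutation_mean_near_expected(self):
        # mean of permuted I over many permutations ~ -1/(n-1)
        rng = np.random.default_rng(2)
        n = 30
        lon, lat = rng.uniform(0, 3, n), rng.uniform(0, 3, n)
        W = build_weights(lon, lat, method="knn", param=4)
        y = rng.normal(size=n)
        Wsp = W.to_sparse()
        z = y - y.mean()
        scale = n / (Wsp.sum() * (z @ z))
        perms = np.array([scale * float(zp @ (Wsp @ zp))
                          for zp in (rng.permutation(z) for _ in range(3000))])
        se = perms.std() / np.sqrt(perms.size)
        assert abs(perms.mean() - (-1 / (n - 1))) < 3 * se

    def test_too_few_permutations_raise(self, random_points):
        lon, lat = random_points
        W = build_weights(lon, lat, method="knn", param=4)
        with pytest.raises(ValueError):
            moran_permutation(np.arange(len(lon), dtype=float), W, n_perm=50)


def gistar_direct(x, M):
    """Independent direct-formula evaluation of Gi* for dense weights M."""
    x = np.asarray(x, float)
    n = x.size
    xbar = x.mean()
    S = np.sqrt((x ** 2).sum() / n - xbar ** 2)
    z = np.empty(n)
    for i in range(n):
        w = M[i]
        num = (w * x).sum() - xbar * w.sum()
        den = S * np.sqrt((n * (w ** 2).sum() - w.sum() ** 2) / (n - 1))
        z[i] = num / den
    return z


class TestGiStar:
    def test_lone_high_value_matches_direct_oracle(self):
        # centre point high, symmetric ring of zeros, plus a distant group
        # so no window spans the whole study area
        theta = np.linspace(0, 2 * np.pi, 9)[:-1]
        lon = np.concatenate([[0.0], 0.5 * np.cos(theta),
                              [5.0, 5.1, 5.2, 5.05, 5.15]])
        lat = np.concatenate([[0.0], 0.5 * np.sin(theta),
                              [0.0, 0.1, 0.0, 0.15, 0.05]])
        x = np.zeros(14)
        x[0] = 1.0
        W = build_weights(lon, lat, method="distance_band", param=60.0,
                          include_self=True)
        res = getis_ord_gistar(x, W)
        want = gistar_direct(x, W.to_sparse().toarray())
        np.testing.assert_allclose(res.z, want, atol=1e-10)
        # the windows containing the lone high value all score positive
        assert np.all(res.z[:9] > 0)

    def test_random_field_matches_direct_oracle(self, random_points):
        lon, lat = random_points
        W = build_weights(lon, lat, method="knn", param=5, include_self=True)
        x = np.random.default_rng(4).normal(size=len(lon))
        res = getis_ord_gistar(x, W)
        np.testing.assert_allclose(res.z, gistar_direct(x, W.to_sparse().toarray()),
                                   atol=1e-10)

    def test_exchangeable_values_mean_z_near_zero(self, random_points):
        lon, lat = random_points
        W = build_weights(lon, lat, method="knn", param=5, include_self=True)
        rng = np.random.default_rng(8)
        means = [getis_ord_gistar(rng.normal(size=len(lon)), W).z.mean()
                 for _ in range(50)]
        assert abs(np.mean(means)) < 0.05

    def test_shift_and_scale_invariance(self, random_points):
        lon, lat = random_points
        W = build_weights(lon, lat, method="knn", param=5, include_self=True)
        x = np.random.default_rng(4).normal(size=len(lon))
        base = getis_ord_gistar(x, W).z
        np.testing.assert_allclose(getis_ord_gistar(x + 7, W).z, base, atol=1e-9)
        np.testing.assert_allclose(getis_ord_gistar(2 * x, W).z, base, atol=1e-9)

    def test_constant_values_raise_not_zero(self, random_points):
        lon, lat = random_points
        W = build_weights(lon, lat, method="knn", param=5, include_self=True)
        with pytest.raises(ValueError, match="constant"):
            getis_ord_gistar(np.full(len(lon), 0.3), W)

    def test_requires_self_inclusive_weights(self, random_points):
        lon, lat = random_points
        W = build_weights(lon, lat, method="knn", param=5)
        with pytest.raises(ValueError, match="self"):
            getis_ord_gistar(np.arange(len(lon), dtype=float), W)


class TestClassification:
    @pytest.mark.parametrize("z,want", [
        (0.0, "not-significant"), (2.0, "hot95"), (-3.0, "cold99"),
        (1.7, "hot90"), (-1.7, "cold90"), (2.6, "hot99"), (-2.0, "cold95"),
    ])
    def test_default_bins(self, z, want):
        assert classify_hotspots([z])[0] == want

    def test_fdr_gate_blocks_non_discoveries(self):
        z = np.array([2.5, -2.5, 3.0])
        cats = classify_hotspots(z, p_values=np.full(3, 0.5), fdr=True)
        assert list(cats) == ["not-significant"] * 3

    def test_non_monotone_thresholds_raise(self):
        with pytest.raises(ValueError):
            classify_hotspots([1.0], thresholds=(2.0, 1.9, 2.5))
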