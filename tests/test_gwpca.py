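import numpy as np
import pytest

from spectroclust.gwpca import (
    GWPCAError,
    KernelSpec,
    bisquare_weight,
    choose_n_components,
    distance_matrix,
    fit_gwpca,
    global_pca,
    haversine_km,
    local_covariance,
    local_eigen,
    select_bandwidth,
    standardize,
    _loo_score,
)
from spectroclust.spectral_data import to_absorbance
from spectroclust.synthetic_scene import generate_scene, preset_config


class TestBisquare:
    @pytest.mark.parametrize(
        "d, b, w", [(0.0, 5.0, 1.0), (5.0, 5.0, 0.0), (2.5, 5.0, 0.5625)]
    )
    def test_kernel_values(self, d, b, w):
        assert bisquare_weight(d, b) == pytest.approx(w, abs=1e-12)

    def test_vectorized_in_unit_interval(self, rng):
        w = bisquare_weight(rng.uniform(0, 10, 100), 4.0)
        assert np.all((w >= 0) & (w <= 1))
        assert np.all(w[rng.uniform(0, 10, 100) >= 4.0] >= 0)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(GWPCAError):
            bisquare_weight(1.0, 0.0)


class TestHaversine:
    def test_symmetric_zero_diagonal(self, rng):
        coords = rng.uniform([-10, 35], [20, 60], (15, 2))
        D = haversine_km(coords, coords)
        np.testing.assert_allclose(D, D.T, atol=1e-9)
        assert np.all(np.diag(D) == 0)
        off = D[~np.eye(15, dtype=bool)]
        assert np.all(off > 0)

    def test_one_degree_latitude(self):
        d = haversine_km(np.array([[0.0, 0.0]]), np.array([[0.0, 1.0]]))[0, 0]
        assert d == pytest.approx(111.19, rel=1e-3)


class TestLocalCovariance:
    def test_uniform_weights_equal_population_covariance(self, rng):
        X = rng.standard_normal((30, 4))
        S = local_covariance(X, np.ones(30))
        np.testing.assert_allclose(S, np.cov(X, rowvar=False, ddof=0), atol=1e-12)

    def test_single_sample_mass_gives_zero_matrix(self, rng):
        X = rng.standard_normal((10, 3))
        w = np.zeros(10)
        w[4] = 2.0
        np.testing.assert_allclose(local_covariance(X, w), 0.0, atol=1e-14)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.standard_normal((6, 3))
        w = rng.uniform(0.1, 2.0, 6)
        S = local_covariance(X, w)
        wn = w / w.sum()
        mu = sum(wn[i] * X[i] for i in range(6))
        expected = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                expected[a, b] = sum(
                    wn[i] * (X[i, a] - mu[a]) * (X[i, b] - mu[b]) for i in range(6)
                )
        np.testing.assert_allclose(S, expected, atol=1e-12)

    def test_zero_weights_rejected(self, rng):
        with pytest.raises(GWPCAError):
            local_covariance(rng.standard_normal((5, 2)), np.zeros(5))


class TestLocalEigen:
    def test_diagonal_matrix(self):
        L, V = local_eigen(np.diag([3.0, 1.0, 0.5]), 3)
        np.testing.assert_allclose(V, [3.0, 1.0, 0.5], atol=1e-12)

    def test_analytic_two_by_two(self):
        L, V = local_eigen(np.array([[2.0, 1.0], [1.0, 2.0]]), 2)
        np.testing.assert_allclose(V, [3.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(L[:, 0]), np.sqrt(0.5), atol=1e-12)

    def test_roots_of_characteristic_polynomial(self, rng):
        A = rng.standard_normal((3, 3))
        S = A @ A.T
        _, V = local_eigen(S, 3)
        # independent oracle: eigenvalues as roots of det(S - x I)
        c2 = -np.trace(S)
        c1 = 0.5 * (np.trace(S) ** 2 - np.trace(S @ S))
        c0 = -np.linalg.det(S)
        roots = np.sort(np.roots([1.0, c2, c1, c0]).real)[::-1]
        np.testing.assert_allclose(V, roots, atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        A = rng.standard_normal((4, 4))
        S = A @ A.T
        L, V = local_eigen(S, 4)
        np.testing.assert_allclose(L @ np.diag(V) @ L.T, S, atol=1e-8)

    def test_k_too_large_rejected(self):
        with pytest.raises(GWPCAError):
            local_eigen(np.eye(3), 4)


class TestChooseComponents:
    def test_perfectly_correlated_bands_give_one(self, rng):
        base = rng.standard_normal(200)
        X = standardize(np.column_stack([base, 2 * base, -base]))
        assert choose_n_components(X) == 1

    def test_independent_bands_match_eigen_oracle(self, rng):
        X = standardize(rng.standard_normal((500, 6)))
        vals = np.linalg.eigvalsh(np.cov(X, rowvar=False, ddof=0))
        assert choose_n_components(X) == max(1, int((vals > 1).sum()))

    def test_single_band_floor(self, rng):
        X = standardize(rng.standard_normal((50, 1)))
        assert choose_n_components(X) == 1


class TestBandwidthSelection:
    def test_two_regions_select_sub_gap_bandwidth(self, rng):
        n1 = 40
        coords = np.vstack(
            [
                np.column_stack([rng.normal(0, 0.3, n1), rng.normal(0, 0.3, n1)]),
                np.column_stack([rng.normal(8, 0.3, n1), rng.normal(0, 0.3, n1)]),
            ]
        )
        t = rng.standard_normal(2 * n1)
        X = np.zeros((2 * n1, 3))
        X[:n1, 0] = t[:n1]
        X[:n1, 1] = t[:n1]  # region A: bands 1, 2 co-vary
        X[n1:, 0] = t[n1:]
        X[n1:, 1] = -t[n1:]  # region B: anti-covary
        X[:, 2] = rng.normal(0, 0.1, 2 * n1)
        X += rng.normal(0, 0.05, X.shape)
        ks = select_bandwidth(standardize(X), coords, 1, metric="euclidean")
        assert ks.bandwidth < 8.0

    def test_homogeneous_scene_flat_score_at_saturation(self):
        ds, _, _ = generate_scene(
            preset_config("homogeneous", seed=2).replace(n_per_cluster=(80,))
        )
        X = standardize(to_absorbance(ds).values[:, ::10])
        D = distance_matrix(ds.coords, "euclidean")
        dmax = D.max()
        scores = [
            _loo_score(X, D, 2, KernelSpec(mult * dmax, metric="euclidean"))
            for mult in (2, 4, 10)
        ]
        assert (max(scores) - min(scores)) / min(scores) < 0.01

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(GWPCAError):
            select_bandwidth(rng.standard_normal((4, 2)), rng.random((4, 2)), 3)

    def test_coincident_points_rejected(self, rng):
        with pytest.raises(GWPCAError):
            select_bandwidth(
                rng.standard_normal((10, 2)), np.zeros((10, 2)), 1,
                metric="euclidean",
            )


class TestFitGWPCA:
    def test_infinite_bandwidth_recovers_global_pca(self, small_scene):
        ds, _, _ = small_scene
        dsa = to_absorbance(ds)
        res = fit_gwpca(dsa, 3, KernelSpec(1e9, metric="haversine"))
        X = standardize(dsa.values)
        Lg, Vg = global_pca(X, 3)
        np.testing.assert_allclose(
            res.eigenvalues, np.tile(Vg, (ds.n_samples, 1)), rtol=1e-6
        )
        np.testing.assert_allclose(res.scores, X @ Lg, atol=1e-6 * np.abs(X @ Lg).max())

    def test_eigenvalue_rows_non_increasing(self, small_scene):
        ds, _, _ = small_scene
        res = fit_gwpca(to_absorbance(ds), 3, KernelSpec(300.0))
        assert np.all(np.diff(res.eigenvalues, axis=1) <= 1e-12)
        assert np.all(res.eigenvalues >= 0)
        assert np.all(np.isfinite(res.scores))

    def test_eigenvalue_sum_equals_local_trace(self, small_scene):
        ds, _, _ = small_scene
        dsa = to_absorbance(ds)
        k = dsa.n_bands // 10
        sub = dsa.replace(values=dsa.values[:, ::10],
                          wavelengths=dsa.wavelengths[::10])
        res = fit_gwpca(sub, sub.n_bands, KernelSpec(500.0))
        # full-rank eigenvalue sum = trace of the local covariance
        X = standardize(sub.values)
        D = distance_matrix(sub.coords, "haversine")
        for i in range(0, sub.n_samples, 40):
            w = bisquare_weight(D[i], 500.0)
            S = local_covariance(X[w > 0], w[w > 0])
            assert res.eigenvalues[i].sum() == pytest.approx(
                np.trace(S), abs=1e-8 * max(1, np.trace(S))
            )

    def test_local_loadings_unit_norm(self, small_scene):
        ds, _, _ = small_scene
        res = fit_gwpca(to_absorbance(ds), 2, KernelSpec(300.0))
        norms = np.linalg.norm(res.loadings, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)

    def test_sign_alignment_makes_scores_continuous(self, small_scene):
        ds, labels, _ = small_scene
        dsa = to_absorbance(ds)
        # duplicate one sample at an almost identical location
        j = 5
        values = np.vstack([dsa.values, dsa.values[j]])
        coords = np.vstack([dsa.coords, dsa.coords[j] + 1e-9])
        dup = dsa.replace(
            values=values,
            coords=coords,
            ids=np.append(dsa.ids, "dup"),
            target=np.append(dsa.target, dsa.target[j]),
        )
        res = fit_gwpca(dup, 3, KernelSpec(300.0))
        np.testing.assert_allclose(res.scores[j], res.scores[-1], atol=1e-6)

    def test_planted_regional_loading_directions(self, rng):
        # two spatial regions with different dominant spectral directions
        n1 = 60
        coords = np.vstack(
            [
                np.column_stack([rng.normal(0, 0.2, n1), rng.normal(0, 0.2, n1)]),
                np.column_stack([rng.normal(6, 0.2, n1), rng.normal(0, 0.2, n1)]),
            ]
        )
        dirs = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, -1.0]]) / np.sqrt(2)
        t = rng.standard_normal(2 * n1)
        X = np.vstack(
            [np.outer(t[:n1], dirs[0]), np.outer(t[n1:], dirs[1])]
        ) + rng.normal(0, 0.05, (2 * n1, 3))
        from spectroclust.spectral_data import SpectralDataset

        ds = SpectralDataset(
            ids=np.array([str(i) for i in range(2 * n1)]),
            coords=coords,
            wavelengths=np.array([400.0, 410.0, 420.0]),
            values=X,
            mode="absorbance",
        )
        res = fit_gwpca(ds, 1, KernelSpec(2.0, metric="euclidean"))
        mean_a = res.loadings[:n1, :, 0].mean(axis=0)
        mean_b = res.loadings[n1:, :, 0].mean(axis=0)

        def cos(u, v):
            return abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))

        assert cos(mean_a, dirs[0]) > cos(mean_a, dirs[1])
        assert cos(mean_b, dirs[1]) > cos(mean_b, dirs[0])

    def test_undersized_neighborhood_rejected(self, small_scene):
        ds, _, _ = small_scene
        with pytest.raises(GWPCAError, match="bandwidth"):
            fit_gwpca(to_absorbance(ds), 3, KernelSpec(0.01))
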