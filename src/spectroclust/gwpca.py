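"""Geographically weighted principal component analysis (GWPCA).

Ordinary PCA assumes one covariance structure for the whole library.  Over
continental extents the covariance of soil spectra is spatially
non-stationary, so GWPCA computes, at each sample location, a locally
weighted covariance matrix

    Sigma(u, v) = X_c^T W(u, v) X_c

with W a diagonal kernel-weight matrix decaying with geographic distance,
and takes its leading eigenstructure.  Each sample is scored on the
eigenvectors of its own location, giving spatially adaptive low-dimensional
coordinates suitable for clustering.

Local eigenvectors are defined only up to sign; every local loading column
is aligned (sign-flipped if needed) to the corresponding global PCA loading
so that scores are comparable across locations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from spectroclust.spectral_data import SpectralDataset

EARTH_RADIUS_KM = 6371.0088


class GWPCAError(ValueError):
    pass


@dataclass
class KernelSpec:
    """Spatial weighting kernel.

    Parameters
    ----------
    bandwidth : float
        Fixed bandwidth in the metric's distance units (km for haversine),
        or a neighbor count when ``adaptive`` is true.
    metric : {"haversine", "euclidean"}
        Haversine treats coordinates as (lon, lat) in decimal degrees and
        returns great-circle km; Euclidean is for projected or synthetic
        planar coordinates.
    adaptive : bool
        If true, the bandwidth at each location is the distance to its
        ``int(bandwidth)``-th nearest neighbor.
    name : str
        Kernel family; only the bisquare kernel is supported.
    """

    bandwidth: float
    metric: str = "haversine"
    adaptive: bool = False
    name: str = "bisquare"

    def __post_init__(self):
        if self.name != "bisquare":
            raise GWPCAError(f"unsupported kernel {self.name!r}")
        if self.metric not in ("haversine", "euclidean"):
            raise GWPCAError(f"unsupported metric {self.metric!r}")
        if self.bandwidth <= 0:
            raise GWPCAError("bandwidth must be positive")


@dataclass
class GWPCAResult:
    """Local eigenstructure at every sample location.

    loadings : (n, m, k) sign-aligned local eigenvector stacks
    eigenvalues : (n, k) local eigenvalues, non-increasing within a row
    scores : (n, k) each sample scored at its own location
    global_loadings : (m, k) reference loadings used for sign alignment
    global_eigenvalues : (k,) global PCA eigenvalues
    """

    k: int
    kernel: KernelSpec
    loadings: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    global_loadings: np.ndarray
    global_eigenvalues: np.ndarray


def haversine_km(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix in km between (lon, lat) degree arrays."""
    a = np.radians(np.atleast_2d(coords_a))
    b = np.radians(np.atleast_2d(coords_b))
    dlon = a[:, None, 0] - b[None, :, 0]
    dlat = a[:, None, 1] - b[None, :, 1]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def distance_matrix(coords: np.ndarray, metric: str) -> np.ndarray:
    if metric == "haversine":
        return haversine_km(coords, coords)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def bisquare_weight(d, b: float):
    """Bisquare kernel w = (1 - (d/b)^2)^2 for d < b, else 0."""
    if b <= 0:
        raise GWPCAError("bandwidth must be positive")
    d = np.asarray(d, dtype=float)
    w = np.where(d < b, (1.0 - (d / b) ** 2) ** 2, 0.0)
    return float(w) if w.ndim == 0 else w


def standardize(X: np.ndarray) -> np.ndarray:
    """Column z-score (population sd).  Zero-variance columns pass through
    centered only, with a warning."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{zero.sum()} constant bands left unscaled", stacklevel=2)
        sd = np.where(zero, 1.0, sd)
    return (X - mu) / sd


def local_covariance(Xstd: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted covariance Sigma = Xc^T diag(w / sum w) Xc about the
    weighted column mean.  Weights are normalized to sum 1 so the
    eigenvalue scale matches an (unweighted) population covariance in the
    uniform-weight limit."""
    Xstd = np.asarray(Xstd, dtype=float)
    w = np.asarray(w, dtype=float)
    total = w.sum()
    if total <= 0:
        raise GWPCAError("all kernel weights are zero: bandwidth too small here")
    wn = w / total
    mu = wn @ Xstd
    Xc = Xstd - mu
    S = (Xc * wn[:, None]).T @ Xc
    return 0.5 * (S + S.T)  # enforce exact symmetry


def local_eigen(S: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of a symmetric PSD matrix, eigenvalues descending."""
    S = np.asarray(S, dtype=float)
    m = S.shape[0]
    if k > m:
        raise GWPCAError(f"k={k} exceeds matrix dimension {m}")
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order], np.maximum(vals[order], 0.0)


def global_pca(Xstd: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenstructure of the population covariance of standardized data."""
    S = np.cov(Xstd, rowvar=False, ddof=0)
    return local_eigen(np.atleast_2d(S), k)


def choose_n_components(Xstd: np.ndarray) -> int:
    """Kaiser rule on the global covariance of standardized data: retain
    components with eigenvalue > 1 (at least one)."""
    Xstd = np.asarray(Xstd, dtype=float)
    m = Xstd.shape[1]
    _, vals = global_pca(Xstd, m)
    return max(1, int(np.sum(vals > 1.0)))


def _adaptive_bandwidths(D: np.ndarray, nn: int) -> np.ndarray:
    """Per-location bandwidth = distance to the nn-th nearest neighbor
    (self excluded)."""
    n = D.shape[0]
    nn = min(nn, n - 1)
    part = np.partition(D, nn, axis=1)
    # include the nn-th neighbor inside the support: bisquare is 0 at d == b
    return part[:, nn] * (1 + 1e-9)


def _loo_score(Xstd: np.ndarray, D: np.ndarray, k: int, kernel: KernelSpec) -> float:
    """Leave-one-out reconstruction score for a candidate bandwidth: at each
    location fit local eigenvectors excluding the sample itself and sum the
    squared residuals of projecting the held-out spectrum on them."""
    n = Xstd.shape[0]
    if kernel.adaptive:
        bands = _adaptive_bandwidths(D, int(kernel.bandwidth))
    else:
        bands = np.full(n, kernel.bandwidth)
    score = 0.0
    for i in range(n):
        w = bisquare_weight(D[i], bands[i])
        w = w.copy()
        w[i] = 0.0
        if np.count_nonzero(w) < k + 1:
            return math.inf
        try:
            S = local_covariance(Xstd, w)
        except GWPCAError:
            return math.inf
        L, _ = local_eigen(S, k)
        mu = (w / w.sum()) @ Xstd
        xi = Xstd[i] - mu
        resid = xi - (xi @ L) @ L.T
        score += float(resid @ resid)
    return score


def select_bandwidth(
    Xstd: np.ndarray,
    coords: np.ndarray,
    k: int,
    *,
    metric: str = "haversine",
    adaptive: bool = False,
    tol: float = 1e-2,
) -> KernelSpec:
    """Select the bisquare bandwidth minimizing the leave-one-out
    reconstruction score.

    Fixed bandwidths are searched by golden-section over
    [smallest feasible distance, max pairwise distance]; adaptive
    (neighbor-count) bandwidths by golden-section on the integers in
    [k + 2, n - 1].
    """
    Xstd = np.asarray(Xstd, dtype=float)
    n = Xstd.shape[0]
    if n < k + 2:
        raise GWPCAError(f"need at least k+2={k + 2} samples, got {n}")
    D = distance_matrix(np.asarray(coords, dtype=float), metric)
    dmax = D.max()
    if dmax == 0:
        raise GWPCAError("all sample locations coincide")

    if adaptive:
        lo, hi = k + 2, n - 1
        cache: dict[int, float] = {}

        def f_int(nn: int) -> float:
            if nn not in cache:
                cache[nn] = _loo_score(
                    Xstd, D, k, KernelSpec(nn, metric=metric, adaptive=True)
                )
            return cache[nn]

        # golden-section on integers
        a, b = lo, hi
        phi = (math.sqrt(5) - 1) / 2
        while b - a > 2:
            c1 = int(round(b - phi * (b - a)))
            c2 = int(round(a + phi * (b - a)))
            if c1 == c2:
                c2 = min(c1 + 1, b)
            if f_int(c1) <= f_int(c2):
                b = c2
            else:
                a = c1
        best = min(range(a, b + 1), key=f_int)
        return KernelSpec(best, metric=metric, adaptive=True)

    pos = D[D > 0]
    dmin = np.median(np.min(np.where(D > 0, D, np.inf), axis=1)) if pos.size else dmax
    res = minimize_scalar(
        lambda b: _loo_score(Xstd, D, k, KernelSpec(b, metric=metric)),
        bounds=(dmin, dmax),
        method="bounded",
        options={"xatol": tol * dmax},
    )
    return KernelSpec(float(res.x), metric=metric)


def fit_gwpca(
    ds: SpectralDataset,
    k: int | None = None,
    kernel: KernelSpec | None = None,
) -> GWPCAResult:
    """Fit GWPCA on a preprocessed dataset.

    Bands are globally z-scored, then for every sample location a
    bisquare-weighted local covariance (about the local weighted mean) is
    eigendecomposed.  The local loading columns are sign-aligned to the
    global PCA loadings and each sample is scored on its own local
    loadings: Z_i = x_i,std . L_i.  The globally standardized row (not a
    locally re-centered one) is projected, so scores keep between-region
    mean differences and reduce to global PCA scores in the infinite
    bandwidth limit.

    Parameters
    ----------
    ds : SpectralDataset (preprocessed; coordinates required)
    k : number of components; default = Kaiser rule (global eigenvalues > 1)
    kernel : KernelSpec; default = adaptive bandwidth of n/2 neighbors
    """
    Xstd = standardize(ds.values)
    n, m = Xstd.shape
    if k is None:
        k = choose_n_components(Xstd)
    if k > m:
        raise GWPCAError(f"k={k} exceeds band count {m}")
    if kernel is None:
        kernel = KernelSpec(max(k + 2, n // 2), metric="haversine", adaptive=True)

    D = distance_matrix(ds.coords, kernel.metric)
    if kernel.adaptive:
        bands = _adaptive_bandwidths(D, int(kernel.bandwidth))
    else:
        bands = np.full(n, kernel.bandwidth)

    Lg, Vg = global_pca(Xstd, k)
    loadings = np.empty((n, m, k))
    eigenvalues = np.empty((n, k))
    scores = np.empty((n, k))
    for i in range(n):
        w = bisquare_weight(D[i], bands[i])
        nz = np.flatnonzero(w)
        if nz.size < k + 1:
            raise GWPCAError(
                f"effective sample size {nz.size} < k+1 at sample {ds.ids[i]}; "
                "increase the bandwidth"
            )
        S = local_covariance(Xstd[nz], w[nz])
        L, V = local_eigen(S, k)
        flip = np.sign(np.einsum("mk,mk->k", L, Lg))
        flip[flip == 0] = 1.0
        L = L * flip
        loadings[i] = L
        eigenvalues[i] = V
        scores[i] = Xstd[i] @ L
    return GWPCAResult(
        k=k,
        kernel=kernel,
        loadings=loadings,
        eigenvalues=eigenvalues,
        scores=scores,
        global_loadings=Lg,
        global_eigenvalues=Vg,
    )
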