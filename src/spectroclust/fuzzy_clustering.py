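"""Fuzzy c-means clustering of local PCA scores, with validity indices.

FCM minimizes J = sum_i sum_j mu_ij^m * d_ij^2 over column-stochastic
memberships mu (c clusters x n samples) and cluster centers, where d_ij is
the Euclidean distance from sample j to center i and m > 1 is the
fuzziness exponent.  The alternating (Bezdek) updates are

    centers:      c_i = sum_j mu_ij^m z_j / sum_j mu_ij^m
    memberships:  mu_ij = [ sum_l (d_ij / d_lj)^(2/(m-1)) ]^-1

and each half-step cannot increase J.

Two validity indices guide the choice of cluster count:

* FPI (fuzzy performance index) = c (1 - PC) / (c - 1) with partition
  coefficient PC = (1/n) sum mu^2.  0 for a crisp partition, 1 for a
  maximally fuzzy one.
* NCE (normalized classification entropy) = n/(n-c) * H with partition
  entropy H = -(1/n) sum mu ln mu.

Lower values of both indicate a better-separated partition.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


class FCMError(ValueError):
    pass


@dataclass
class FCMResult:
    """Outcome of one FCM fit.

    U : (c, n) membership matrix, columns sum to 1
    centers : (c, k)
    labels : (n,) hard assignment = argmax membership
    objective : J per iteration of the winning restart (non-increasing)
    fpi, nce : validity indices (NaN when c == 1 or n <= c)
    """

    U: np.ndarray
    centers: np.ndarray
    labels: np.ndarray
    objective: np.ndarray
    fpi: float
    nce: float
    seed: int
    iterations: int


@dataclass
class ValidityCurve:
    """FPI/NCE as a function of cluster count, plus the automatic choice."""

    c_values: np.ndarray
    fpi: np.ndarray
    nce: np.ndarray
    chosen_c: int
    results: dict = field(default_factory=dict, repr=False)


def _hash_init(Z: np.ndarray, c: int, seed: int, restart: int) -> np.ndarray:
    """Order-independent random column-stochastic init: each sample's
    membership column is derived from a hash of its own coordinates, so
    permuting sample order permutes the columns identically."""
    n = Z.shape[0]
    U = np.empty((c, n))
    for j in range(n):
        h = hashlib.blake2b(digest_size=16)
        h.update(np.ascontiguousarray(Z[j], dtype=np.float64).tobytes())
        h.update(np.int64(seed).tobytes())
        h.update(np.int64(restart).tobytes())
        rng = np.random.default_rng(int.from_bytes(h.digest(), "little"))
        col = rng.random(c) + 1e-12
        U[:, j] = col / col.sum()
    return U


def _memberships(dist2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances (c, n).  Samples coincident
    with one or more centers split membership equally among the coincident
    centers."""
    c, n = dist2.shape
    U = np.empty((c, n))
    zero = dist2 <= 0
    any_zero = zero.any(axis=0)
    with np.errstate(divide="ignore", over="ignore"):
        p = dist2 ** (-1.0 / (m - 1.0))
    p_sum = p.sum(axis=0)
    cols = ~any_zero
    U[:, cols] = p[:, cols] / p_sum[cols]
    if any_zero.any():
        for j in np.flatnonzero(any_zero):
            U[:, j] = zero[:, j] / zero[:, j].sum()
    return U


def _objective(U: np.ndarray, dist2: np.ndarray, m: float) -> float:
    return float(np.sum(U**m * dist2))


def fcm_fit(
    Z: np.ndarray,
    c: int,
    *,
    fuzziness: float = 1.5,
    max_iter: int = 300,
    tol: float = 1e-3,
    seed: int = 0,
    restarts: int = 5,
) -> FCMResult:
    """Fit fuzzy c-means to score vectors Z (n samples x k dims).

    Runs ``restarts`` seeded random initializations and keeps the one with
    the lowest final objective J.  Convergence: max absolute membership
    change < ``tol``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]
    if c < 1:
        raise FCMError("c must be >= 1")
    if c > n:
        raise FCMError(f"c={c} exceeds sample count {n}")
    if fuzziness <= 1:
        raise FCMError("fuzziness exponent must be > 1")

    if c == 1:
        center = Z.mean(axis=0, keepdims=True)
        d2 = ((Z - center) ** 2).sum(axis=1)[None, :]
        U = np.ones((1, n))
        return FCMResult(
            U=U,
            centers=center,
            labels=np.zeros(n, dtype=int),
            objective=np.array([_objective(U, d2, fuzziness)]),
            fpi=float("nan"),
            nce=float("nan"),
            seed=seed,
            iterations=0,
        )

    best = None
    for r in range(restarts):
        U = _hash_init(Z, c, seed, r)
        trace = []
        for it in range(1, max_iter + 1):
            Um = U**fuzziness
            centers = (Um @ Z) / Um.sum(axis=1, keepdims=True)
            d2 = ((Z[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
            U_new = _memberships(d2, fuzziness)
            trace.append(_objective(U_new, d2, fuzziness))
            delta = np.abs(U_new - U).max()
            U = U_new
            if delta < tol:
                break
        cand = (trace[-1], r, U, centers, np.array(trace), it)
        if best is None or cand[0] < best[0]:
            best = cand
    _, r, U, centers, trace, iters = best
    return FCMResult(
        U=U,
        centers=centers,
        labels=np.argmax(U, axis=0),
        objective=trace,
        fpi=fpi(U),
        nce=nce(U) if Z.shape[0] > c else float("nan"),
        seed=seed,
        iterations=iters,
    )


def fpi(U: np.ndarray) -> float:
    """Fuzzy performance index: c (1 - PC) / (c - 1), PC = (1/n) sum mu^2.

    0 for a crisp partition (well-separated clusters), 1 for uniform
    memberships.
    """
    U = np.asarray(U, dtype=float)
    c, n = U.shape
    if c < 2:
        raise FCMError("FPI requires at least 2 clusters")
    pc = float(np.sum(U**2)) / n
    return c * (1.0 - pc) / (c - 1.0)


def nce(U: np.ndarray, *, base: float = np.e) -> float:
    """Normalized classification entropy: n/(n-c) * H with
    H = -(1/n) sum mu log mu (0 log 0 := 0; natural log by default)."""
    U = np.asarray(U, dtype=float)
    c, n = U.shape
    if c < 2:
        raise FCMError("NCE requires at least 2 clusters")
    if n <= c:
        raise FCMError(f"NCE undefined for n={n} <= c={c}")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(U > 0, U * np.log(U), 0.0)
    H = -terms.sum() / n
    if base != np.e:
        H /= np.log(base)
    return float(n / (n - c) * H)


def sweep_clusters(
    Z: np.ndarray,
    c_range=range(2, 11),
    *,
    fuzziness: float = 1.5,
    max_iter: int = 300,
    tol: float = 1e-3,
    seed: int = 0,
    restarts: int = 5,
    chosen_c: int | None = None,
) -> ValidityCurve:
    """Fit FCM for each candidate cluster count and record FPI/NCE.

    The automatic choice is the candidate minimizing the rank-sum of
    (FPI, NCE); ties go to the smaller count.  Domain judgment (e.g.
    agreement with land-cover strata) can override via ``chosen_c``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    c_values = np.array(sorted(c_range), dtype=int)
    if c_values.max() >= Z.shape[0]:
        raise FCMError("largest candidate c must be smaller than n")
    if np.allclose(Z, Z[0], atol=1e-12):
        warnings.warn("all score vectors identical; validity indices degenerate",
                      stacklevel=2)
    fpis, nces, results = [], [], {}
    for c in c_values:
        res = fcm_fit(
            Z, int(c), fuzziness=fuzziness, max_iter=max_iter, tol=tol,
            seed=seed, restarts=restarts,
        )
        results[int(c)] = res
        fpis.append(res.fpi)
        nces.append(res.nce)
    fpis = np.array(fpis)
    nces = np.array(nces)
    if chosen_c is None:
        ranks = rankdata(fpis, method="average") + rankdata(nces, method="average")
        chosen_c = int(c_values[int(np.argmin(ranks))])
    elif chosen_c not in c_values:
        raise FCMError(f"override c={chosen_c} not among candidates")
    return ValidityCurve(
        c_values=c_values, fpi=fpis, nce=nces, chosen_c=int(chosen_c),
        results=results,
    )
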