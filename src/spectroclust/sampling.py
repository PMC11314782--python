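"""Kennard-Stone calibration/validation splitting.

The Kennard-Stone algorithm picks a calibration subset spread uniformly
through the feature space: it seeds with the two most distant samples and
then repeatedly adds the sample whose minimum distance to the already
selected set is largest (max-min criterion).  The procedure is fully
deterministic; ties are broken by the lowest row index.

Distances are Euclidean on the matrix handed in, which for spectral
calibration should be the preprocessed absorbance spectra — the actual
model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.spatial.distance import squareform, pdist


class SplitError(ValueError):
    pass


@dataclass
class SplitResult:
    """Calibration/validation index split.

    ``cal`` is in selection order (the seed pair first); ``val`` is sorted.
    """

    cal: np.ndarray
    val: np.ndarray
    ratio: tuple[int, int]
    metric: str = "euclidean"

    @property
    def n(self) -> int:
        return len(self.cal) + len(self.val)


def _parse_ratio(ratio) -> tuple[int, int]:
    if isinstance(ratio, str):
        a, b = ratio.split(":")
        return int(a), int(b)
    a, b = ratio
    return int(a), int(b)


def kennard_stone_split(X: np.ndarray, ratio=(2, 1)) -> SplitResult:
    """Split rows of X into calibration and validation sets by Kennard-Stone.

    The calibration size is ceil(n * a / (a + b)) for ratio a:b (so 2:1
    keeps two thirds, rounded up).  Requires n >= 3 so both sets are
    non-empty under the default ratio.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise SplitError(f"need at least 3 samples, got {n}")
    a, b = _parse_ratio(ratio)
    if a <= 0 or b <= 0:
        raise SplitError("ratio parts must be positive")
    frac = Fraction(a, a + b)
    n_cal = -(-n * frac.numerator // frac.denominator)  # ceil
    n_cal = min(max(n_cal, 2), n - 1)

    D = squareform(pdist(X, metric="euclidean"))
    # seed pair: maximum pairwise distance, lowest (i, j) on ties (row-major
    # argmax over the upper triangle)
    iu = np.triu_indices(n, k=1)
    seed_flat = int(np.argmax(D[iu]))
    i0, j0 = int(iu[0][seed_flat]), int(iu[1][seed_flat])
    selected = [i0, j0]
    in_cal = np.zeros(n, dtype=bool)
    in_cal[[i0, j0]] = True
    mindist = np.minimum(D[i0], D[j0])
    mindist[in_cal] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(mindist))  # argmax returns lowest index on ties
        selected.append(nxt)
        in_cal[nxt] = True
        mindist = np.minimum(mindist, D[nxt])
        mindist[in_cal] = -np.inf
    val = np.flatnonzero(~in_cal)
    return SplitResult(cal=np.array(selected), val=val, ratio=(a, b))
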