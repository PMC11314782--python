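"""Calibration models: PLSR and an M5-style model tree, plus grouped fits.

Both regressors share a ``fit``/``predict`` contract on a numeric matrix of
preprocessed spectra and a (log-transformed) target.

PLSR is implemented as PLS1 NIPALS with mean centering.  The latent-variable
count can be chosen by 10-fold cross-validation; the NIPALS recursion yields
regression coefficients for every truncation from a single decomposition, so
the whole CV path costs one fit per fold.

The model tree is a single M5-style tree: splits maximize the standard
deviation reduction SDR = sd(S) - sum |S_i|/|S| sd(S_i), leaves hold
multivariate linear models (least squares with a ridge fallback when the
band matrix is ill-conditioned, as it always is for n < m spectra),
predictions are smoothed along the path to the root, and subtrees are
pruned when the node's own linear model cross-validates at least as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from spectroclust.sampling import SplitResult, kennard_stone_split
from spectroclust.spectral_data import SpectralDataset, log_transform_target


class CalibrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------


@dataclass
class PLSRModel:
    """PLS1 regression model (mean-centered NIPALS).

    ``coef_path`` holds the coefficient vector for every truncation
    1..A_max; ``n_components`` selects the column used for prediction.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (m, A) X-weights w_a
    x_loadings: np.ndarray  # (m, A) p_a
    y_loadings: np.ndarray  # (A,) q_a
    coef_path: np.ndarray  # (m, A) coefficients per truncation
    cv_rmse: np.ndarray | None = None

    @property
    def coef_(self) -> np.ndarray:
        if self.n_components == 0:
            return np.zeros(len(self.x_mean))
        return self.coef_path[:, self.n_components - 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.x_mean):
            raise CalibrationError(
                f"{X.shape[1]} bands, model trained on {len(self.x_mean)}"
            )
        return (X - self.x_mean) @ self.coef_ + self.y_mean


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, a_max: int):
    """PLS1 NIPALS on centered data; returns (W, P, q, coef_path)."""
    n, m = Xc.shape
    Xd = Xc.copy()
    yd = yc.copy()
    W = np.zeros((m, a_max))
    P = np.zeros((m, a_max))
    q = np.zeros(a_max)
    R = np.zeros((m, a_max))
    coef_path = np.zeros((m, a_max))
    B = np.zeros(m)
    a_eff = 0
    for a in range(a_max):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn < 1e-14:
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        p = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, p)
        yd -= qa * t
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        W[:, a], P[:, a], q[a], R[:, a] = w, p, qa, r
        B = B + qa * r
        coef_path[:, a] = B
        a_eff = a + 1
    if a_eff < a_max:  # pad the path with the last attainable coefficients
        coef_path[:, a_eff:] = coef_path[:, [max(a_eff - 1, 0)]]
    return W[:, :a_max], P[:, :a_max], q[:a_max], coef_path, a_eff


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | str = "auto",
    *,
    max_components: int = 30,
    cv_folds: int = 10,
) -> PLSRModel:
    """Fit PLS1 regression.

    ``n_components="auto"`` selects the count minimizing 10-fold CV RMSE
    over 1..min(max_components, n-2, m); ties go to the smaller count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if len(y) != n:
        raise CalibrationError("X and y length mismatch")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if np.ptp(y) == 0:
        warnings.warn("constant target: intercept-only PLSR model", stacklevel=2)
        z = np.zeros((m, 1))
        return PLSRModel(0, x_mean, y_mean, z, z, np.zeros(1), z)

    a_cap = max(1, min(max_components, n - 2, m))
    cv_rmse = None
    if n_components == "auto":
        if n < 4:
            raise CalibrationError("auto component selection needs n >= 4")
        folds = min(cv_folds, n)
        sse = np.zeros(a_cap)
        counts = 0
        for tr, va in KFold(n_splits=folds).split(X):
            xm = X[tr].mean(axis=0)
            ym = y[tr].mean()
            a_fold = max(1, min(a_cap, len(tr) - 1))
            _, _, _, path, _ = _nipals_pls1(X[tr] - xm, y[tr] - ym, a_fold)
            pred = (X[va] - xm) @ path + ym  # (n_va, a_fold)
            err = pred - y[va][:, None]
            if a_fold < a_cap:
                err = np.pad(err, ((0, 0), (0, a_cap - a_fold)), mode="edge")
            sse += (err**2).sum(axis=0)
            counts += len(va)
        cv_rmse = np.sqrt(sse / counts)
        n_components = int(np.argmin(cv_rmse)) + 1
    n_components = int(n_components)
    if not 1 <= n_components <= min(n - 1, m):
        raise CalibrationError(
            f"n_components={n_components} outside [1, {min(n - 1, m)}]"
        )
    W, P, q, path, a_eff = _nipals_pls1(Xc, yc, n_components)
    return PLSRModel(
        min(n_components, max(a_eff, 1)), x_mean, y_mean, W, P, q, path,
        cv_rmse=cv_rmse,
    )


# ---------------------------------------------------------------------------
# M5-style model tree
# ---------------------------------------------------------------------------


@dataclass
class _LinearModel:
    coef: np.ndarray
    intercept: float
    x_mean: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) @ self.coef + self.intercept


def _fit_linear(X: np.ndarray, y: np.ndarray, ridge_scale: float) -> _LinearModel:
    """Least squares on centered data; ridge fallback (lambda =
    ridge_scale * trace(X_c^T X_c)) when the system is rank-deficient or
    underdetermined."""
    n, m = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if n > m:
        coef, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
        if rank == m:
            return _LinearModel(coef, y_mean, x_mean)
    G = Xc.T @ Xc
    tr = float(np.trace(G))
    if tr <= 0:
        return _LinearModel(np.zeros(m), y_mean, x_mean)
    lam = ridge_scale * tr
    coef = np.linalg.solve(G + lam * np.eye(m), Xc.T @ yc)
    return _LinearModel(coef, y_mean, x_mean)


def _cv_rmse_linear(X, y, ridge_scale, folds=3) -> float:
    n = len(y)
    if n < folds + 1 or np.ptp(y) == 0:
        return float(np.std(y))
    sse = 0.0
    for tr, va in KFold(n_splits=folds).split(X):
        model = _fit_linear(X[tr], y[tr], ridge_scale)
        sse += float(((model.predict(X[va]) - y[va]) ** 2).sum())
    return float(np.sqrt(sse / n))


@dataclass
class _Node:
    n: int
    sd: float
    model: _LinearModel | None = None
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    cv_error: float = np.inf

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _best_split(X, y, min_leaf):
    """Exhaustive SDR split search; returns (sdr, feature, threshold)."""
    n, m = X.shape
    sd_all = float(np.std(y))
    best = (0.0, None, None)
    for f in range(m):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y[order]
        cs = np.cumsum(ys)
        cs2 = np.cumsum(ys**2)
        idx = np.arange(min_leaf, n - min_leaf + 1)
        if idx.size == 0:
            continue
        idx = idx[xs[idx - 1] < xs[np.minimum(idx, n - 1)]]
        if idx.size == 0:
            continue
        nl = idx.astype(float)
        nr = n - nl
        sl = cs[idx - 1]
        sl2 = cs2[idx - 1]
        var_l = np.maximum(sl2 / nl - (sl / nl) ** 2, 0.0)
        var_r = np.maximum((cs2[-1] - sl2) / nr - ((cs[-1] - sl) / nr) ** 2, 0.0)
        sdr = sd_all - (nl / n) * np.sqrt(var_l) - (nr / n) * np.sqrt(var_r)
        j = int(np.argmax(sdr))
        if sdr[j] > best[0] + 1e-12:
            thr = 0.5 * (xs[idx[j] - 1] + xs[idx[j]])
            best = (float(sdr[j]), f, float(thr))
    return best


@dataclass
class ModelTree:
    """Single M5-style regression tree with linear models in the nodes.

    Parameters
    ----------
    min_leaf : minimum samples per leaf (splits need 2x this)
    smoothing_k : M5 smoothing constant blending child predictions with
        ancestor node models; set to 0 (or ``smoothing=False`` at predict
        time) for raw leaf-model output
    prune : collapse a subtree when the node's own linear model has a
        3-fold CV RMSE no worse than the weighted CV RMSE of its children
    sd_stop_frac : stop splitting once node sd < this fraction of root sd
    ridge_scale : ridge fallback strength for ill-conditioned node models
    """

    min_leaf: int = 20
    smoothing_k: float = 15.0
    prune: bool = True
    sd_stop_frac: float = 0.05
    ridge_scale: float = 1e-6
    root: _Node | None = field(default=None, repr=False)
    n_features_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ModelTree":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if n < 2:
            raise CalibrationError("need at least 2 samples")
        self.n_features_ = X.shape[1]
        root_sd = float(np.std(y))
        self.root = self._grow(X, y, root_sd)
        if self.prune:
            self._prune(self.root, X, y)
        return self

    def _grow(self, X, y, root_sd) -> _Node:
        n = len(y)
        node = _Node(n=n, sd=float(np.std(y)))
        node.model = _fit_linear(X, y, self.ridge_scale)
        if n < 2 * self.min_leaf or node.sd < self.sd_stop_frac * root_sd:
            return node
        sdr, f, thr = _best_split(X, y, self.min_leaf)
        if f is None:
            return node
        mask = X[:, f] <= thr
        node.feature, node.threshold = f, thr
        node.left = self._grow(X[mask], y[mask], root_sd)
        node.right = self._grow(X[~mask], y[~mask], root_sd)
        return node

    def _prune(self, node: _Node, X, y) -> float:
        """Bottom-up pruning; returns the node's retained CV error."""
        own = _cv_rmse_linear(X, y, self.ridge_scale)
        node.cv_error = own
        if node.is_leaf:
            return own
        mask = X[:, node.feature] <= node.threshold
        el = self._prune(node.left, X[mask], y[mask])
        er = self._prune(node.right, X[~mask], y[~mask])
        sub = (mask.sum() * el + (~mask).sum() * er) / len(y)
        # favor the simpler node model on (numerical) ties
        if own <= sub * (1 + 1e-9) + 1e-12:
            node.left = node.right = None
            node.feature = node.threshold = None
            return own
        node.cv_error = sub
        return sub

    def predict(self, X: np.ndarray, *, smoothing: bool | None = None) -> np.ndarray:
        if self.root is None:
            raise CalibrationError("model not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_:
            raise CalibrationError(
                f"{X.shape[1]} bands, model trained on {self.n_features_}"
            )
        smooth = self.smoothing_k > 0 if smoothing is None else smoothing
        return self._predict(self.root, X, smooth)

    def _predict(self, node: _Node, X, smooth) -> np.ndarray:
        if node.is_leaf:
            return node.model.predict(X)
        mask = X[:, node.feature] <= node.threshold
        out = np.empty(len(X))
        child_n = np.where(mask, node.left.n, node.right.n).astype(float)
        if mask.any():
            out[mask] = self._predict(node.left, X[mask], smooth)
        if (~mask).any():
            out[~mask] = self._predict(node.right, X[~mask], smooth)
        if smooth:
            out = (child_n * out + self.smoothing_k * node.model.predict(X)) / (
                child_n + self.smoothing_k
            )
        return out

    @property
    def n_leaves(self) -> int:
        def count(nd):
            return 1 if nd.is_leaf else count(nd.left) + count(nd.right)

        return count(self.root) if self.root else 0


def fit_model_tree(
    X: np.ndarray,
    y: np.ndarray,
    *,
    min_leaf: int = 20,
    smoothing_k: float = 15.0,
    prune: bool = True,
) -> ModelTree:
    """Fit an M5-style model tree (see :class:`ModelTree`)."""
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        tree = ModelTree(min_leaf=min_leaf, smoothing_k=smoothing_k, prune=False)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        tree.n_features_ = X.shape[1]
        tree.root = _Node(n=len(y), sd=0.0, model=_fit_linear(X, y, 1e-6))
        return tree
    return ModelTree(min_leaf=min_leaf, smoothing_k=smoothing_k, prune=prune).fit(
        X, y
    )


# ---------------------------------------------------------------------------
# grouped calibration
# ---------------------------------------------------------------------------

MODEL_FITTERS = {
    "plsr": lambda X, y, kw: fit_plsr(X, y, **kw),
    "cubist": lambda X, y, kw: fit_model_tree(X, y, **kw),
}


@dataclass
class GroupFit:
    model: object
    split: SplitResult
    indices: np.ndarray  # dataset row indices of this group, split-order base


@dataclass
class GroupedCalibration:
    """Per-group fitted models plus the pooled global model.

    ``X`` and ``y`` are the modeling matrix and (log) target actually used,
    after dropping samples below the log floor; split indices inside each
    :class:`GroupFit` refer to positions within ``indices``.
    """

    model_name: str
    groups: dict
    global_fit: GroupFit
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    excluded: list = field(default_factory=list)
    log_target: bool = True


def fit_per_group(
    ds: SpectralDataset,
    labels,
    model: str = "plsr",
    *,
    model_params: dict | None = None,
    min_size: int = 30,
    ratio=(2, 1),
    log_target: bool = True,
    log_floor: float = 0.1,
) -> GroupedCalibration:
    """Kennard-Stone split and model fit within each group, plus a pooled
    global model over all samples.

    ``labels`` may be FCM hard labels or a categorical column; groups
    smaller than ``min_size`` are excluded with a warning.
    """
    if ds.target is None:
        raise CalibrationError("dataset has no target")
    labels = np.asarray(labels)
    if labels.size == 0 or labels.size != ds.n_samples:
        raise CalibrationError("labels must match the dataset rows")
    if model not in MODEL_FITTERS:
        raise CalibrationError(f"unknown model {model!r}")
    kw = dict(model_params or {})
    fitter = MODEL_FITTERS[model]

    if log_target:
        y_all, kept = log_transform_target(ds.target, floor=log_floor)
    else:
        y_all, kept = ds.target.astype(float), np.ones(ds.n_samples, bool)
    X_all = ds.values[kept]
    labels = labels[kept]

    def fit_subset(idx: np.ndarray) -> GroupFit:
        split = kennard_stone_split(X_all[idx], ratio)
        mdl = fitter(X_all[idx][split.cal], y_all[idx][split.cal], kw)
        return GroupFit(model=mdl, split=split, indices=idx)

    global_fit = fit_subset(np.arange(len(y_all)))
    groups = {}
    excluded = []
    for lab in pd_unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_size:
            warnings.warn(
                f"group {lab!r} has {idx.size} samples < {min_size}; excluded",
                stacklevel=2,
            )
            excluded.append(lab)
            continue
        groups[lab] = fit_subset(idx)
    return GroupedCalibration(
        model_name=model,
        groups=groups,
        global_fit=global_fit,
        X=X_all,
        y=y_all,
        excluded=excluded,
        log_target=log_target,
    )


def fit_global(
    ds: SpectralDataset,
    model: str = "plsr",
    *,
    model_params: dict | None = None,
    ratio=(2, 1),
    log_target: bool = True,
    log_floor: float = 0.1,
) -> GroupedCalibration:
    """Pooled (unclassified) fit only: a :class:`GroupedCalibration` with an
    empty group map and the global model."""
    if ds.target is None:
        raise CalibrationError("dataset has no target")
    if model not in MODEL_FITTERS:
        raise CalibrationError(f"unknown model {model!r}")
    kw = dict(model_params or {})
    if log_target:
        y_all, kept = log_transform_target(ds.target, floor=log_floor)
    else:
        y_all, kept = ds.target.astype(float), np.ones(ds.n_samples, bool)
    X_all = ds.values[kept]
    split = kennard_stone_split(X_all, ratio)
    mdl = MODEL_FITTERS[model](X_all[split.cal], y_all[split.cal], kw)
    gf = GroupFit(model=mdl, split=split, indices=np.arange(len(y_all)))
    return GroupedCalibration(
        model_name=model, groups={}, global_fit=gf, X=X_all, y=y_all,
        log_target=log_target,
    )


def pd_unique(values):
    """Unique labels in order of first appearance."""
    seen = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)
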