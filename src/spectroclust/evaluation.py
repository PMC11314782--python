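"""Validation metrics, grouped reports and random-forest band importance.

Metrics follow chemometrics conventions: RMSE, R^2 = 1 - SSE/SST, and
RPIQ = IQR(observed)/RMSE with linearly interpolated quartiles.  RPIQ
quality categories: < 1.5 very bad, 1.5-2.0 poor, 2.0-2.5 good, > 2.5
very good.

Grouped reports mirror the layout used to compare per-cluster local models
against a pooled global model: one row per group, a pooled "All" row, and
an unweighted "Mean" row over the groups.  Display rounding is decimal
half-up at 2 dp, and the Mean row is computed from the rounded group cells
so the printed table is internally reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------


def _check_pair(obs, pred):
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if len(obs) != len(pred):
        raise EvaluationError("obs and pred lengths differ")
    if len(obs) < 2:
        raise EvaluationError("need at least 2 observations")
    return obs, pred


def rmse(obs, pred) -> float:
    obs, pred = _check_pair(obs, pred)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r2(obs, pred) -> float:
    """Coefficient of determination 1 - SSE/SST (SST about the observed
    mean).  NaN for constant observations."""
    obs, pred = _check_pair(obs, pred)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def rpiq(obs, pred) -> float:
    """Ratio of performance to inter-quartile distance:
    (Q3 - Q1 of obs) / RMSE, quartiles by linear interpolation."""
    obs, pred = _check_pair(obs, pred)
    err = rmse(obs, pred)
    q1, q3 = np.quantile(obs, [0.25, 0.75])
    if err == 0:
        return float("inf")
    return float((q3 - q1) / err)


RPIQ_CATEGORIES = ("very bad", "poor", "good", "very good")


def rpiq_category(v: float) -> str:
    """Model quality from RPIQ: < 1.5 very bad, [1.5, 2.0) poor,
    [2.0, 2.5] good, > 2.5 very good."""
    if v < 0:
        raise EvaluationError("RPIQ cannot be negative")
    if v < 1.5:
        return "very bad"
    if v < 2.0:
        return "poor"
    if v <= 2.5:
        return "good"
    return "very good"


# ---------------------------------------------------------------------------
# grouped report
# ---------------------------------------------------------------------------


def _round2(v) -> Decimal:
    """Decimal half-up rounding at 2 dp, tolerant of float representation
    noise (rounds the 12-significant-digit decimal of the float)."""
    if isinstance(v, Decimal):
        d = v
    elif isinstance(v, str):
        d = Decimal(v)
    else:
        if not np.isfinite(v):
            return Decimal("NaN")
        d = Decimal(f"{float(v):.12g}")
    return d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


@dataclass
class ReportRow:
    group: str
    n: int
    model: str
    r2: float
    rmse: float
    rpiq: float

    @property
    def category(self) -> str:
        return rpiq_category(self.rpiq)


@dataclass
class GroupedReport:
    """Per-group validation rows plus pooled-All and Mean rows.

    The Mean row is the unweighted arithmetic mean over the group rows,
    computed in 2-dp decimal arithmetic from the displayed group cells
    (half-up), so a printed table can be re-derived from its own rows.
    """

    rows: list = field(default_factory=list)  # per-group ReportRow
    all_row: ReportRow | None = None

    @classmethod
    def from_rows(cls, rows, all_row=None) -> "GroupedReport":
        def mk(r):
            if isinstance(r, ReportRow):
                return r
            return ReportRow(*r) if not isinstance(r, dict) else ReportRow(**r)

        return cls(rows=[mk(r) for r in rows],
                   all_row=mk(all_row) if all_row is not None else None)

    @property
    def mean_row(self) -> dict:
        if not self.rows:
            raise EvaluationError("no group rows")
        k = len(self.rows)

        def mean2(vals):
            total = sum(_round2(v) for v in vals)
            return _round2(total / k)

        n_mean = Decimal(sum(r.n for r in self.rows)) / k
        mean_rpiq = mean2(r.rpiq for r in self.rows)
        return {
            "group": "Mean",
            "n": int(n_mean.quantize(Decimal(1), rounding=ROUND_HALF_UP)),
            "r2": float(mean2(r.r2 for r in self.rows)),
            "rmse": float(mean2(r.rmse for r in self.rows)),
            "rpiq": float(mean_rpiq),
            "category": rpiq_category(float(mean_rpiq)),
        }

    def to_frame(self, *, display: bool = True) -> pd.DataFrame:
        recs = []
        rows = list(self.rows)
        if self.all_row is not None:
            rows = [self.all_row] + rows
        for r in rows:
            recs.append(
                {
                    "group": r.group,
                    "n": r.n,
                    "model": r.model,
                    "r2": float(_round2(r.r2)) if display else r.r2,
                    "rmse": float(_round2(r.rmse)) if display else r.rmse,
                    "rpiq": float(_round2(r.rpiq)) if display else r.rpiq,
                    "category": r.category,
                }
            )
        if self.rows:
            m = self.mean_row
            m["model"] = self.rows[0].model
            recs.append(m)
        return pd.DataFrame(recs)


def evaluate_grouped(gc, ds=None) -> GroupedReport:
    """Validation-set metrics for a :class:`GroupedCalibration`.

    Metrics are computed on the target scale the models were fitted on
    (log space by default).  Groups whose validation set has fewer than 2
    samples are excluded with a warning.
    """
    import warnings

    rows = []
    for lab, gf in gc.groups.items():
        idx = gf.indices
        val = gf.split.val
        if len(val) < 2:
            warnings.warn(f"group {lab!r} validation set too small; skipped",
                          stacklevel=2)
            continue
        obs = gc.y[idx][val]
        pred = gf.model.predict(gc.X[idx][val])
        rows.append(
            ReportRow(
                group=str(lab),
                n=len(idx),
                model=gc.model_name,
                r2=r2(obs, pred),
                rmse=rmse(obs, pred),
                rpiq=rpiq(obs, pred),
            )
        )
    g = gc.global_fit
    obs = gc.y[g.split.val]
    pred = g.model.predict(gc.X[g.split.val])
    all_row = ReportRow(
        group="All",
        n=len(gc.y),
        model=gc.model_name,
        r2=r2(obs, pred),
        rmse=rmse(obs, pred),
        rpiq=rpiq(obs, pred),
    )
    return GroupedReport(rows=rows, all_row=all_row)


# ---------------------------------------------------------------------------
# random-forest band importance
# ---------------------------------------------------------------------------


@dataclass
class ImportanceProfile:
    wavelengths: np.ndarray
    importance: np.ndarray  # mean OOB MSE increase per band
    ntree: int
    mtry: int
    seed: int

    def top_bands(self, k: int = 10) -> np.ndarray:
        order = np.argsort(self.importance)[::-1][:k]
        return self.wavelengths[order]


def band_importance_rf(
    X: np.ndarray,
    y: np.ndarray,
    *,
    wavelengths=None,
    ntree: int = 500,
    mtry: int | None = None,
    seed: int = 0,
) -> ImportanceProfile:
    """Permutation band importance from a regression random forest.

    A bagged ensemble of CART trees (``mtry`` features per split,
    regression default m/3) is fitted; for each tree the out-of-bag MSE
    increase after permuting one band is recorded, and importances are the
    increase averaged over trees — Breiman's OOB permutation importance,
    which is less biased than impurity importance for strongly correlated
    spectral bands.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if m < 2:
        raise EvaluationError("need at least 2 bands")
    if n < 30:
        raise EvaluationError("need at least 30 samples")
    if mtry is None:
        mtry = max(1, m // 3)
    wavelengths = (
        np.arange(m) if wavelengths is None else np.asarray(wavelengths, dtype=float)
    )
    if len(wavelengths) != m:
        raise EvaluationError("wavelengths length mismatch")

    forest = BaggingRegressor(
        estimator=DecisionTreeRegressor(max_features=mtry, random_state=0),
        n_estimators=ntree,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)

    rng = np.random.default_rng(seed)
    deltas = np.zeros(m)
    counts = np.zeros(m)
    for tree, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samples, assume_unique=False)
        if oob.size < 2:
            continue
        Xo = X[oob]
        base = float(np.mean((tree.predict(Xo) - y[oob]) ** 2))
        perm = rng.permutation(oob.size)
        for f in range(m):
            saved = Xo[:, f].copy()
            Xo[:, f] = saved[perm]
            mse = float(np.mean((tree.predict(Xo) - y[oob]) ** 2))
            Xo[:, f] = saved
            deltas[f] += mse - base
            counts[f] += 1
    counts[counts == 0] = 1
    return ImportanceProfile(
        wavelengths=wavelengths,
        importance=deltas / counts,
        ntree=ntree,
        mtry=mtry,
        seed=seed,
    )
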