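"""Spectral library container, I/O and preprocessing.

The central object is :class:`SpectralDataset`: a wide table of soil samples
with geographic coordinates, a target variable (soil organic carbon, SOC,
in g kg^-1) and one numeric column per wavelength (nm).  Preprocessing
follows the common vis-NIR chemometrics chain: resample to a coarser band
grid, convert reflectance to absorbance log10(1/R), and smooth with a
Savitzky-Golay filter.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter


class SpectraError(ValueError):
    """Raised on malformed or invalid spectral data."""


@dataclass
class SpectralDataset:
    """A spectral library: samples x wavelengths plus metadata.

    Parameters
    ----------
    ids : array of str
        Sample identifiers, one per row.
    coords : (n, 2) float array
        Longitude, latitude in WGS84 decimal degrees (or projected/synthetic
        planar coordinates when a Euclidean metric is used downstream).
    wavelengths : (m,) float array
        Strictly increasing band centers in nm.
    values : (n, m) float array
        Reflectance in (0, 1] or absorbance, according to ``mode``.
    mode : {"reflectance", "absorbance"}
    target : (n,) float array, optional
        SOC in g kg^-1 (or any scalar property to calibrate against).
    strata : array of str, optional
        Categorical label per sample, e.g. land cover class.
    """

    ids: np.ndarray
    coords: np.ndarray
    wavelengths: np.ndarray
    values: np.ndarray
    mode: str = "reflectance"
    target: np.ndarray | None = None
    strata: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
        if self.strata is not None:
            self.strata = np.asarray(self.strata, dtype=object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, m = self.values.shape
        if len(self.ids) != n:
            raise SpectraError(f"{len(self.ids)} ids for {n} spectra")
        if self.coords.shape != (n, 2):
            raise SpectraError(f"coords shape {self.coords.shape}, expected ({n}, 2)")
        if len(self.wavelengths) != m:
            raise SpectraError(
                f"{len(self.wavelengths)} wavelengths for {m} spectral columns"
            )
        if m > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if self.mode not in ("reflectance", "absorbance"):
            raise SpectraError(f"unknown mode {self.mode!r}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            raise SpectraError(f"non-finite spectral values, first at {bad[0]}")
        if self.mode == "reflectance":
            if np.any(self.values <= 0) or np.any(self.values > 1):
                rows = np.unique(
                    np.where((self.values <= 0) | (self.values > 1))[0]
                )
                raise SpectraError(
                    "reflectance outside (0, 1] for samples "
                    + ", ".join(str(self.ids[r]) for r in rows[:10])
                )
        if self.target is not None and len(self.target) != n:
            raise SpectraError("target length mismatch")
        if self.strata is not None and len(self.strata) != n:
            raise SpectraError("strata length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def replace(self, **kw) -> "SpectralDataset":
        return dataclasses.replace(self, **kw)

    def subset(self, idx) -> "SpectralDataset":
        """Row subset by integer index array (order preserved)."""
        idx = np.asarray(idx)
        return SpectralDataset(
            ids=self.ids[idx],
            coords=self.coords[idx],
            wavelengths=self.wavelengths,
            values=self.values[idx],
            mode=self.mode,
            target=None if self.target is None else self.target[idx],
            strata=None if self.strata is None else self.strata[idx],
        )

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {"id": self.ids, "lon": self.coords[:, 0], "lat": self.coords[:, 1]}
        if self.target is not None:
            cols["soc"] = self.target
        if self.strata is not None:
            cols["stratum"] = self.strata
        df = pd.DataFrame(cols)
        spec = pd.DataFrame(
            self.values, columns=[_fmt_wavelength(w) for w in self.wavelengths]
        )
        return pd.concat([df, spec.set_index(df.index)], axis=1)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _fmt_wavelength(w: float) -> str:
    return f"{w:g}"


@dataclass
class SummaryStats:
    """Moment summary of a target variable (units of the target)."""

    mean: float
    median: float
    sd: float
    skewness: float  # g1 = m3 / m2^1.5; nan when sd == 0
    kurtosis: float  # raw b2 = m4 / m2^2; nan when sd == 0
    excess_kurtosis: float  # b2 - 3
    min: float
    max: float
    n: int


def read_spectra_table(
    path,
    *,
    mode: str = "reflectance",
    id_col: str = "id",
    lon_col: str = "lon",
    lat_col: str = "lat",
    target_col: str = "soc",
    stratum_col: str = "stratum",
) -> SpectralDataset:
    """Read a wide spectral-library CSV into a :class:`SpectralDataset`.

    The file must contain ``id``, ``lon``, ``lat`` columns, optionally a
    target and a stratum column, and numeric wavelength-named columns
    (e.g. ``400``, ``410.5``).  Wavelength columns are sorted ascending;
    row order is preserved.
    """
    df = pd.read_csv(path)
    for col in (id_col, lon_col, lat_col):
        if col not in df.columns:
            raise SpectraError(f"required column {col!r} missing from {path}")
    meta = {id_col, lon_col, lat_col, target_col, stratum_col}
    wl_cols = []
    for c in df.columns:
        if c in meta:
            continue
        try:
            wl_cols.append((float(c), c))
        except ValueError:
            raise SpectraError(f"unrecognized non-wavelength column {c!r}")
    if not wl_cols:
        raise SpectraError("no wavelength columns found")
    wl_cols.sort()
    wavelengths = np.array([w for w, _ in wl_cols])
    spec = df[[c for _, c in wl_cols]]
    try:
        values = spec.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for c in spec.columns:
            coerced = pd.to_numeric(spec[c], errors="coerce")
            if coerced.isna().any() and not spec[c].isna().any():
                row = int(np.where(coerced.isna())[0][0])
                raise SpectraError(
                    f"non-numeric reflectance at row {row}, column {c!r}"
                )
        raise
    if np.isnan(values).any():
        rows, cols = np.where(np.isnan(values))
        raise SpectraError(
            f"missing reflectance at row {rows[0]}, column {spec.columns[cols[0]]}"
        )
    return SpectralDataset(
        ids=df[id_col].astype(str).to_numpy(),
        coords=df[[lon_col, lat_col]].to_numpy(dtype=float),
        wavelengths=wavelengths,
        values=values,
        mode=mode,
        target=df[target_col].to_numpy(dtype=float) if target_col in df else None,
        strata=df[stratum_col].astype(str).to_numpy() if stratum_col in df else None,
    )


def resample_spectra(
    ds: SpectralDataset, interval: float, *, method: str = "mean"
) -> SpectralDataset:
    """Resample spectra onto a coarser regular grid.

    Output band centers run from the first native wavelength upward in
    steps of ``interval``; each output band is the mean of native channels
    in the half-open window [c - interval/2, c + interval/2), clipped to
    the native range.  ``method="interp"`` uses linear interpolation at
    the band centers instead.
    """
    wl = ds.wavelengths
    native = np.diff(wl)
    if native.size and interval < native.min() - 1e-12:
        raise SpectraError(
            f"resampling interval {interval} finer than native spacing {native.min()}"
        )
    centers = np.arange(wl[0], wl[-1] + interval / 2, interval)
    centers = centers[centers <= wl[-1] + 1e-9]
    if method == "interp":
        out = np.vstack([np.interp(centers, wl, row) for row in ds.values])
    elif method == "mean":
        lo = np.searchsorted(wl, centers - interval / 2, side="left")
        hi = np.searchsorted(wl, centers + interval / 2, side="left")
        hi = np.maximum(hi, lo + 1)  # window always covers the center channel
        csum = np.concatenate(
            [np.zeros((ds.n_samples, 1)), np.cumsum(ds.values, axis=1)], axis=1
        )
        out = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    else:
        raise SpectraError(f"unknown resampling method {method!r}")
    return ds.replace(wavelengths=centers, values=out)


def to_absorbance(ds: SpectralDataset) -> SpectralDataset:
    """Convert reflectance R in (0, 1] to absorbance A = log10(1/R)."""
    if ds.mode != "reflectance":
        raise SpectraError("dataset is not in reflectance mode")
    if np.any(ds.values <= 0):
        rows = np.unique(np.where(ds.values <= 0)[0])
        raise SpectraError(
            "non-positive reflectance for samples "
            + ", ".join(str(ds.ids[r]) for r in rows[:10])
        )
    return ds.replace(values=np.log10(1.0 / ds.values), mode="absorbance")


def from_absorbance(ds: SpectralDataset) -> SpectralDataset:
    """Inverse of :func:`to_absorbance`: R = 10^(-A)."""
    if ds.mode != "absorbance":
        raise SpectraError("dataset is not in absorbance mode")
    return ds.replace(values=10.0 ** (-ds.values), mode="reflectance")


def savgol_smooth(
    ds: SpectralDataset, window: int = 15, order: int = 2
) -> SpectralDataset:
    """Savitzky-Golay smoothing along the wavelength axis.

    Each band is replaced by the value of a local least-squares polynomial
    of the given order fitted over ``window`` channels.  Edges are handled
    by polynomial extrapolation from the nearest full window, so the band
    count is unchanged and any polynomial of degree <= ``order`` passes
    through unaltered.
    """
    if window % 2 == 0:
        raise SpectraError("window must be odd")
    if order >= window:
        raise SpectraError("polynomial order must be smaller than window")
    if window > ds.n_bands:
        raise SpectraError(f"window {window} exceeds band count {ds.n_bands}")
    out = savgol_filter(ds.values, window, order, axis=1, mode="interp")
    return ds.replace(values=out)


def log_transform_target(
    y, *, floor: float = 0.1, policy: str = "drop"
) -> tuple[np.ndarray, np.ndarray]:
    """Natural-log transform of the target with a positivity floor.

    SOC distributions in large libraries are strongly right-skewed;
    modeling is done on ln(SOC).  Samples with y below ``floor``
    (default 0.1 g kg^-1) cannot be log-transformed meaningfully and are
    dropped (``policy="drop"``) or raise (``policy="error"``).

    Returns
    -------
    (log_y, kept) : transformed values and a boolean keep-mask aligned
    with the input.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise SpectraError("target contains non-finite values")
    kept = y >= floor
    if policy == "error" and not kept.all():
        raise SpectraError(f"{(~kept).sum()} samples below floor {floor}")
    if not kept.any():
        raise SpectraError("all samples below the positivity floor")
    if not kept.all():
        warnings.warn(
            f"dropped {(~kept).sum()} samples with target below {floor}",
            stacklevel=2,
        )
    return np.log(y[kept]), kept


def describe_target(y) -> SummaryStats:
    """Moment-based summary of the target distribution.

    Skewness g1 = m3 / m2^1.5 and raw kurtosis b2 = m4 / m2^2 (population
    moments, no bias correction); both the raw and the excess (b2 - 3)
    kurtosis are reported since conventions differ between software
    packages.  A constant input yields sd 0 and NaN shape coefficients.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise SpectraError("need at least two values")
    mu = y.mean()
    d = y - mu
    m2 = np.mean(d**2)
    if m2 == 0:
        skew = kurt = math.nan
    else:
        skew = np.mean(d**3) / m2**1.5
        kurt = np.mean(d**4) / m2**2
    return SummaryStats(
        mean=float(mu),
        median=float(np.median(y)),
        sd=float(math.sqrt(m2)),
        skewness=float(skew),
        kurtosis=float(kurt),
        excess_kurtosis=float(kurt - 3) if not math.isnan(kurt) else math.nan,
        min=float(y.min()),
        max=float(y.max()),
        n=int(y.size),
    )
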