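"""Synthetic spatially structured soil spectral libraries.

The generator emulates the statistical structure of a continental soil
vis-NIR library without any claim to radiative-transfer realism:

* samples fall in spatially clustered groups (Gaussian blobs in a
  synthetic 10 x 10 degree region, or uniformly for homogeneous scenes);
* each cluster has a smooth absorbance endmember — a sloping baseline
  plus Gaussian absorption features near 1400, 1900 and 2200 nm (water,
  clay and organo-mineral bands);
* SOC is lognormal with cluster-specific log-medians, and is coupled to
  the spectrum: higher SOC raises absorbance (darkens the soil), so SOC
  and mean reflectance are negatively correlated by construction;
* the coupling shape/strength can differ per cluster, creating scenes
  where one global spectra-to-SOC model is mis-specified but per-cluster
  models are not;
* noise is a smooth Gaussian process along wavelength (length scale
  ~50 nm), mimicking instrument drift rather than white noise.

Everything is deterministic given the config and its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from spectroclust.spectral_data import SpectralDataset

STRATA_NAMES = ("cropland", "grassland", "shrubland", "woodland")


class SceneError(ValueError):
    pass


@dataclass
class SceneConfig:
    """Configuration of a synthetic scene; all per-cluster fields must have
    one entry per cluster.

    Absorbance model for sample j of cluster c at wavelength lam:

        A(lam) = offset_c + slope_c * s(lam)
                 + sum_k depth_ck * exp(-((lam - center_k)^2 / (2 width_k^2)))
                 + coupling_c * (ln SOC_j - soc_log_ref) * g_c(lam)
                 + GP noise,

    with s(lam) the 0..1 normalized wavelength and g_c a smooth positive
    coupling shape (``coupling_freq``/``coupling_phase`` bend it per
    cluster; both zero gives a broad visible-weighted default).
    Reflectance is R = 10^(-A), clipped into (0, 1].
    """

    n_per_cluster: tuple = (250, 250, 250, 250)
    wl_start: float = 400.0
    wl_stop: float = 2500.0
    wl_step: float = 10.0
    spatial_centers: tuple = ((2.5, 42.5), (7.5, 42.5), (2.5, 47.5), (7.5, 47.5))
    spatial_spread: float = 0.8
    spatial_uniform: bool = False
    region: tuple = (0.0, 10.0, 40.0, 50.0)  # lon min/max, lat min/max
    baseline_offset: tuple = (0.40, 0.80, 1.20, 1.60)
    baseline_slope: tuple = (-0.10, -0.30, -0.10, -0.30)
    feature_centers: tuple = (1400.0, 1900.0, 2200.0)
    feature_widths: tuple = (60.0, 80.0, 100.0)
    feature_depths: tuple = (
        (0.04, 0.40, 0.06),
        (0.40, 0.06, 0.08),
        (0.06, 0.10, 0.40),
        (0.28, 0.28, 0.28),
    )
    soc_log_median: tuple = (2.99, 3.15, 3.24, 3.50)
    soc_log_sigma: float = 0.8
    soc_log_ref: float = 3.2
    coupling: tuple = (0.06, 0.06, 0.06, 0.06)
    coupling_freq: tuple = (0.0, 0.0, 0.0, 0.0)
    coupling_phase: tuple = (0.0, 0.0, 0.0, 0.0)
    coupling_band: float | None = None  # narrow planted band center (nm)
    coupling_band_width: float = 15.0
    noise_sd: float = 0.01
    noise_length_scale: float = 50.0
    strata_flip: float | None = None
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.n_per_cluster)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_start, self.wl_stop + self.wl_step / 2, self.wl_step)

    def replace(self, **kw) -> "SceneConfig":
        return dataclasses.replace(self, **kw)

    def validate(self) -> None:
        C = self.n_clusters
        if any(n <= 0 for n in self.n_per_cluster):
            raise SceneError("cluster sizes must be positive")
        for name in (
            "spatial_centers",
            "baseline_offset",
            "baseline_slope",
            "feature_depths",
            "soc_log_median",
            "coupling",
            "coupling_freq",
            "coupling_phase",
        ):
            if len(getattr(self, name)) != C:
                raise SceneError(f"{name} needs one entry per cluster ({C})")
        if self.noise_sd < 0 or self.spatial_spread < 0 or self.soc_log_sigma < 0:
            raise SceneError("spreads and noise sd must be non-negative")


def _coupling_shape(cfg: SceneConfig, c: int, wl: np.ndarray) -> np.ndarray:
    if cfg.coupling_band is not None:
        return np.exp(-0.5 * ((wl - cfg.coupling_band) / cfg.coupling_band_width) ** 2)
    s = (wl - cfg.wl_start) / (cfg.wl_stop - cfg.wl_start)
    base = 0.5 + 0.5 * np.exp(-(((wl - 600.0) / 500.0) ** 2))
    f = cfg.coupling_freq[c]
    if f == 0:
        return base
    # bent variant: stays positive, shifts weight across the spectrum
    return 0.6 + 0.45 * np.cos(2 * np.pi * f * s + cfg.coupling_phase[c])


def _smooth_noise(rng, n, m, step_nm, length_scale, sd) -> np.ndarray:
    if sd == 0:
        return np.zeros((n, m))
    white = rng.standard_normal((n, m))
    sigma_bands = length_scale / step_nm
    sm = gaussian_filter1d(white, sigma_bands, axis=1, mode="nearest")
    scale = sm.std()
    return sd * sm / (scale if scale > 0 else 1.0)


def generate_scene(cfg: SceneConfig):
    """Generate a scene.

    Returns
    -------
    (dataset, labels, memberships) :
        the :class:`SpectralDataset` (reflectance mode, SOC target,
        optional strata), the planted cluster label per sample, and the
        planted (one-hot) membership matrix of shape (C, n).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.wavelengths
    m = len(wl)
    s = (wl - cfg.wl_start) / (cfg.wl_stop - cfg.wl_start)

    coords_list, soc_list, spec_list, labels_list = [], [], [], []
    for c, n_c in enumerate(cfg.n_per_cluster):
        if cfg.spatial_uniform:
            lon = rng.uniform(cfg.region[0], cfg.region[1], n_c)
            lat = rng.uniform(cfg.region[2], cfg.region[3], n_c)
        else:
            cx, cy = cfg.spatial_centers[c]
            lon = rng.normal(cx, cfg.spatial_spread, n_c)
            lat = rng.normal(cy, cfg.spatial_spread, n_c)
        ln_soc = rng.normal(cfg.soc_log_median[c], cfg.soc_log_sigma, n_c)

        endmember = cfg.baseline_offset[c] + cfg.baseline_slope[c] * s
        for center, width, depth in zip(
            cfg.feature_centers, cfg.feature_widths, cfg.feature_depths[c]
        ):
            endmember = endmember + depth * np.exp(
                -0.5 * ((wl - center) / width) ** 2
            )
        g = _coupling_shape(cfg, c, wl)
        A = (
            endmember[None, :]
            + cfg.coupling[c] * (ln_soc - cfg.soc_log_ref)[:, None] * g[None, :]
            + _smooth_noise(
                rng, n_c, m, cfg.wl_step, cfg.noise_length_scale, cfg.noise_sd
            )
        )
        coords_list.append(np.column_stack([lon, lat]))
        soc_list.append(np.exp(ln_soc))
        spec_list.append(A)
        labels_list.append(np.full(n_c, c))

    A = np.vstack(spec_list)
    A = np.clip(A, 0.005, 2.5)
    R = 10.0 ** (-A)
    labels = np.concatenate(labels_list)
    n = len(labels)

    strata = None
    if cfg.strata_flip is not None:
        strata_idx = labels % len(STRATA_NAMES)
        flip = rng.random(n) < cfg.strata_flip
        strata_idx = np.where(
            flip, rng.integers(0, len(STRATA_NAMES), n), strata_idx
        )
        strata = np.array([STRATA_NAMES[i] for i in strata_idx])

    ds = SpectralDataset(
        ids=np.array([f"s{i:05d}" for i in range(n)]),
        coords=np.vstack(coords_list),
        wavelengths=wl,
        values=R,
        mode="reflectance",
        target=np.concatenate(soc_list),
        strata=strata,
    )
    memberships = np.zeros((cfg.n_clusters, n))
    memberships[labels, np.arange(n)] = 1.0
    return ds, labels, memberships


_PRESETS = {
    # well-separated endmembers and compact spatial blobs: cluster-count
    # sweeps and hard labels should recover the planted partition
    "four-cluster-separated": dict(),
    # moderately separated endmembers but strongly different SOC-to-spectrum
    # coupling per cluster: one global calibration is mis-specified while
    # per-cluster calibrations are not
    "heterogeneous-slopes": dict(
        n_per_cluster=(200, 200, 200, 200),
        soc_log_median=(3.0, 3.2, 3.3, 3.5),
        coupling=(0.05, 0.10, 0.16, 0.24),
        coupling_freq=(1.0, 1.5, 2.0, 2.5),
        coupling_phase=(0.0, 1.5707963267948966, 3.141592653589793, 4.71238898038469),
        strata_flip=0.3,
    ),
    # SOC driven by one narrow band near 1400 nm: band-importance profiling
    # should light up that region
    "planted-band": dict(
        n_per_cluster=(300,),
        spatial_centers=((5.0, 45.0),),
        baseline_offset=(0.6,),
        baseline_slope=(-0.15,),
        feature_depths=((0.12, 0.15, 0.10),),
        soc_log_median=(3.2,),
        coupling=(0.3,),
        coupling_freq=(0.0,),
        coupling_phase=(0.0,),
        coupling_band=1400.0,
        noise_sd=0.005,
    ),
    # single spatially uniform population: the bandwidth-selection score
    # curve should be flat at large bandwidths
    "homogeneous": dict(
        n_per_cluster=(200,),
        spatial_centers=((5.0, 45.0),),
        spatial_uniform=True,
        baseline_offset=(0.7,),
        baseline_slope=(-0.15,),
        feature_depths=((0.12, 0.15, 0.10),),
        soc_log_median=(3.2,),
        coupling=(0.12,),
        coupling_freq=(0.0,),
        coupling_phase=(0.0,),
    ),
}


def scene_presets() -> tuple:
    """Names of the built-in scene presets."""
    return tuple(_PRESETS)


def preset_config(name: str, seed: int = 0) -> SceneConfig:
    """Build the :class:`SceneConfig` for a named preset."""
    if name not in _PRESETS:
        raise SceneError(f"unknown preset {name!r}; known: {sorted(_PRESETS)}")
    return SceneConfig(seed=seed, **_PRESETS[name])
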