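import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectroclust.spectral_data import (
    SpectraError,
    SpectralDataset,
    describe_target,
    from_absorbance,
    log_transform_target,
    read_spectra_table,
    resample_spectra,
    savgol_smooth,
    to_absorbance,
)


def make_ds(values, wavelengths=None, mode="reflectance", **kw):
    values = np.atleast_2d(np.asarray(values, float))
    n, m = values.shape
    if wavelengths is None:
        wavelengths = 400 + 10 * np.arange(m)
    return SpectralDataset(
        ids=np.array([f"s{i}" for i in range(n)]),
        coords=np.column_stack([np.linspace(0, 1, n), np.full(n, 45.0)]),
        wavelengths=np.asarray(wavelengths, float),
        values=values,
        mode=mode,
        **kw,
    )


class TestReadTable:
    def test_reads_wide_csv(self, tiny_csv):
        ds = read_spectra_table(tiny_csv)
        assert ds.n_samples == 3 and ds.n_bands == 2
        assert list(ds.ids) == ["a", "b", "c"]
        assert ds.wavelengths.tolist() == [400.0, 410.0]
        assert ds.target is not None and ds.target[1] == 25.0

    def test_wavelength_columns_sorted(self, tmp_path):
        p = tmp_path / "unordered.csv"
        p.write_text("id,lon,lat,soc,410,400\na,1,40,10,0.6,0.5\n")
        ds = read_spectra_table(p)
        assert ds.wavelengths.tolist() == [400.0, 410.0]
        assert ds.values[0].tolist() == [0.5, 0.6]

    def test_reflectance_above_one_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,lon,lat,soc,400\na,1,40,10,1.2\n")
        with pytest.raises(SpectraError):
            read_spectra_table(p)

    def test_non_numeric_reflectance_located(self, tmp_path):
        p = tmp_path / "nn.csv"
        p.write_text("id,lon,lat,soc,400\na,1,40,10,oops\n")
        with pytest.raises(SpectraError, match="row 0.*400"):
            read_spectra_table(p)

    def test_missing_coordinate_column(self, tmp_path):
        p = tmp_path / "noc.csv"
        p.write_text("id,lat,soc,400\na,40,10,0.5\n")
        with pytest.raises(SpectraError, match="lon"):
            read_spectra_table(p)

    def test_roundtrip_write_read(self, tiny_csv, tmp_path):
        ds = read_spectra_table(tiny_csv)
        out = tmp_path / "copy.csv"
        ds.write_csv(out)
        ds2 = read_spectra_table(out)
        np.testing.assert_allclose(ds.values, ds2.values)
        assert list(ds.ids) == list(ds2.ids)


class TestResample:
    def test_band_count_for_native_half_nm(self):
        wl = np.arange(400, 2500.5, 0.5)
        ds = make_ds(np.full((1, len(wl)), 0.5), wl)
        out = resample_spectra(ds, 10)
        assert out.n_bands == 211
        assert out.wavelengths[0] == 400 and out.wavelengths[-1] == 2500

    def test_identity_on_matching_grid(self, rng):
        ds = make_ds(rng.uniform(0.2, 0.8, (3, 20)))
        out = resample_spectra(ds, 10)
        np.testing.assert_allclose(out.values, ds.values)

    def test_window_means_match_bruteforce(self, rng):
        wl = np.arange(400, 410, 0.5)
        vals = rng.uniform(0.1, 0.9, (1, len(wl)))
        ds = make_ds(vals, wl)
        out = resample_spectra(ds, 2.0)
        for c, got in zip(out.wavelengths, out.values[0]):
            mask = (wl >= c - 1.0) & (wl < c + 1.0)
            assert got == pytest.approx(vals[0][mask].mean(), abs=1e-12)

    def test_idempotent(self, rng):
        wl = np.arange(400, 500, 0.5)
        ds = make_ds(rng.uniform(0.2, 0.8, (2, len(wl))), wl)
        once = resample_spectra(ds, 10)
        twice = resample_spectra(once, 10)
        np.testing.assert_allclose(once.values, twice.values)

    def test_interval_finer_than_native_rejected(self, rng):
        ds = make_ds(rng.uniform(0.2, 0.8, (1, 10)))
        with pytest.raises(SpectraError):
            resample_spectra(ds, 5)


class TestAbsorbance:
    @pytest.mark.parametrize("r, a", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_log10_values(self, r, a):
        ds = make_ds([[r, r]])
        assert to_absorbance(ds).values[0, 0] == pytest.approx(a, abs=1e-12)

    def test_roundtrip_identity(self, rng):
        ds = make_ds(rng.uniform(0.05, 1.0, (4, 7)))
        back = from_absorbance(to_absorbance(ds))
        np.testing.assert_allclose(back.values, ds.values, atol=1e-12)

    def test_mode_flag_updated(self):
        ds = to_absorbance(make_ds([[0.5, 0.5]]))
        assert ds.mode == "absorbance"
        with pytest.raises(SpectraError):
            to_absorbance(ds)


class TestSavgol:
    def test_reproduces_quadratic_exactly(self):
        wl = 400 + 10 * np.arange(51)
        y = 1e-6 * (wl - 1000) ** 2 + 0.01 * wl + 3
        ds = make_ds(y[None, :], wl, mode="absorbance")
        out = savgol_smooth(ds, 15, 2)
        np.testing.assert_allclose(out.values, ds.values, atol=1e-10)

    def test_constant_unchanged(self):
        ds = make_ds(np.full((2, 31), 0.4))
        out = savgol_smooth(ds, 15, 2)
        np.testing.assert_allclose(out.values, ds.values, atol=1e-12)

    def test_matches_least_squares_window_oracle(self, rng):
        m, window, order = 41, 9, 2
        y = np.sin(np.linspace(0, 6, m)) + rng.normal(0, 0.1, m)
        ds = make_ds(y[None, :], mode="absorbance")
        out = savgol_smooth(ds, window, order)
        half = window // 2
        for i in range(half, m - half):  # interior: explicit LS fit
            xs = np.arange(-half, half + 1)
            coef = np.polyfit(xs, y[i - half : i + half + 1], order)
            assert out.values[0, i] == pytest.approx(np.polyval(coef, 0), abs=1e-10)
        # edges: polynomial fit to the nearest full window, extrapolated
        coef = np.polyfit(np.arange(window), y[:window], order)
        for i in range(half):
            assert out.values[0, i] == pytest.approx(np.polyval(coef, i), abs=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        r = np.random.default_rng(seed)
        X, Y = r.standard_normal((2, 1, 21))
        f = lambda v: savgol_smooth(make_ds(v, mode="absorbance"), 7, 2).values
        np.testing.assert_allclose(f(a * X + b * Y), a * f(X) + b * f(Y), atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(SpectraError):
            savgol_smooth(make_ds(np.full((1, 30), 0.5)), 14, 2)

    def test_window_exceeding_bands_rejected(self):
        with pytest.raises(SpectraError):
            savgol_smooth(make_ds(np.full((1, 10), 0.5)), 15, 2)


class TestLogTarget:
    def test_max_soc_maps_to_printed_log_max(self):
        y, kept = log_transform_target(np.array([586.8, 1.0]))
        assert round(float(y[0]), 2) == 6.37

    @pytest.mark.parametrize("v, expect", [(1.0, 0.0), (math.e, 1.0)])
    def test_natural_log(self, v, expect):
        y, _ = log_transform_target(np.array([v, 5.0]))
        assert y[0] == pytest.approx(expect, abs=1e-12)

    def test_subfloor_samples_dropped_and_reported(self):
        with pytest.warns(UserWarning, match="dropped 2"):
            y, kept = log_transform_target(np.array([0.0, 0.05, 10.0]))
        assert kept.tolist() == [False, False, True]
        assert len(y) == 1

    def test_all_dropped_raises(self):
        with pytest.raises(SpectraError):
            log_transform_target(np.array([0.0, 0.0]))


class TestDescribeTarget:
    def test_symmetric_vector_zero_skew(self):
        s = describe_target(np.array([1.0, 2.0, 3.0]))
        assert s.skewness == pytest.approx(0.0, abs=1e-12)
        assert s.min <= s.median <= s.max

    def test_hand_computed_moments(self):
        s = describe_target(np.array([0.0, 0.0, 0.0, 1.0]))
        assert s.mean == pytest.approx(0.25)
        assert s.sd == pytest.approx(math.sqrt(0.1875), abs=1e-12)
        assert s.skewness == pytest.approx(0.09375 / 0.1875**1.5, abs=1e-12)
        assert s.kurtosis == pytest.approx(0.08203125 / 0.1875**2, abs=1e-12)
        assert s.excess_kurtosis == pytest.approx(s.kurtosis - 3, abs=1e-12)

    def test_constant_vector_undefined_shape(self):
        s = describe_target(np.full(5, 2.5))
        assert s.sd == 0.0
        assert math.isnan(s.skewness) and math.isnan(s.kurtosis)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_moment_oracle(self, seed):
        y = np.random.default_rng(seed).standard_normal(20)
        s = describe_target(y)
        d = y - y.mean()
        m2, m3, m4 = (np.mean(d**k) for k in (2, 3, 4))
        assert s.sd == pytest.approx(math.sqrt(m2), abs=1e-12)
        assert s.skewness == pytest.approx(m3 / m2**1.5, rel=1e-10)
        assert s.kurtosis == pytest.approx(m4 / m2**2, rel=1e-10)


class TestDatasetInvariants:
    def test_row_metadata_lengths_enforced(self):
        with pytest.raises(SpectraError):
            SpectralDataset(
                ids=np.array(["a"]),
                coords=np.array([[0.0, 0.0], [1.0, 1.0]]),
                wavelengths=np.array([400.0]),
                values=np.array([[0.5], [0.5]]),
            )

    def test_decreasing_wavelengths_rejected(self):
        with pytest.raises(SpectraError):
            make_ds([[0.5, 0.5]], wavelengths=[410, 400])

    def test_nan_rejected(self):
        with pytest.raises(SpectraError):
            make_ds([[0.5, np.nan]])
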