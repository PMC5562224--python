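"""Spectral unmixing: exact recovery, oracle equivalence, validity logic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oeot import (
    ExtinctionTable,
    IllPosedUnmixingError,
    MultispectralSeries,
    unmix_pixelwise,
    unmix_roi_series,
    unmix_spectrum,
)
from oeot.unmixing import block_downsample


def make_series(data, wavelengths, spacing=0.075):
    n_f = data.shape[0]
    return MultispectralSeries(
        data=data,
        wavelengths=wavelengths,
        frame_times=np.arange(n_f) * 11.5,
        pixel_spacing=spacing,
    )


def uniform_series(ext_table, wavelengths, so2, thb=10.0, shape=(12, 12), n_frames=3):
    E = ext_table.design_matrix(wavelengths)
    spectrum = E @ np.array([thb * so2, thb * (1 - so2)])
    data = np.broadcast_to(
        spectrum[None, :, None, None], (n_frames, len(wavelengths), *shape)
    ).copy()
    return make_series(data, wavelengths)


class TestExtinctionTable:
    def test_rejects_non_monotone_wavelengths(self):
        with pytest.raises(ValueError, match="ascending"):
            ExtinctionTable([700, 690, 710], [1, 2, 3], [3, 2, 1])

    def test_rejects_non_positive_extinction(self):
        with pytest.raises(ValueError, match="positive"):
            ExtinctionTable([700, 710], [1.0, 0.0], [1.0, 2.0])

    def test_rejects_out_of_range_query(self, ext_table):
        with pytest.raises(ValueError, match="outside"):
            ext_table.interp([650.0])

    def test_isosbestic_point_near_800nm(self, ext_table):
        wl = ext_table.isosbestic_wavelength(near_nm=800.0, tol=0.05)
        assert 780 <= wl <= 820
        e1, e2 = ext_table.interp([wl])[0]
        assert abs(e1 - e2) / e2 < 0.05

    def test_interpolation_identity_at_tabulated_rows(self, ext_table):
        i = len(ext_table.wavelengths) // 2
        row = ext_table.interp([ext_table.wavelengths[i]])[0]
        assert row[0] == ext_table.eps_hbo2[i]
        assert row[1] == ext_table.eps_hb[i]

    def test_midpoint_is_arithmetic_mean_of_rows(self, ext_table):
        wl = ext_table.wavelengths
        mid = 0.5 * (wl[3] + wl[4])
        row = ext_table.interp([mid])[0]
        np.testing.assert_allclose(
            row,
            [(ext_table.eps_hbo2[3] + ext_table.eps_hbo2[4]) / 2,
             (ext_table.eps_hb[3] + ext_table.eps_hb[4]) / 2],
        )


class TestUnmixSpectrum:
    @pytest.mark.parametrize("c_true", [(0.3, 0.7), (1.0, 0.0), (0.05, 2.5)])
    def test_noiseless_linear_recovery(self, ext_table, wavelengths15, c_true):
        E = ext_table.design_matrix(wavelengths15)
        c = unmix_spectrum(E @ np.asarray(c_true), ext_table, wavelengths15)
        np.testing.assert_allclose(c, c_true, atol=1e-12)

    def test_noisy_spectrum_matches_normal_equations_oracle(self, ext_table, wavelengths15):
        rng = np.random.default_rng(7)
        E = ext_table.design_matrix(wavelengths15)
        s = E @ np.array([0.4, 0.6])
        s = s + rng.normal(0.0, 0.01 * s.max(), s.shape)
        c = np.asarray(unmix_spectrum(s, ext_table, wavelengths15))
        # independent oracle: solve the normal equations directly
        oracle = np.linalg.solve(E.T @ E, E.T @ s)
        np.testing.assert_allclose(c, oracle, atol=1e-6)

    def test_single_wavelength_is_ill_posed(self, ext_table):
        with pytest.raises(IllPosedUnmixingError):
            unmix_spectrum([1.0], ext_table, [800.0])

    def test_isosbestic_only_set_is_ill_posed(self, ext_table):
        wl = ext_table.isosbestic_wavelength()
        # two near-identical columns: rank deficient design
        tab = ExtinctionTable([wl - 0.01, wl + 0.01],
                              ext_table.interp([wl - 0.01, wl + 0.01])[:, 0],
                              ext_table.interp([wl - 0.01, wl + 0.01])[:, 0] * 1.0000001)
        with pytest.raises(IllPosedUnmixingError):
            unmix_spectrum([1.0, 1.0], tab, [wl - 0.01, wl + 0.01])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        c1=st.floats(0.0, 5.0),
        c2=st.floats(0.0, 5.0),
    )
    def test_round_trip_property(self, ext_table, wavelengths15, c1, c2):
        E = ext_table.design_matrix(wavelengths15)
        c = unmix_spectrum(E @ np.array([c1, c2]), ext_table, wavelengths15)
        np.testing.assert_allclose(c, [c1, c2], atol=1e-9 * max(1.0, c1, c2))

    def test_scale_invariance_of_table(self, ext_table, wavelengths15):
        E = ext_table.design_matrix(wavelengths15)
        s = E @ np.array([0.3, 0.7])
        scaled = ExtinctionTable(ext_table.wavelengths, ext_table.eps_hbo2 * 10,
                                 ext_table.eps_hb * 10)
        c = unmix_spectrum(s, scaled, wavelengths15)
        # weights rescale inversely; the SO2 ratio is unchanged
        assert c[0] / (c[0] + c[1]) == pytest.approx(0.3, abs=1e-10)


class TestRoiSeries:
    def test_uniform_so2_recovered(self, ext_table, wavelengths15):
        series = uniform_series(ext_table, wavelengths15, so2=0.5)
        roi = np.ones(series.shape[2:], dtype=bool)
        df = unmix_roi_series(series, roi, table=ext_table)
        np.testing.assert_allclose(df["so2"], 0.5, atol=1e-10)
        assert df["valid"].all()

    def test_two_halves_equal_thb_average_to_midpoint(self, ext_table, wavelengths15):
        # oracle: averaging the spectra of SO2 0.2 and 0.8 at equal THb
        # gives the spectrum of SO2 0.5, so the ROI estimate must be 0.5
        E = ext_table.design_matrix(wavelengths15)
        thb = 5.0
        s_a = E @ np.array([thb * 0.2, thb * 0.8])
        s_b = E @ np.array([thb * 0.8, thb * 0.2])
        data = np.empty((2, len(wavelengths15), 4, 4))
        data[:, :, :, :2] = s_a[None, :, None, None]
        data[:, :, :, 2:] = s_b[None, :, None, None]
        series = make_series(data, wavelengths15)
        df = unmix_roi_series(series, np.ones((4, 4), bool), table=ext_table)
        np.testing.assert_allclose(df["so2"], 0.5, atol=1e-10)

    def test_zero_signal_roi_all_frames_invalid(self, ext_table, wavelengths15):
        data = np.zeros((3, len(wavelengths15), 4, 4))
        series = make_series(data, wavelengths15)
        with pytest.raises(ValueError, match="invalid"):
            unmix_roi_series(series, np.ones((4, 4), bool), table=ext_table)

    def test_empty_roi_rejected(self, ext_table, wavelengths15):
        series = uniform_series(ext_table, wavelengths15, so2=0.5)
        with pytest.raises(ValueError, match="empty"):
            unmix_roi_series(series, np.zeros(series.shape[2:], bool), table=ext_table)


class TestPixelwise:
    def test_downsampling_geometry(self, ext_table, wavelengths15):
        series = uniform_series(ext_table, wavelengths15, so2=0.4, shape=(13, 14))
        maps = unmix_pixelwise(series, target_spacing=0.225, table=ext_table)
        assert maps[0].so2.shape == (13 // 3, 14 // 3)
        assert maps[0].pixel_spacing == pytest.approx(0.225)

    def test_non_integer_ratio_rejected(self, ext_table, wavelengths15):
        series = uniform_series(ext_table, wavelengths15, so2=0.4)
        with pytest.raises(ValueError, match="integer multiple"):
            unmix_pixelwise(series, target_spacing=0.1, table=ext_table)

    def test_block_mean_weighting_with_uniform_thb(self, ext_table, wavelengths15):
        # per-pixel SO2 varies, THb uniform: coarse SO2 equals the plain
        # block mean of the fine SO2 map
        rng = np.random.default_rng(3)
        so2 = rng.uniform(0.1, 0.9, (6, 6))
        thb = 4.0
        E = ext_table.design_matrix(wavelengths15)
        data = np.einsum("wk,kij->wij", E,
                         np.stack([thb * so2, thb * (1 - so2)]))[None]
        series = make_series(data, wavelengths15)
        maps = unmix_pixelwise(series, target_spacing=0.225, table=ext_table)
        expected = block_downsample(so2, 3)
        np.testing.assert_allclose(maps[0].so2, expected, atol=1e-8)

    def test_all_zero_frame_invalid(self, ext_table, wavelengths15):
        data = np.zeros((1, len(wavelengths15), 6, 6))
        series = make_series(data, wavelengths15)
        maps = unmix_pixelwise(series, target_spacing=0.225, table=ext_table)
        assert not maps[0].valid_mask.any()

    def test_roi_series_equals_mean_pixelwise_on_homogeneous_roi(
        self, ext_table, wavelengths15
    ):
        series = uniform_series(ext_table, wavelengths15, so2=0.35, shape=(9, 9))
        roi = np.ones((9, 9), bool)
        df = unmix_roi_series(series, roi, table=ext_table)
        maps = unmix_pixelwise(series, target_spacing=0.075, table=ext_table)
        assert abs(df["so2"].iloc[0] - np.nanmean(maps[0].so2)) < 1e-8

    def test_so2_bounds_under_noise(self, ext_table, wavelengths15):
        rng = np.random.default_rng(11)
        series = uniform_series(ext_table, wavelengths15, so2=0.5, shape=(8, 8))
        noisy = series.data + rng.normal(0, 0.3 * series.data.mean(), series.data.shape)
        series2 = make_series(noisy, wavelengths15)
        maps = unmix_pixelwise(series2, target_spacing=0.075, table=ext_table)
        so2 = maps[0].so2[maps[0].valid_mask]
        assert np.all((so2 >= 0) & (so2 <= 1))


class TestFluenceBias:
    def test_wavelength_dependent_fluence_biases_so2(self, ext_table, wavelengths15):
        E = ext_table.design_matrix(wavelengths15)
        s = E @ np.array([0.5, 0.5])  # truth SO2 = 0.5
        # fluence decaying with wavelength, as in tissue
        phi = np.exp(-(wavelengths15 - 700.0) / 400.0)
        c = unmix_spectrum(s * phi, ext_table, wavelengths15)
        so2 = max(c[0], 0) / (max(c[0], 0) + max(c[1], 0))
        assert abs(so2 - 0.5) > 0.01  # bias detected

    def test_flat_fluence_is_unbiased(self, ext_table, wavelengths15):
        E = ext_table.design_matrix(wavelengths15)
        s = E @ np.array([0.5, 0.5])
        c = unmix_spectrum(s * 1.7, ext_table, wavelengths15)
        so2 = c[0] / (c[0] + c[1])
        assert so2 == pytest.approx(0.5, abs=1e-12)


class TestSeriesIO:
    def test_tiff_round_trip(self, ext_table, wavelengths15, tmp_path):
        series = uniform_series(ext_table, wavelengths15, so2=0.4, shape=(5, 6))
        path = tmp_path / "series.tif"
        series.to_tiff(path)
        back = MultispectralSeries.from_tiff(path)
        np.testing.assert_allclose(back.data, series.data, rtol=1e-6)
        np.testing.assert_allclose(back.wavelengths, series.wavelengths)
        assert back.pixel_spacing == series.pixel_spacing

    def test_nifti_round_trip(self, ext_table, wavelengths15, tmp_path):
        series = uniform_series(ext_table, wavelengths15, so2=0.4, shape=(5, 6))
        path = tmp_path / "series.nii"
        series.to_nifti(path)
        back = MultispectralSeries.from_nifti(path)
        np.testing.assert_allclose(back.data, series.data, rtol=1e-6)
        assert back.pixel_spacing == pytest.approx(series.pixel_spacing)
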