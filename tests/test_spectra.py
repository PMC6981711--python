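"""Spectrum container, resampling, derivatives, blank subtraction, peaks, I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from specbind.exceptions import DataError, RangeError
from specbind.spectra import (
    EEM,
    Spectrum,
    SpectrumKind,
    TitrationSeries,
    find_peaks,
    read_eem,
    read_spectrum,
    read_titration,
    resample,
    savgol_second_derivative,
    subtract_blank,
    uniform_grid,
    write_eem,
    write_spectrum,
    write_titration,
)
from conftest import gaussian_spectrum


class TestContainers:
    def test_wavelengths_must_increase(self):
        with pytest.raises(DataError):
            Spectrum([300, 300, 310], [1, 2, 3], SpectrumKind.ABSORBANCE)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            Spectrum([300, 310], [1, 2, 3], SpectrumKind.ABSORBANCE)

    def test_eem_shape_must_match_axes(self):
        with pytest.raises(DataError):
            EEM([250, 260], [300, 310, 320], np.zeros((3, 2)))

    def test_titration_first_concentration_zero(self):
        with pytest.raises(DataError):
            TitrationSeries([1e-6, 2e-6], [100, 90], temperature=298.0)

    def test_titration_positive_intensities(self):
        with pytest.raises(DataError):
            TitrationSeries([0, 1e-6], [100, 0.0], temperature=298.0)


class TestResample:
    def test_constant_spectrum_stays_constant(self):
        s = Spectrum([200, 250, 300], [7.0, 7.0, 7.0], SpectrumKind.ABSORBANCE)
        out = resample(s, np.linspace(200, 300, 37))
        assert np.allclose(out.values, 7.0)

    def test_midpoint_of_linear_segment(self):
        s = Spectrum([200, 300], [0.0, 10.0], SpectrumKind.ABSORBANCE)
        assert resample(s, [250.0]).values[0] == pytest.approx(5.0)

    def test_gaussian_refinement_matches_analytic(self):
        # 1 nm sampling refined to 0.5 nm must track the analytic band
        coarse = gaussian_spectrum(center=340, sigma=12, step=1.0)
        fine_grid = np.arange(280.0, 420.0 + 0.25, 0.5)
        out = resample(coarse, fine_grid)
        analytic = np.exp(-((fine_grid - 340) ** 2) / (2 * 12.0**2))
        assert np.max(np.abs(out.values - analytic)) < 1e-3

    def test_out_of_range_grid_rejected(self):
        s = gaussian_spectrum()
        with pytest.raises(RangeError):
            resample(s, [250.0, 300.0])

    @given(st.integers(min_value=3, max_value=40))
    def test_idempotent_on_own_grid(self, n):
        wl = np.linspace(300, 400, n)
        s = Spectrum(wl, np.sin(wl / 10.0), SpectrumKind.FLUORESCENCE)
        out = resample(s, wl)
        assert np.array_equal(out.values, s.values)

    def test_kind_and_meta_preserved(self):
        s = Spectrum([200, 300], [0, 1], SpectrumKind.CD, {"label": "x"})
        out = resample(s, [210, 290])
        assert out.kind is SpectrumKind.CD and out.meta["label"] == "x"


class TestSecondDerivative:
    def test_linear_trace_gives_zero(self):
        wl = np.arange(200.0, 300.0, 0.5)
        s = Spectrum(wl, 0.3 + 0.01 * wl, SpectrumKind.ABSORBANCE)
        d2 = savgol_second_derivative(s)
        assert np.max(np.abs(d2.values)) < 1e-10

    def test_quadratic_gives_constant_curvature(self):
        a = 0.002
        wl = np.arange(200.0, 300.0, 0.5)
        s = Spectrum(wl, a * wl**2, SpectrumKind.ABSORBANCE)
        d2 = savgol_second_derivative(s)
        interior = d2.values[25:-25]
        assert np.allclose(interior, 2 * a, rtol=1e-6)

    def test_requires_uniform_grid(self):
        s = Spectrum([200, 201, 203, 210, 230], np.ones(5), SpectrumKind.ABSORBANCE)
        with pytest.raises(DataError):
            savgol_second_derivative(s, window_points=5, poly_order=2)

    def test_even_window_rejected(self):
        s = uniform_grid(gaussian_spectrum())
        with pytest.raises(DataError):
            savgol_second_derivative(s, window_points=20)

    def test_linearity(self):
        wl = np.arange(200.0, 300.0, 0.5)
        s1 = Spectrum(wl, np.exp(-((wl - 240) ** 2) / 50), SpectrumKind.ABSORBANCE)
        s2 = Spectrum(wl, np.exp(-((wl - 270) ** 2) / 90), SpectrumKind.ABSORBANCE)
        combo = Spectrum(wl, 2.0 * s1.values + 3.0 * s2.values, SpectrumKind.ABSORBANCE)
        lhs = savgol_second_derivative(combo).values
        rhs = 2.0 * savgol_second_derivative(s1).values + 3.0 * savgol_second_derivative(s2).values
        assert np.max(np.abs(lhs - rhs)) < 1e-9


class TestSubtractBlank:
    def test_self_subtraction_is_zero(self):
        s = gaussian_spectrum(kind=SpectrumKind.ABSORBANCE)
        assert np.allclose(subtract_blank(s, s).values, 0.0)

    def test_zero_blank_is_identity(self):
        s = gaussian_spectrum(kind=SpectrumKind.ABSORBANCE)
        zero = s.with_values(np.zeros(len(s)))
        out = subtract_blank(s, zero)
        assert np.array_equal(out.values, s.values)

    def test_kind_mismatch_raises(self):
        a = gaussian_spectrum(kind=SpectrumKind.ABSORBANCE)
        f = gaussian_spectrum(kind=SpectrumKind.FLUORESCENCE)
        with pytest.raises(TypeError):
            subtract_blank(a, f)

    def test_disjoint_ranges_raise(self):
        a = gaussian_spectrum(lo=200, hi=250, center=225, kind=SpectrumKind.ABSORBANCE)
        b = gaussian_spectrum(lo=300, hi=350, center=325, kind=SpectrumKind.ABSORBANCE)
        with pytest.raises(RangeError):
            subtract_blank(a, b)


class TestFindPeaks:
    def test_single_gaussian_found_at_center(self):
        peaks = find_peaks(gaussian_spectrum(center=340))
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(340.0, abs=1.0)

    def test_monotone_spectrum_has_no_peaks(self):
        wl = np.arange(300.0, 400.0)
        s = Spectrum(wl, wl * 0.01, SpectrumKind.FLUORESCENCE)
        assert find_peaks(s) == []

    def test_minima_mode_finds_negative_bands(self):
        wl = np.arange(200.0, 260.0)
        s = Spectrum(wl, -np.exp(-((wl - 222) ** 2) / 40), SpectrumKind.CD)
        peaks = find_peaks(s, invert=True)
        assert [round(w) for w, _ in peaks] == [222]

    def test_results_sorted_by_wavelength(self):
        wl = np.arange(200.0, 320.0, 0.5)
        y = np.exp(-((wl - 222) ** 2) / 60) + 0.6 * np.exp(-((wl - 278) ** 2) / 200)
        peaks = find_peaks(Spectrum(wl, y, SpectrumKind.ABSORBANCE))
        assert [w for w, _ in peaks] == sorted(w for w, _ in peaks)
        assert [round(w) for w, _ in peaks] == [222, 278]


class TestIO:
    def test_spectrum_round_trip(self, tmp_path):
        s = gaussian_spectrum(kind=SpectrumKind.CD)
        s.meta.update({"temperature_K": 310.0, "label": "bsa"})
        path = tmp_path / "cd.tsv"
        write_spectrum(s, path)
        back = read_spectrum(path)
        assert back.kind is SpectrumKind.CD
        assert np.allclose(back.wavelengths, s.wavelengths)
        assert np.allclose(back.values, s.values, atol=1e-4 * np.max(np.abs(s.values)))
        assert back.meta["temperature_K"] == 310.0

    def test_eem_round_trip(self, tmp_path):
        ex, em = np.arange(250.0, 300.0, 5.0), np.arange(300.0, 400.0, 10.0)
        z = np.random.default_rng(0).random((ex.size, em.size))
        path = tmp_path / "eem.tsv"
        write_eem(EEM(ex, em, z), path)
        back = read_eem(path)
        assert np.allclose(back.excitation, ex)
        assert np.allclose(back.intensities, z, atol=1e-5)

    def test_titration_round_trip(self, tmp_path):
        conc = np.array([0, 1, 5, 10]) * 1e-6
        series = TitrationSeries(conc, [1000.0, 940.0, 760.0, 600.0], temperature=300.0)
        path = tmp_path / "titration.tsv"
        write_titration(series, path)
        back = read_titration(path)
        assert back.temperature == 300.0
        assert np.allclose(back.concentrations, conc)
        assert np.allclose(back.intensities, series.intensities)
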