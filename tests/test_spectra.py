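"""Spectral container, window aggregation and the 14 spectral indices."""

import math

import numpy as np
import pytest

from anthoquant import Spectrum, band_aggregate, point_reflectance, resample_spectrum
from anthoquant.spectra import (
    compute_spectral_indices,
    read_spectra_wide_csv,
    read_spectrum_text,
    spectral_anthocyanin_indices,
    spectral_basic_indices,
    spectral_segment_indices,
    spectral_strength_indices,
)


class TestSpectrumInvariants:
    def test_rejects_nonincreasing_grid(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([500.0, 500.0, 501.0]), np.ones(3))

    def test_rejects_length_mismatch_and_short(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([500.0, 501.0]), np.ones(3))
        with pytest.raises(ValueError, match="at least 2"):
            Spectrum(np.array([500.0]), np.ones(1))

    def test_negative_reflectance_rejected_unless_clamped(self):
        wl = np.array([500.0, 501.0])
        with pytest.raises(ValueError, match="negative"):
            Spectrum(wl, np.array([0.5, -0.1]))
        s = Spectrum(wl, np.array([0.5, -0.1]), clamp_negative=True)
        assert s.reflectance[1] == 0.0


class TestResample:
    def test_midpoint_interpolation(self):
        s = resample_spectrum([(540, 0.1), (541, 0.2)], 540, 541, 0.5)
        np.testing.assert_allclose(s.reflectance, [0.1, 0.15, 0.2])

    def test_identity_on_matching_grid(self):
        pairs = [(500.0, 1.0), (501.0, 2.0), (502.0, 3.0)]
        s = resample_spectrum(pairs, 500, 502, 1.0)
        np.testing.assert_allclose(s.reflectance, [1.0, 2.0, 3.0])

    def test_hand_linear_interpolation(self):
        s = resample_spectrum([(500, 1.0), (600, 3.0)], 500, 600, 25)
        np.testing.assert_allclose(s.reflectance, [1.0, 1.5, 2.0, 2.5, 3.0])

    def test_duplicate_wavelengths_averaged(self):
        s = resample_spectrum([(500, 1.0), (500, 3.0), (600, 2.0)], 500, 600, 100)
        np.testing.assert_allclose(s.reflectance, [2.0, 2.0])

    def test_grid_outside_span_is_range_error(self):
        with pytest.raises(ValueError, match="span"):
            resample_spectrum([(500, 1.0), (600, 3.0)], 450, 600, 50)

    def test_fewer_than_two_distinct_wavelengths(self):
        with pytest.raises(ValueError, match="distinct"):
            resample_spectrum([(500, 1.0), (500, 2.0)], 500, 500, 1)


class TestBandAggregate:
    def test_flat_mean_and_sum(self, flat_spectrum):
        s = flat_spectrum(1.0)
        assert band_aggregate(s, 600, 699, mode="mean") == pytest.approx(1.0)
        # 100 inclusive grid points in 600–699 on a 1-nm grid
        assert band_aggregate(s, 600, 699, mode="sum") == pytest.approx(100.0)

    def test_linear_ramp_mean(self):
        wl = np.arange(300.0, 801.0)
        s = Spectrum(wl, wl / 1000.0)
        assert band_aggregate(s, 500, 502, mode="mean") == pytest.approx(0.501)

    def test_sum_equals_count_times_mean_exactly(self, rng):
        wl = np.arange(300.0, 801.0)
        s = Spectrum(wl, rng.uniform(0, 100, wl.size))
        total = band_aggregate(s, 459, 479, mode="sum")
        mean = band_aggregate(s, 459, 479, mode="mean")
        assert total == 21 * mean

    def test_empty_window_names_the_window(self, flat_spectrum):
        with pytest.raises(ValueError, match=r"\[400.5, 400.7\]"):
            band_aggregate(flat_spectrum(), 400.5, 400.7)

    def test_coarse_grid_warns(self):
        s = Spectrum(np.arange(300.0, 801.0, 5.0), np.ones(101))
        with pytest.warns(UserWarning, match="coarser"):
            band_aggregate(s, 400, 500)


class TestPointReflectance:
    def test_exact_grid_value(self, flat_spectrum):
        s = flat_spectrum(0.1)
        assert point_reflectance(s, 550) == 0.1

    @pytest.mark.parametrize(
        "pairs,target,expected",
        [
            ([(540, 0.1), (541, 0.2)], 540.5, 0.15),
            ([(449, 0.40), (451, 0.50)], 450, 0.45),
        ],
    )
    def test_interpolation(self, pairs, target, expected):
        arr = np.asarray(pairs, dtype=float)
        s = Spectrum(arr[:, 0], arr[:, 1])
        assert point_reflectance(s, target) == pytest.approx(expected)

    def test_outside_span_is_range_error(self, flat_spectrum):
        with pytest.raises(ValueError, match="span"):
            point_reflectance(flat_spectrum(), 250)


class TestBasicIndices:
    def test_unique_peak_gives_hue(self, piecewise_spectrum):
        s = piecewise_spectrum([((640, 640), 5.0)], fill=1.0)
        assert spectral_basic_indices(s)["H"] == 640

    def test_hue_tie_breaks_to_lowest_wavelength(self, piecewise_spectrum):
        s = piecewise_spectrum([((500, 500), 5.0), ((620, 620), 5.0)], fill=1.0)
        assert spectral_basic_indices(s)["H"] == 500

    def test_flat_spectrum_degenerate(self, flat_spectrum):
        out = spectral_basic_indices(flat_spectrum(3.0))
        assert out["C"] == 0.0
        assert out["H"] == 300.0
        assert out.flags["C"] == "degenerate-constant"

    def test_chroma_arithmetic(self, piecewise_spectrum):
        # half the 300–699 range at 0.6, half at 0.2: mean 0.4, C = 0.4/0.4
        s = piecewise_spectrum([((300, 499), 0.6), ((500, 699), 0.2)])
        assert spectral_basic_indices(s)["C"] == pytest.approx(1.0)

    def test_brightness_is_band_average_by_default(self, flat_spectrum):
        assert spectral_basic_indices(flat_spectrum(2.5))["B"] == pytest.approx(2.5)


class TestSegmentIndices:
    def test_flat_spectrum_undefined_hue(self, flat_spectrum):
        out = spectral_segment_indices(flat_spectrum())
        assert out["C_SC"] == 0.0
        assert not out.defined("H_SC")

    def test_sign_degenerate_convention(self, piecewise_spectrum):
        # segment means (1, 1, 1, 2): green-violet contrast is 0
        s = piecewise_spectrum([((600, 699), 2.0)], fill=1.0)
        out = spectral_segment_indices(s)
        assert out["C_SC"] == pytest.approx(1.0)
        assert out["H_SC"] == 0.0
        assert out.flags["H_SC"] == "sign-degenerate"

    def test_hand_trigonometry(self, piecewise_spectrum):
        # segment means (1, 2, 3, 4): C_SC = sqrt(8), H_SC = arcsin(2/sqrt(8))
        s = piecewise_spectrum(
            [((300, 399), 1.0), ((400, 499), 2.0), ((500, 599), 3.0), ((600, 699), 4.0)]
        )
        out = spectral_segment_indices(s)
        assert out["C_SC"] == pytest.approx(2.8284271247)
        assert out["H_SC"] == pytest.approx(math.pi / 4)

    def test_negative_sign_maps_into_two_pi_range(self, piecewise_spectrum):
        # green segment below violet: H_SC negative before the 2π wrap
        s = piecewise_spectrum(
            [((300, 399), 3.0), ((400, 499), 2.0), ((500, 599), 1.0), ((600, 699), 4.0)]
        )
        out = spectral_segment_indices(s)
        assert 0.0 <= out["H_SC"] < 2 * math.pi
        assert out["H_SC"] == pytest.approx(2 * math.pi - math.pi / 4)


class TestAnthocyaninIndices:
    def test_hand_arithmetic(self):
        wl = np.arange(300.0, 801.0)
        control_wl = np.array([300.0, 450.0, 550.0, 650.0, 800.0])
        control_r = np.array([0.4, 0.4, 0.1, 0.5, 0.5])
        s = Spectrum(wl, np.interp(wl, control_wl, control_r))
        out = spectral_anthocyanin_indices(s)
        assert out["AC_CD"] == pytest.approx(0.35)
        assert out["AC_CR"] == pytest.approx(0.1 / 0.45)
        assert out["AC_CB"] == pytest.approx(9.0)

    def test_flat_spectrum_ratios_are_one(self, flat_spectrum):
        out = spectral_anthocyanin_indices(flat_spectrum(0.7))
        for name in ("R:G_R", "R:G_I", "mACI"):
            assert out[name] == pytest.approx(1.0)

    def test_accr_times_accb_identity(self, rng):
        wl = np.arange(300.0, 801.0)
        for _ in range(20):
            s = Spectrum(wl, rng.uniform(0.01, 100.0, wl.size))
            out = spectral_anthocyanin_indices(s)
            assert out["AC_CR"] * out["AC_CB"] == pytest.approx(2.0, abs=1e-9)

    def test_zero_denominator_flagged_not_raised(self, piecewise_spectrum):
        s = piecewise_spectrum([((540, 560), 0.0)], fill=1.0)
        out = spectral_anthocyanin_indices(s)
        assert not out.defined("AC_CB")
        assert not out.defined("R:G_I")
        assert out.flags["AC_CB"].startswith("undefined")


class TestStrengthIndices:
    def test_flat_spectrum_symmetry(self, flat_spectrum):
        out = spectral_strength_indices(flat_spectrum())
        for name in ("S_green", "S_red", "S_blue"):
            assert out[name] == pytest.approx(1.0 / 3.0)

    def test_hand_arithmetic(self, piecewise_spectrum):
        # window means: green 1, red 2, blue 1
        s = piecewise_spectrum([((620, 670), 2.0)], fill=1.0)
        out = spectral_strength_indices(s)
        assert out["S_green"] == pytest.approx(0.25)
        assert out["S_red"] == pytest.approx(0.5)
        assert out["S_blue"] == pytest.approx(0.25)

    def test_zero_denominator_flags_all_three(self, flat_spectrum):
        out = spectral_strength_indices(flat_spectrum(0.0))
        assert not any(out.defined(n) for n in ("S_green", "S_red", "S_blue"))


class TestFullSweep:
    def test_identities_on_random_spectra(self, rng):
        wl = np.arange(300.0, 801.0)
        for _ in range(1000):
            s = Spectrum(wl, rng.uniform(0.01, 100.0, wl.size))
            out = compute_spectral_indices(s)
            assert abs(out["S_green"] + out["S_red"] + out["S_blue"] - 1.0) < 1e-9
            assert abs(out["AC_CR"] * out["AC_CB"] - 2.0) < 1e-9

    def test_scaling_equivariance(self, rng):
        wl = np.arange(300.0, 801.0)
        s = Spectrum(wl, rng.uniform(0.01, 100.0, wl.size))
        k = 3.7
        a, b = compute_spectral_indices(s), compute_spectral_indices(s.scaled(k))
        invariant = ("C", "H", "H_SC", "AC_CR", "AC_CB", "R:G_R", "R:G_I", "mACI",
                     "S_green", "S_red", "S_blue")
        for name in invariant:
            assert b[name] == pytest.approx(a[name], rel=1e-12), name
        for name in ("B", "AC_CD"):
            assert b[name] == pytest.approx(k * a[name], rel=1e-12), name

    def test_short_span_flags_instead_of_raising(self):
        wl = np.arange(300.0, 721.0)
        s = Spectrum(wl, np.full(wl.size, 50.0))
        out = compute_spectral_indices(s)
        assert len(out) == 14
        assert not out.defined("mACI")  # needs coverage to 800 nm
        assert out.defined("S_green")


class TestSpectrumIO:
    def test_two_column_text_with_comments(self, tmp_path):
        p = tmp_path / "petal.txt"
        p.write_text("# wavelength reflectance\n500 10.5\n501, 11.0\n499 10.0\n")
        s = read_spectrum_text(p)
        np.testing.assert_allclose(s.wavelengths_nm, [499, 500, 501])
        np.testing.assert_allclose(s.reflectance, [10.0, 10.5, 11.0])
        assert s.meta == "petal"

    def test_wide_csv_one_column_per_sample(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text("wavelength,s1,s2\n500,1.0,2.0\n501,1.5,2.5\n")
        spectra = read_spectra_wide_csv(p)
        assert set(spectra) == {"s1", "s2"}
        np.testing.assert_allclose(spectra["s2"].reflectance, [2.0, 2.5])
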