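"""Second-derivative UV-vis and center-of-spectral-mass analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desfold.exceptions import (
    FeatureNotFoundError,
    InvalidInputError,
    NonUniformGridError,
    UndefinedResultError,
)
from desfold.spectrum import Spectrum
from desfold.synthetic import gen_emission
from desfold.uvvis import (
    center_of_spectral_mass,
    second_derivative,
    tyr_trp_parameters,
)

WL = np.arange(250.0, 320.0, 0.5)


def _two_gauss(wl, a1=0.5, c1=287.0, s1=3.0, a2=0.45, c2=295.0, s2=3.0):
    return (a1 * np.exp(-0.5 * ((wl - c1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((wl - c2) / s2) ** 2))


class TestSecondDerivative:
    def test_quadratic_gives_constant_curvature(self):
        s = Spectrum(WL, 0.1 + 0.002 * WL + 0.003 * WL**2)
        d2 = second_derivative(s)
        edge = d2.metadata["edge_points"]
        assert d2.values[edge:-edge] == pytest.approx(2 * 0.003, rel=1e-8)

    def test_gaussian_band_minimum_at_center(self):
        s = Spectrum(WL, np.exp(-0.5 * ((WL - 287.0) / 3.0) ** 2))
        d2 = second_derivative(s)
        interior = slice(d2.metadata["edge_points"], -d2.metadata["edge_points"])
        lam = d2.wavelengths[interior][np.argmin(d2.values[interior])]
        assert lam == pytest.approx(287.0, abs=0.25)  # half the grid step

    def test_matches_dense_central_difference_oracle(self):
        """SG derivative of a two-band spectrum vs 0.01 nm finite differences."""
        s = Spectrum(WL, _two_gauss(WL))
        d2 = second_derivative(s, window_points=9, poly_order=5)  # quintic: minimal attenuation
        fine = np.arange(250.0, 320.0, 0.01)
        y = _two_gauss(fine)
        oracle_fine = (y[2:] - 2 * y[1:-1] + y[:-2]) / 0.01**2
        edge = d2.metadata["edge_points"]
        interior_wl = d2.wavelengths[edge:-edge]
        oracle = np.interp(interior_wl, fine[1:-1], oracle_fine)
        rms = np.sqrt(np.mean((d2.values[edge:-edge] - oracle) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(oracle**2))

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(-5, 5), b=st.floats(-0.1, 0.1))
    def test_annihilates_affine_signals(self, a, b):
        s = Spectrum(WL, a + b * WL)
        d2 = second_derivative(s)
        scale = max(np.max(np.abs(s.values)), 1.0)
        assert np.max(np.abs(d2.values)) < 1e-10 * scale

    def test_rejects_non_uniform_grid(self):
        wl = np.concatenate([WL[:50], WL[50:] + 0.05])
        with pytest.raises(NonUniformGridError):
            second_derivative(Spectrum(wl, np.ones_like(wl)))

    def test_rejects_oversized_window(self):
        s = Spectrum(WL[:11], np.ones(11))
        with pytest.raises(InvalidInputError):
            second_derivative(s, window_points=13)


class TestTyrTrpParameters:
    def test_equal_bands_give_unit_ratio_and_tyr_position(self):
        # narrow bands do not overlap, so the construction is exactly symmetric
        s = Spectrum(WL, _two_gauss(WL, a1=0.5, s1=1.5, a2=0.5, s2=1.5))
        p = tyr_trp_parameters(second_derivative(s))
        assert p.ratio == pytest.approx(1.0, rel=1e-6)
        assert p.lambda_tyr == pytest.approx(287.0, abs=0.05)

    def test_amplitude_linearity_doubles_ratio(self):
        base = tyr_trp_parameters(second_derivative(
            Spectrum(WL, _two_gauss(WL, a1=0.5, s1=1.5, a2=0.5, s2=1.5))))
        doubled = tyr_trp_parameters(second_derivative(
            Spectrum(WL, _two_gauss(WL, a1=1.0, s1=1.5, a2=0.5, s2=1.5))))
        # exact up to parabolic-refinement error on the 0.5 nm grid
        assert doubled.amp_tyr == pytest.approx(2 * base.amp_tyr, rel=1e-3)
        assert doubled.ratio == pytest.approx(2.0, rel=1e-3)

    def test_overlapping_bands_match_dense_grid_oracle(self):
        """1.5:1 bands, sigma 3 nm, 8 nm apart, vs brute-force extremum search."""
        s = Spectrum(WL, _two_gauss(WL, a1=0.6, a2=0.4))
        p = tyr_trp_parameters(second_derivative(s, window_points=5))

        fine = np.arange(255.0, 315.0, 0.01)
        y = _two_gauss(fine, a1=0.6, a2=0.4)
        d2 = (y[2:] - 2 * y[1:-1] + y[:-2]) / 0.01**2
        wl_f = fine[1:-1]

        maxima = np.where((d2[1:-1] > d2[:-2]) & (d2[1:-1] > d2[2:]))[0] + 1

        def window_amp(lo, hi, side):
            win = (wl_f >= lo) & (wl_f <= hi)
            i_min = np.where(win)[0][np.argmin(d2[win])]
            on_side = maxima[maxima < i_min] if side == "blue" else maxima[maxima > i_min]
            nearest = on_side[np.argmin(np.abs(on_side - i_min))]
            return wl_f[i_min], d2[nearest] - d2[i_min]

        lam_oracle, amp_tyr_oracle = window_amp(283, 291, "blue")
        _, amp_trp_oracle = window_amp(291, 299, "red")
        assert p.lambda_tyr == pytest.approx(lam_oracle, abs=0.05)
        assert p.ratio == pytest.approx(amp_tyr_oracle / amp_trp_oracle, rel=0.02)

    def test_ratio_invariant_to_global_scaling(self):
        s1 = Spectrum(WL, _two_gauss(WL))
        s2 = Spectrum(WL, 7.3 * _two_gauss(WL))
        p1 = tyr_trp_parameters(second_derivative(s1))
        p2 = tyr_trp_parameters(second_derivative(s2))
        assert p1.ratio == pytest.approx(p2.ratio, rel=1e-9)

    def test_missing_feature_names_window(self):
        featureless_d2 = Spectrum(WL, np.linspace(0.0, 1.0, WL.size))  # no minima anywhere
        with pytest.raises(FeatureNotFoundError, match="Tyr"):
            tyr_trp_parameters(featureless_d2)

    def test_extremum_mode_uses_absolute_minimum(self):
        s = Spectrum(WL, _two_gauss(WL, a1=0.5, s1=1.5, a2=0.5, s2=1.5))
        p = tyr_trp_parameters(second_derivative(s), mode="extremum")
        assert p.ratio == pytest.approx(1.0, rel=1e-6)
        assert p.mode == "extremum"


class TestCenterOfSpectralMass:
    def test_symmetric_triangle_centered(self):
        wl = np.arange(305.0, 380.5, 0.5)
        vals = np.maximum(0.0, 1.0 - np.abs(wl - 340.0) / 20.0)
        csm = center_of_spectral_mass(Spectrum(wl, vals, kind="emission"))
        assert csm.csm == pytest.approx(340.0, abs=1e-9)

    def test_uniform_intensity_gives_window_midpoint(self):
        wl = np.arange(305.0, 380.5, 0.5)
        csm = center_of_spectral_mass(Spectrum(wl, np.ones_like(wl), kind="emission"))
        assert csm.csm == pytest.approx(342.5, abs=1e-9)

    def test_lognormal_peak_matches_direct_summation(self):
        s, _ = gen_emission(mode_nm=338.0, asymmetry=0.3)
        csm = center_of_spectral_mass(s)
        mask = (s.wavelengths >= 305.0) & (s.wavelengths <= 380.0)
        oracle = np.sum(s.wavelengths[mask] * s.values[mask]) / np.sum(s.values[mask])
        assert csm.csm == pytest.approx(oracle, abs=1e-9)

    def test_translation_equivariance(self):
        s, _ = gen_emission(mode_nm=330.0, asymmetry=0.2, grid=(300.0, 390.0, 0.5))
        delta = 4.5
        shifted = Spectrum(s.wavelengths + delta, s.values, kind="emission")
        c0 = center_of_spectral_mass(s, (305.0, 380.0)).csm
        c1 = center_of_spectral_mass(shifted, (305.0 + delta, 380.0 + delta)).csm
        assert c1 - c0 == pytest.approx(delta, abs=1e-9)

    def test_zero_intensity_rejected(self):
        wl = np.arange(305.0, 380.5, 0.5)
        with pytest.raises(UndefinedResultError):
            center_of_spectral_mass(Spectrum(wl, np.zeros_like(wl), kind="emission"))

    def test_wrong_kind_rejected(self):
        wl = np.arange(305.0, 380.5, 0.5)
        with pytest.raises(InvalidInputError):
            center_of_spectral_mass(Spectrum(wl, np.ones_like(wl), kind="absorbance"))
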