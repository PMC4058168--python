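"""Spectral homogeneity features: mean spectrum, FT2 area, std envelope, ramp."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cartwave.spectral_features import (
    envelope,
    ft2_feature,
    legacy_spectral_areas,
    mean_spectrum,
    ramp_feature,
    std_curve,
)
from cartwave.wave_maps import SpatiospectralMap


def _ss(values):
    values = np.asarray(values, dtype=float)
    F = values.shape[0]
    return SpatiospectralMap(values=values, freq_axis=np.arange(1, F + 1) / F)


class TestMeanSpectrum:
    def test_identical_columns_average_to_themselves(self):
        col = np.array([1.0, 3.0, 0.5, 2.0])
        ms, _ = mean_spectrum(_ss(np.tile(col[:, None], (1, 5))))
        np.testing.assert_allclose(ms, col)

    def test_two_column_arithmetic(self):
        ms, area = mean_spectrum(_ss(np.array([[0.0, 2.0], [2.0, 0.0]])))
        np.testing.assert_allclose(ms, [1.0, 1.0])
        assert area == pytest.approx(1.0)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            mean_spectrum(_ss(np.zeros((0, 0))))

    def test_young_phantom_has_larger_area_than_elderly(self, case_runner):
        young = case_runner("young", 1).mean_spectrum_area
        elderly = case_runner("elderly", 1).mean_spectrum_area
        assert young > elderly


class TestFT2:
    def test_zero_spectrum_zero_area(self):
        _, area = ft2_feature(np.zeros(16))
        assert area == 0.0

    def test_cosine_closed_form(self):
        F = 64
        j = np.arange(F)
        ms = np.cos(2 * np.pi * 3 * j / F)
        curve, area = ft2_feature(ms)
        expect = np.zeros(F // 2)
        expect[2] = 0.5  # bin 3 of |DFT|/F
        np.testing.assert_allclose(curve, expect, atol=1e-9)
        assert area == pytest.approx(100.0 * (2.0 / F) * 0.5, abs=1e-9)

    def test_linearity_after_mean_removal(self):
        rng = np.random.default_rng(0)
        ms = rng.uniform(0, 2, 40)
        _, a1 = ft2_feature(ms)
        _, a2 = ft2_feature(2 * ms)
        assert a2 == pytest.approx(2 * a1)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError):
            ft2_feature(np.ones(3))


class TestStdCurve:
    def test_identical_columns_zero_everywhere(self):
        np.testing.assert_allclose(
            std_curve(_ss(np.tile(np.arange(6.0)[:, None], (1, 4)))), 0.0
        )

    def test_population_std_rows(self):
        sc = std_curve(_ss(np.array([[0.0, 1.0], [1.0, 2.0]])))
        np.testing.assert_allclose(sc, [0.5, 0.5])
        sc = std_curve(_ss(np.array([[1.0, 2.0, 3.0]])))
        assert sc[0] == pytest.approx(np.sqrt(2 / 3))

    def test_single_roi_rejected(self):
        with pytest.raises(ValueError):
            std_curve(_ss(np.ones((8, 1))))

    def test_zero_iff_columns_identical(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(size=(12, 5))
        assert np.all(std_curve(_ss(v)) > 0) or np.any(
            np.ptp(v, axis=1) == 0
        )


class TestEnvelope:
    def test_alternating_curve_hand_traced(self):
        env = envelope(np.array([0.0, 1.0, 0.0, 1.0, 0.0]))
        np.testing.assert_allclose(env, [0.0, 1.0, 1.0, 1.0, 0.0])

    def test_all_zero_curve_stays_zero(self):
        np.testing.assert_allclose(envelope(np.zeros(7)), 0.0)

    def test_monotone_decreasing_dominated_with_endpoint_equality(self):
        curve = np.array([8.0, 4.0, 2.0, 1.0, 0.5])
        env = envelope(curve)
        norm = curve / 8.0
        assert np.all(env >= norm - 1e-12)
        assert env[0] == pytest.approx(1.0)
        assert env[-1] == pytest.approx(norm[-1])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=3, max_size=60)
    )
    def test_dominance_with_equality_at_strict_maxima(self, vals):
        curve = np.asarray(vals)
        env = envelope(curve)
        m = curve.max()
        norm = curve / m if m > 0 else curve
        assert np.all(env >= norm - 1e-12)
        interior = (curve[1:-1] > curve[:-2]) & (curve[1:-1] > curve[2:])
        np.testing.assert_allclose(env[1:-1][interior], norm[1:-1][interior])


class TestRampFeature:
    def test_zero_envelope_hits_log_floor(self):
        f = ramp_feature(np.zeros(10), np.arange(1, 11) / 10)
        assert f == pytest.approx(np.log(1e-6))

    def test_flat_unit_envelope_closed_form(self):
        F = 64
        freq = np.arange(1, F + 1) / F
        f = ramp_feature(np.ones(F), freq)
        assert f == pytest.approx(np.log(65 / 128 + 1e-6), abs=1e-9)

    def test_heterogeneous_phantom_scores_higher(self, case_runner):
        hom = case_runner("young", 1).ramp_feature
        het = case_runner("young", 1, 1.0).ramp_feature
        assert het > hom

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ramp_feature(np.ones(5), np.ones(4))


class TestLegacyAreas:
    def test_flat_spectrum_both_unity(self):
        F = 100
        freq = np.arange(1, F + 1) / F
        full, low = legacy_spectral_areas(np.ones(F), freq)
        assert full == pytest.approx(1.0) and low == pytest.approx(1.0)

    def test_high_band_only_spectrum_has_zero_low_area(self):
        F = 100
        freq = np.arange(1, F + 1) / F
        ms = np.where(freq > 0.15, 1.0, 0.0)
        _, low = legacy_spectral_areas(ms, freq)
        assert low == 0.0

    def test_linear_spectrum_direct_sums(self):
        F = 100
        freq = np.arange(1, F + 1) / F
        full, low = legacy_spectral_areas(freq.copy(), freq)
        assert full == pytest.approx(0.505)
        assert low == pytest.approx(0.08)

    def test_missing_low_band_rejected(self):
        with pytest.raises(ValueError):
            legacy_spectral_areas(np.ones(3), np.array([0.5, 0.75, 1.0]))
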