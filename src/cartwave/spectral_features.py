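"""Homogeneity features of the spatiospectral map.

Two summary features quantify how uniform the spectral content of the wall
motion is along the vessel:

* the **FT-squared area**: the ROI-averaged magnitude spectrum is itself
  Fourier-transformed, and the normalized area under the resulting magnitude
  curve (scaled by a fixed reporting constant of 100) summarizes the shape
  and strength of the mean spectral curve — large for strong, sharply peaked
  (periodic, homogeneous) motion;
* the **ramp-weighted std-envelope feature**: the across-ROI standard
  deviation of the spectra is max-normalized, its upper envelope is taken
  through the strict local maxima, and the area under the envelope weighted
  by a frequency ramp ``w(f) = f`` is reported on a natural-log scale —
  large when ROIs disagree spectrally, especially at high frequencies.

Two band-limited spectral areas of the mean spectrum (full band 0 < f <= 1
and low band 0 < f <= 0.15) are also provided as simpler legacy measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wave_maps import SpatiospectralMap

__all__ = [
    "CaseFeatures",
    "mean_spectrum",
    "ft2_feature",
    "std_curve",
    "envelope",
    "ramp_feature",
    "legacy_spectral_areas",
    "compute_case_features",
    "FT2_REPORTING_SCALE",
    "RAMP_EPSILON",
]

FT2_REPORTING_SCALE = 100.0
RAMP_EPSILON = 1e-6
LOW_BAND_EDGE = 0.15


@dataclass
class CaseFeatures:
    """All per-case spectral summaries used for classification."""

    mean_spectrum: np.ndarray
    mean_spectrum_area: float
    ft2_curve: np.ndarray
    ft2_area: float
    std_curve: np.ndarray
    envelope: np.ndarray
    ramp_feature: float
    legacy_area_full: float
    legacy_area_low: float
    freq_axis: np.ndarray = field(default=None, repr=False)

    def scalars(self) -> dict[str, float]:
        return {
            "mean_spectrum_area": self.mean_spectrum_area,
            "ft2_area": self.ft2_area,
            "ramp_feature": self.ramp_feature,
            "legacy_area_full": self.legacy_area_full,
            "legacy_area_low": self.legacy_area_low,
        }


def mean_spectrum(ss_map: SpatiospectralMap) -> tuple[np.ndarray, float]:
    """ROI-averaged magnitude spectrum and its normalized area (bin mean)."""
    v = ss_map.values
    if v.size == 0:
        raise ValueError("empty spatiospectral map")
    ms = v.mean(axis=1)
    return ms, float(ms.mean())


def ft2_feature(ms: np.ndarray) -> tuple[np.ndarray, float]:
    """Magnitude spectrum of the (mean-removed) mean spectral curve.

    Returns the one-sided magnitude curve normalized by the number of bins
    F, and the area ``100 * (2/F) * sum(curve)``.
    """
    ms = np.asarray(ms, dtype=float)
    F = ms.size
    if F < 4:
        raise ValueError("mean spectrum too short for an FT2 feature")
    y = ms - ms.mean()
    curve = np.abs(np.fft.rfft(y))[1 : F // 2 + 1] / F
    area = FT2_REPORTING_SCALE * (2.0 / F) * float(curve.sum())
    return curve, area


def std_curve(ss_map: SpatiospectralMap) -> np.ndarray:
    """Across-ROI population standard deviation per frequency bin."""
    v = ss_map.values
    if v.shape[1] < 2:
        raise ValueError("std curve needs at least 2 ROIs")
    return v.std(axis=1)


def envelope(curve: np.ndarray) -> np.ndarray:
    """Upper envelope of the max-normalized curve.

    Knots are both endpoints plus every strict local maximum, joined by
    linear interpolation; an elementwise maximum with the normalized curve
    enforces dominance everywhere.
    """
    curve = np.asarray(curve, dtype=float)
    n = curve.size
    if n < 3:
        raise ValueError("envelope needs at least 3 samples")
    m = curve.max()
    norm = curve / m if m > 0 else curve.astype(float).copy()
    interior = np.flatnonzero(
        (norm[1:-1] > norm[:-2]) & (norm[1:-1] > norm[2:])
    ) + 1
    knots = np.concatenate([[0], interior, [n - 1]])
    env = np.interp(np.arange(n), knots, norm[knots])
    return np.maximum(env, norm)


def ramp_feature(env: np.ndarray, freq_axis: np.ndarray) -> float:
    """Log of the ramp-weighted normalized area under the envelope."""
    env = np.asarray(env, dtype=float)
    freq_axis = np.asarray(freq_axis, dtype=float)
    if env.shape != freq_axis.shape:
        raise ValueError("envelope and freq_axis must be congruent")
    area = float((freq_axis * env).mean())
    return float(np.log(area + RAMP_EPSILON))


def legacy_spectral_areas(
    ms: np.ndarray, freq_axis: np.ndarray
) -> tuple[float, float]:
    """Band-limited normalized areas of the mean spectrum.

    Full band 0 < f <= 1 and low band 0 < f <= 0.15; each area is the mean
    of the spectrum over the band's bins.
    """
    ms = np.asarray(ms, dtype=float)
    freq_axis = np.asarray(freq_axis, dtype=float)
    low = freq_axis <= LOW_BAND_EDGE
    if not low.any():
        raise ValueError("no frequency bins at or below the low band edge")
    full = freq_axis <= 1.0
    return float(ms[full].mean()), float(ms[low].mean())


def compute_case_features(ss_map: SpatiospectralMap) -> CaseFeatures:
    """Compute every per-case feature from one spatiospectral map."""
    ms, ms_area = mean_spectrum(ss_map)
    ft2_curve, ft2_area = ft2_feature(ms)
    sc = std_curve(ss_map)
    env = envelope(sc)
    ramp = ramp_feature(env, ss_map.freq_axis)
    area_full, area_low = legacy_spectral_areas(ms, ss_map.freq_axis)
    return CaseFeatures(
        mean_spectrum=ms,
        mean_spectrum_area=ms_area,
        ft2_curve=ft2_curve,
        ft2_area=ft2_area,
        std_curve=sc,
        envelope=env,
        ramp_feature=ramp,
        legacy_area_full=area_full,
        legacy_area_low=area_low,
        freq_axis=ss_map.freq_axis,
    )
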