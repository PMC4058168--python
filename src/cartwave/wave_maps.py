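"""Spatiotemporal and spatiospectral 2D maps of wall motion.

The spatiotemporal map stacks the per-ROI radial distension signals side by
side (rows = frames, columns = ROIs).  The spatiospectral map replaces each
column by the one-sided magnitude of its discrete Fourier transform after
mean removal, on a normalized frequency axis with f = 1 at Nyquist; the DC
bin is excluded and magnitudes are divided by the number of frames so that a
unit-amplitude sinusoid contributes a bin magnitude of 0.5 regardless of
sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .phantom import ECGTrace
from .roi_tracking import RadialSignals

__all__ = [
    "SpatiotemporalMap",
    "SpatiospectralMap",
    "build_spatiotemporal",
    "build_spatiospectral",
    "render_map",
    "render_with_ecg",
]


@dataclass
class SpatiotemporalMap:
    """Radial distension (pixels) as time x ROI."""

    values: np.ndarray  # (n_frames, n_rois)
    frame_rate: float = 30.0
    ecg: ECGTrace | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class SpatiospectralMap:
    """One-sided Fourier magnitudes as frequency x ROI."""

    values: np.ndarray  # (F, n_rois), non-negative
    freq_axis: np.ndarray  # (F,), in (0, 1], 1 = Nyquist

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def build_spatiotemporal(
    signals: RadialSignals | np.ndarray,
    frame_rate: float = 30.0,
    ecg: ECGTrace | None = None,
) -> SpatiotemporalMap:
    """Assemble the time x ROI map (a pass-through of the signal matrix)."""
    values = signals.signals if isinstance(signals, RadialSignals) else signals
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("signals are empty")
    if not np.isfinite(values).all():
        raise ValueError("signals contain non-finite entries")
    return SpatiotemporalMap(values=values.copy(), frame_rate=frame_rate, ecg=ecg)


def build_spatiospectral(
    st_map: SpatiotemporalMap, hann: bool = False
) -> SpatiospectralMap:
    """Column-wise magnitude spectra of the spatiotemporal map.

    Per column the mean is removed, an optional Hann taper applied (off by
    default), and bins 1..floor(n/2) of |DFT|/n kept on the normalized axis
    ``f = bin / (n/2)``.
    """
    x = st_map.values
    n = x.shape[0]
    if n < 8:
        raise ValueError("spectral analysis needs at least 8 frames")
    y = x - x.mean(axis=0, keepdims=True)
    if hann:
        y = y * np.hanning(n)[:, None]
    mags = np.abs(np.fft.rfft(y, axis=0))[1 : n // 2 + 1] / n
    freq = np.arange(1, n // 2 + 1) / (n // 2)
    return SpatiospectralMap(values=mags, freq_axis=freq)


def _normalized(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-300:
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def render_map(
    map_obj: SpatiotemporalMap | SpatiospectralMap | np.ndarray,
    out_path,
    palette: str = "viridis",
    grayscale: bool = False,
) -> None:
    """Write the map as a min-max-normalized pseudocolor (or grayscale) PNG."""
    values = getattr(map_obj, "values", map_obj)
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("map contains non-finite entries")
    norm = _normalized(values)
    if grayscale:
        img = np.round(norm * 255).astype(np.uint8)
    else:
        cmap = plt.get_cmap(palette)
        img = np.round(cmap(norm)[..., :3] * 255).astype(np.uint8)
    iio.imwrite(str(out_path), img)


def render_with_ecg(
    st_map: SpatiotemporalMap,
    out_path,
    palette: str = "viridis",
    ylabel: str = "frame",
) -> None:
    """Figure with the pseudocolor map and, when present, an ECG side panel."""
    has_ecg = st_map.ecg is not None
    fig, axes = plt.subplots(
        1,
        2 if has_ecg else 1,
        figsize=(8, 4),
        sharey=True,
        gridspec_kw={"width_ratios": [1, 3]} if has_ecg else None,
        squeeze=False,
    )
    col = 0
    if has_ecg:
        ax = axes[0, 0]
        ax.plot(st_map.ecg.samples, np.arange(st_map.ecg.samples.size))
        ax.invert_yaxis()
        ax.set_xlabel("ECG")
        ax.set_ylabel(ylabel)
        col = 1
    ax = axes[0, col]
    ax.imshow(st_map.values, aspect="auto", cmap=palette, origin="upper")
    ax.set_xlabel("ROI")
    if not has_ecg:
        ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(str(out_path), dpi=120)
    plt.close(fig)
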