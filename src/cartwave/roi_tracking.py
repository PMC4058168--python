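"""Inner-boundary tracking and ROI-wise radial distension signals.

The lumen-facing edge of the segmented wall is localized per frame and per
column by the half-maximum crossing of the intensity profile running from the
lumen into the wall, searched in a band around the reference mask edge.  A
series of fixed-width regions of interest (ROIs) overlapping midway (50%) is
laid along the usable columns, and each ROI yields a radial distension time
signal: the mean boundary row over the ROI's columns, oriented so that motion
toward the lumen is positive, with the temporal mean removed.

Coordinate conventions: row 0 is the top of the image, columns are the
longitudinal axis, ranges are 0-based and half-open.  A boundary value of
``b`` means the lumen-wall interface sits at geometric depth ``b`` (pixel row
``r`` covers the interval [r, r+1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exceptions import BoundaryNotFoundError
from .phantom import UltrasoundSequence

__all__ = [
    "BoundaryTrack",
    "RoiSet",
    "RadialSignals",
    "extract_inner_boundary",
    "assign_rois",
    "default_roi_width",
    "extract_radial_signals",
]

MIN_DIRECT_FRACTION = 0.9


@dataclass
class BoundaryTrack:
    """Sub-pixel boundary rows per frame over a contiguous column range."""

    rows: np.ndarray  # (n_frames, n_columns)
    valid_columns: tuple[int, int]  # absolute [start, stop)
    lumen_side: Literal["above", "below"]

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]


@dataclass
class RoiSet:
    """Midway-overlapping ROIs: ``starts`` are absolute start columns."""

    roi_width: int
    starts: np.ndarray
    n_rois: int


@dataclass
class RadialSignals:
    """Zero-mean radial distension per ROI (n_frames, n_rois), pixels."""

    signals: np.ndarray
    referenced: bool = True


def _largest_valid_window(direct_frac: np.ndarray, min_frac: float) -> tuple[int, int]:
    """Longest contiguous column window whose mean direct fraction >= min_frac."""
    n = direct_frac.size
    best = (0, 0)
    csum = np.concatenate([[0.0], np.cumsum(direct_frac)])
    lo = 0
    for hi in range(1, n + 1):
        while lo < hi and (csum[hi] - csum[lo]) / (hi - lo) < min_frac:
            lo += 1
        if hi - lo > best[1] - best[0]:
            best = (lo, hi)
    return best


def extract_inner_boundary(
    wall_mask: np.ndarray,
    sequence: UltrasoundSequence,
    search_halfwidth: int | None = None,
) -> BoundaryTrack:
    """Track the lumen-wall interface through the sequence.

    The lumen side is the side of the mask with the lower mean intensity in
    the reference (temporal median) frame.  Columns where the half-maximum
    crossing fails in a frame are filled by linear interpolation along the
    wall; the usable range is the largest contiguous run of columns with at
    least 90% direct detections.
    """
    wall_mask = np.asarray(wall_mask, dtype=bool)
    if not wall_mask.any():
        raise ValueError("wall_mask is empty")
    frames = sequence.frames
    T, H, W = frames.shape
    reference = np.median(frames, axis=0)

    col_has = wall_mask.any(axis=0)
    mask_cols = np.flatnonzero(col_has)
    # Work on the full contiguous span; columns without mask pixels are
    # treated as never directly detected and filled by interpolation.
    cols = np.arange(mask_cols[0], mask_cols[-1] + 1)
    covered = col_has[cols]
    top_m = np.argmax(wall_mask[:, mask_cols], axis=0)
    bot_m = H - 1 - np.argmax(wall_mask[::-1, :][:, mask_cols], axis=0)
    thickness = int(np.median(bot_m - top_m + 1))
    top = np.round(np.interp(cols, mask_cols, top_m)).astype(int)
    bot = np.round(np.interp(cols, mask_cols, bot_m)).astype(int)

    def _side_mean(edge: np.ndarray, sign: int) -> float:
        vals = []
        for j, c in enumerate(cols):
            r0 = edge[j] + sign
            r1 = r0 + sign * thickness
            lo, hi = (min(r0, r1), max(r0, r1) + 1)
            lo, hi = max(lo, 0), min(hi, H)
            if hi > lo:
                vals.append(reference[lo:hi, c].mean())
        return float(np.mean(vals)) if vals else np.inf

    above_mean = _side_mean(top, -1)
    below_mean = _side_mean(bot, +1)
    lumen_side: Literal["above", "below"] = (
        "above" if above_mean <= below_mean else "below"
    )

    edge = top if lumen_side == "above" else bot
    # Search the inner half of the band only, so that deeper echogenic
    # layers do not drag the half-maximum level away from the interface.
    hw = (
        search_halfwidth
        if search_halfwidth is not None
        else max(4, int(np.ceil(thickness / 2)))
    )
    # Offsets ordered from lumen toward wall.
    step = 1 if lumen_side == "above" else -1
    offsets = step * np.arange(-hw, hw + 1)
    idx = np.clip(edge[None, :] + offsets[:, None], 0, H - 1)  # (n_off, n_cols)

    n_cols = cols.size
    boundary = np.full((T, n_cols), np.nan)
    direct = np.zeros((T, n_cols), dtype=bool)
    for t in range(T):
        prof = frames[t][idx, cols[None, :]]  # (n_off, n_cols)
        # Light smoothing along the profile suppresses texture bumps that
        # would otherwise cause impulsive bracket switches frame to frame.
        prof = np.vstack(
            [prof[:1], 0.25 * prof[:-2] + 0.5 * prof[1:-1] + 0.25 * prof[2:], prof[-1:]]
        )
        half = 0.5 * (prof.min(axis=0) + prof.max(axis=0))
        above = prof >= half[None, :]
        above[0, :] = False  # need a sample on the lumen side to interpolate
        first = np.argmax(above, axis=0)
        ok = above[first, np.arange(n_cols)] & (prof.max(axis=0) - prof.min(axis=0) > 1e-6)
        i0 = np.where(ok, first, 1)
        prev = prof[i0 - 1, np.arange(n_cols)]
        cur = prof[i0, np.arange(n_cols)]
        denom = cur - prev
        frac = np.where(np.abs(denom) > 1e-12, (half - prev) / denom, 0.5)
        # Sub-pixel crossing in row units, then shift from pixel centers to
        # the geometric edge (+0.5).
        row_prev = edge + step * (-hw + (i0 - 1))
        crossing = row_prev + step * frac
        b = crossing + 0.5
        boundary[t, ok] = b[ok]
        direct[t, ok] = True

    boundary[:, ~covered] = np.nan
    direct[:, ~covered] = False
    frac_direct = direct.mean(axis=0)
    lo, hi = _largest_valid_window(frac_direct, MIN_DIRECT_FRACTION)
    if hi - lo == 0:
        raise BoundaryNotFoundError("no usable run of tracked columns")

    sub_cols = cols[lo:hi]
    rows = boundary[:, lo:hi]
    xs = np.arange(hi - lo)
    for t in range(T):
        good = np.isfinite(rows[t])
        if not good.any():
            raise BoundaryNotFoundError(f"frame {t}: boundary lost everywhere")
        if not good.all():
            rows[t, ~good] = np.interp(xs[~good], xs[good], rows[t, good])

    return BoundaryTrack(
        rows=rows,
        valid_columns=(int(sub_cols[0]), int(sub_cols[-1]) + 1),
        lumen_side=lumen_side,
    )


def default_roi_width(n_columns: int, target_rois: int = 16) -> int:
    """Largest even ROI width giving about ``target_rois`` midway ROIs."""
    w = int(2 * n_columns / (target_rois + 1))
    w -= w % 2
    return max(4, min(w, n_columns - n_columns % 2))


def assign_rois(track: BoundaryTrack, roi_width: int) -> RoiSet:
    """Lay midway-overlapping ROIs over the track's usable columns.

    ``R = floor((L - w) / (w/2)) + 1`` ROIs of width ``w`` starting every
    ``w/2`` columns; trailing columns that do not fill an ROI are dropped.
    """
    w = int(roi_width)
    L = track.n_columns
    if w % 2 != 0 or w < 4:
        raise ValueError("roi_width must be an even integer >= 4")
    if w > L:
        raise ValueError("roi_width exceeds the usable column range")
    rel_starts = np.arange(0, L - w + 1, w // 2)
    starts = track.valid_columns[0] + rel_starts
    return RoiSet(roi_width=w, starts=starts, n_rois=rel_starts.size)


def extract_radial_signals(track: BoundaryTrack, rois: RoiSet) -> RadialSignals:
    """Per-ROI radial distension: ROI-mean boundary row, lumen-positive,
    temporal mean removed."""
    base = track.valid_columns[0]
    sign = -1.0 if track.lumen_side == "above" else 1.0
    sig = np.empty((track.rows.shape[0], rois.n_rois))
    for i, s in enumerate(rois.starts):
        a = s - base
        sig[:, i] = sign * track.rows[:, a : a + rois.roi_width].mean(axis=1)
    sig -= sig.mean(axis=0, keepdims=True)
    return RadialSignals(signals=sig, referenced=True)
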