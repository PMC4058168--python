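"""Reading and writing sequences, traces, and map/feature artifacts.

Sequences are either a directory of same-shaped PNG frames (lexicographic
order, optional ``meta.json`` sidecar with ``frame_rate``) or a multi-page
TIFF.  Integer images are rescaled to [0, 1] by their dtype range.  Matrices
are written as comma-separated CSV with a header row, rows = time or
frequency, columns = ROIs.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError
from .phantom import ECGTrace, UltrasoundSequence
from .roi_tracking import BoundaryTrack

__all__ = [
    "read_sequence",
    "write_sequence",
    "write_ecg",
    "read_ecg",
    "write_boundary",
    "write_matrix",
    "read_matrix",
]

DEFAULT_FRAME_RATE = 30.0


def _scale(frame: np.ndarray) -> np.ndarray:
    if np.issubdtype(frame.dtype, np.integer):
        return frame.astype(float) / np.iinfo(frame.dtype).max
    return frame.astype(float)


def read_sequence(path, frame_rate: float | None = None) -> UltrasoundSequence:
    """Load a grayscale sequence from a frame directory or multi-page TIFF."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise FormatError(f"no image frames found in {path}")
        frames = []
        shape = None
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3:  # collapse RGB(A) to luminance
                img = img[..., :3].mean(axis=-1)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(f"frame {f.name} has shape {img.shape}, expected {shape}")
            frames.append(_scale(np.asarray(img)))
        stack = np.stack(frames)
        if frame_rate is None:
            meta = path / "meta.json"
            if meta.exists():
                frame_rate = float(json.loads(meta.read_text()).get("frame_rate", DEFAULT_FRAME_RATE))
    elif path.suffix.lower() in {".tif", ".tiff"}:
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
        if raw.ndim != 3:
            raise FormatError("TIFF must hold a stack of grayscale pages")
        stack = _scale(np.asarray(raw))
    else:
        raise FormatError(f"unsupported input {path}")
    if stack.shape[0] < 8:
        raise ValueError("a sequence needs at least 8 frames")
    return UltrasoundSequence(frames=stack, frame_rate=frame_rate or DEFAULT_FRAME_RATE)


def write_sequence(seq: UltrasoundSequence, out_dir) -> Path:
    """Write frames as ``frame_%04d.png`` plus a ``meta.json`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        img = np.round(np.clip(frame, 0.0, 1.0) * 255).astype(np.uint8)
        iio.imwrite(out_dir / f"frame_{i:04d}.png", img)
    (out_dir / "meta.json").write_text(
        json.dumps({"frame_rate": seq.frame_rate, "n_frames": seq.n_frames}, indent=2)
    )
    return out_dir


def write_ecg(ecg: ECGTrace, path) -> None:
    df = pd.DataFrame(
        {"frame": np.arange(ecg.samples.size), "amplitude": ecg.samples}
    )
    df.to_csv(path, index=False)


def read_ecg(path) -> ECGTrace:
    df = pd.read_csv(path)
    samples = df["amplitude"].to_numpy(dtype=float)
    # R peaks are recovered as the per-cycle maxima only when stored; a flat
    # trace from disk keeps an empty peak list.
    return ECGTrace(samples=samples, r_peaks=np.array([], dtype=int))


def write_boundary(track: BoundaryTrack, path) -> None:
    t_idx, c_idx = np.meshgrid(
        np.arange(track.rows.shape[0]),
        np.arange(track.valid_columns[0], track.valid_columns[1]),
        indexing="ij",
    )
    pd.DataFrame(
        {"frame": t_idx.ravel(), "column": c_idx.ravel(), "row": track.rows.ravel()}
    ).to_csv(path, index=False)


def write_matrix(values: np.ndarray, path, index: np.ndarray | None = None, index_name: str = "t") -> None:
    df = pd.DataFrame(
        np.asarray(values), columns=[f"roi_{i}" for i in range(np.asarray(values).shape[1])]
    )
    if index is not None:
        df.insert(0, index_name, index)
    df.to_csv(path, index=False)


def read_matrix(path) -> tuple[np.ndarray, np.ndarray | None]:
    df = pd.read_csv(path)
    roi_cols = [c for c in df.columns if c.startswith("roi_")]
    index_cols = [c for c in df.columns if c not in roi_cols]
    idx = df[index_cols[0]].to_numpy() if index_cols else None
    return df[roi_cols].to_numpy(dtype=float), idx
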