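"""Vessel-wall segmentation from spatial texture and temporal variance.

Each pixel of a reference frame (the pixelwise temporal median of the
sequence) is described by three spatial features computed over a square
neighborhood — mean, population standard deviation, and Shannon entropy of a
16-bin intensity histogram — plus one temporal feature, the per-pixel
standard deviation across frames.  The four channels are z-scored and
clustered with k-means (k = 3).  The wall is the cluster that is both
*visible* (mean neighborhood intensity above the global median) and the most
*dynamic* (largest mean temporal standard deviation); its largest connected
component, morphologically closed, is the wall mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk
from sklearn.cluster import KMeans

from .exceptions import NoWallFoundError
from .phantom import UltrasoundSequence

__all__ = [
    "FeatureStack",
    "WallSegmentation",
    "compute_spatial_features",
    "compute_temporal_std",
    "kmeans_segment",
    "select_wall",
    "segment_sequence",
]

N_HIST_BINS = 16
MIN_DYNAMISM = 1e-3


@dataclass
class FeatureStack:
    """Per-pixel features: 3 spatial channels plus the temporal one."""

    spatial: np.ndarray  # (H, W, 3): mean, std, entropy
    temporal_std: np.ndarray  # (H, W)
    window: int

    @property
    def n_features(self) -> int:
        return self.spatial.shape[-1] + 1

    def stacked(self) -> np.ndarray:
        """All four channels as an (H, W, 4) array."""
        return np.concatenate(
            [self.spatial, self.temporal_std[..., None]], axis=-1
        )


@dataclass
class WallSegmentation:
    labels: np.ndarray
    wall_mask: np.ndarray
    k: int
    cluster_dynamism: np.ndarray
    features: FeatureStack | None = None
    reference_frame: np.ndarray | None = None


def compute_spatial_features(frame: np.ndarray, window: int = 9) -> np.ndarray:
    """Neighborhood mean, population std, and histogram entropy per pixel.

    Entropy is Shannon entropy in bits over a fixed 16-bin partition of
    [0, 1].  Borders are handled by reflection padding.
    """
    frame = np.asarray(frame, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if frame.min() < -1e-9 or frame.max() > 1 + 1e-9:
        raise ValueError("frame values must lie in [0, 1]")

    mean = uniform_filter(frame, window, mode="reflect")
    mean_sq = uniform_filter(frame * frame, window, mode="reflect")
    std = np.sqrt(np.clip(mean_sq - mean * mean, 0.0, None))

    bins = np.clip((frame * N_HIST_BINS).astype(int), 0, N_HIST_BINS - 1)
    entropy = np.zeros_like(frame)
    for b in range(N_HIST_BINS):
        p = uniform_filter((bins == b).astype(float), window, mode="reflect")
        p = np.clip(p, 0.0, 1.0)
        nz = p > 1e-12
        entropy[nz] -= p[nz] * np.log2(p[nz])
    return np.stack([mean, std, entropy], axis=-1)


def compute_temporal_std(sequence: UltrasoundSequence | np.ndarray) -> np.ndarray:
    """Per-pixel population standard deviation across frames."""
    frames = sequence.frames if isinstance(sequence, UltrasoundSequence) else sequence
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("temporal std needs at least 2 frames")
    return frames.std(axis=0)


def kmeans_segment(
    features: np.ndarray, k: int = 3, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """Cluster per-pixel feature vectors into ``k`` classes.

    Channels are z-scored before clustering (constant channels are dropped
    to zero), k-means++ initialization with ``n_init`` restarts, the best
    inertia kept; deterministic for a fixed seed.
    """
    features = np.asarray(features, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    h, w = features.shape[:2]
    X = features.reshape(-1, features.shape[-1]).copy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    X -= mu
    nz = sd > 0
    X[:, nz] /= sd[nz]
    X[:, ~nz] = 0.0
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("fewer distinct feature vectors than clusters")
    if k == 1:
        return np.zeros((h, w), dtype=int)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-point convergence chatter
        lab = km.fit_predict(X)
    return lab.reshape(h, w)


def select_wall(
    labels: np.ndarray,
    temporal_std: np.ndarray,
    intensity: np.ndarray,
    min_dynamism: float = MIN_DYNAMISM,
    closing_radius: int = 2,
) -> np.ndarray:
    """Pick the moving, visible cluster and return its main component.

    Candidate clusters must have a mean neighborhood intensity above the
    global median (visibility guard); among those the one with the largest
    mean temporal standard deviation wins.  A near-zero winning dynamism
    means the scene is static and no wall exists.
    """
    labels = np.asarray(labels)
    if labels.shape != np.asarray(temporal_std).shape:
        raise ValueError("labels and temporal_std must be congruent")
    ids = np.unique(labels)
    dyn = np.array([temporal_std[labels == c].mean() for c in ids])
    vis = np.array([intensity[labels == c].mean() for c in ids])
    visible = vis > np.median(intensity)
    if not visible.any():
        raise NoWallFoundError("no cluster passes the visibility guard")
    dyn_vis = np.where(visible, dyn, -np.inf)
    winner = ids[int(np.argmax(dyn_vis))]
    if dyn_vis.max() < min_dynamism:
        raise NoWallFoundError("sequence appears static; no moving wall")
    mask = labels == winner
    mask = closing(mask, footprint=disk(closing_radius))
    comps = cc_label(mask, connectivity=1)
    if comps.max() == 0:
        raise NoWallFoundError("selected cluster is empty after closing")
    sizes = np.bincount(comps.ravel())[1:]
    return comps == (int(np.argmax(sizes)) + 1)


def segment_sequence(
    sequence: UltrasoundSequence,
    window: int = 9,
    k: int = 3,
    seed: int = 0,
) -> WallSegmentation:
    """Full segmentation stage: features, clustering, wall selection."""
    reference = np.median(sequence.frames, axis=0)
    spatial = compute_spatial_features(reference, window=window)
    tstd = compute_temporal_std(sequence)
    feats = FeatureStack(spatial=spatial, temporal_std=tstd, window=window)
    labels = kmeans_segment(feats.stacked(), k=k, seed=seed)
    dyn = np.array([tstd[labels == c].mean() for c in np.unique(labels)])
    wall = select_wall(labels, tstd, spatial[..., 0])
    return WallSegmentation(
        labels=labels,
        wall_mask=wall,
        k=k,
        cluster_dynamism=dyn,
        features=feats,
        reference_frame=reference,
    )
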