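"""Shared fixtures: cached full-pipeline runs on phantom cases."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import settings

import cartwave as cw
from cartwave.phantom import PhantomConfig, generate_phantom

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@dataclass
class CaseRun:
    """Everything downstream tests need from one phantom pipeline run."""

    config: PhantomConfig
    dice: float
    boundary_rmse: float
    signals: np.ndarray
    ft2_area: float
    ramp_feature: float
    mean_spectrum_area: float


@lru_cache(maxsize=None)
def run_case(
    category: str,
    seed: int,
    heterogeneity: float = 0.0,
    irregularity: float = 0.0,
) -> CaseRun:
    cfg = PhantomConfig(
        category=category,
        seed=seed,
        heterogeneity=heterogeneity,
        irregularity=irregularity,
    )
    seq, ecg, truth = generate_phantom(cfg)
    seg = cw.segment_sequence(seq, seed=seed)
    inter = (seg.wall_mask & truth.wall_mask).sum()
    dice = 2 * inter / (seg.wall_mask.sum() + truth.wall_mask.sum())
    track = cw.extract_inner_boundary(seg.wall_mask, seq)
    c0, c1 = track.valid_columns
    rmse = float(np.sqrt(np.mean((track.rows - truth.boundary[:, c0:c1]) ** 2)))
    rois = cw.assign_rois(track, cw.default_roi_width(track.n_columns))
    signals = cw.extract_radial_signals(track, rois)
    ss = cw.build_spatiospectral(cw.build_spatiotemporal(signals))
    feats = cw.compute_case_features(ss)
    return CaseRun(
        config=cfg,
        dice=float(dice),
        boundary_rmse=rmse,
        signals=signals.signals,
        ft2_area=feats.ft2_area,
        ramp_feature=feats.ramp_feature,
        mean_spectrum_area=feats.mean_spectrum_area,
    )


@pytest.fixture(scope="session")
def young_cases() -> list[CaseRun]:
    """Default young phantoms, seeds 1-10."""
    return [run_case("young", s) for s in range(1, 11)]


@pytest.fixture(scope="session")
def case_runner():
    return run_case
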