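"""Synthetic ultrasound phantom of a pulsating carotid-artery wall.

The phantom renders a longitudinal B-mode view: an anechoic lumen above a
bright, layered wall band (intima / echolucent media / adventitia) sitting on
speckle-textured tissue.  The inner (lumen-facing) boundary of the band rides
on a class-specific radial waveform that propagates along the vessel with a
finite phase velocity, mimicking the pulse wave.  Three case categories are
emulated:

``young``
    three damped longitudinal oscillations per cardiac cycle, repeated
    identically cycle after cycle (a compliant, homogeneous wall);
``elderly``
    a slow, strongly damped, low-amplitude double oscillation (a stiffer but
    still regular wall);
``cad``
    a double oscillation with cycle-to-cycle amplitude/phase/frequency jitter
    (coronary-artery-disease-like irregular motion).

Two dimensionless dials control departure from wall homogeneity:

``heterogeneity``
    modulates the motion amplitude along the wall *and* injects a
    position-dependent high-frequency motion component whose local frequency
    grows with the dial, so that larger values produce spectrally broader,
    spatially non-uniform wall motion;
``irregularity``
    scales the per-cycle random jitter of the ``cad`` waveform.

Speckle and texture are static (tissue-bound) multiplicative fields, and the
wall texture moves rigidly with the wall, which is what makes the moving band
stand out in the temporal-variance feature used by the segmentation stage.
All randomness derives from ``PhantomConfig.seed``; identical configurations
produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CATEGORIES",
    "PhantomConfig",
    "UltrasoundSequence",
    "ECGTrace",
    "PhantomTruth",
    "generate_ecg",
    "motion_waveform",
    "generate_phantom",
]

CATEGORIES = ("young", "elderly", "cad")

# Base waveforms: exponentially damped sinusoids with 3 (young) or 2
# (elderly, cad) local maxima per cycle; peak amplitude normalized to 1
# (elderly carries an intrinsic 0.4 attenuation: its motion is weaker).
_DAMPING = {"young": 2.2, "elderly": 2.8, "cad": 1.2}
_N_OSC = {"young": 3, "elderly": 2, "cad": 2}
_INTRINSIC = {"young": 1.0, "elderly": 0.4, "cad": 0.65}

# Broadband heterogeneity component: per-position band-limited motion whose
# upper band edge grows with the heterogeneity dial (in cycles per cardiac
# cycle, from _BAND_LO up to the Nyquist limit of the sequence).
_BAND_LO = 4.0
_BAND_SOFTNESS = 0.7
_BAND_AMP = 1.2
_BAND_EDGE_EXP = 0.7
_AMP_MOD = 0.05
# Even a perfectly healthy wall distends a few percent unevenly along an
# 11 mm segment; this fixed baseline modulation (zero at column 0) keeps the
# homogeneous case realistic rather than mathematically identical.
_AMP_MOD_BASE = 0.04


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic sequence; see module docstring."""

    height: int = 128
    width: int = 256
    n_frames: int = 120
    frame_rate: float = 30.0
    n_cycles: int = 3
    wall_row: float = 56.0
    wall_thickness: float = 16.0
    lumen_intensity: float = 0.05
    wall_intensity: float = 0.85
    tissue_intensity: float = 0.35
    speckle_scale: float = 0.05
    amplitude: float = 2.0
    wave_speed: float = 40.0
    category: Literal["young", "elderly", "cad"] = "young"
    heterogeneity: float = 0.0
    irregularity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.n_frames < 2 * self.n_cycles:
            raise ValueError("n_frames must be >= 2 * n_cycles")
        if not (self.wall_row + self.wall_thickness < self.height):
            raise ValueError("wall band must fit inside the image")
        for name in ("lumen_intensity", "wall_intensity", "tissue_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.heterogeneity < 0 or self.irregularity < 0:
            raise ValueError("heterogeneity and irregularity must be >= 0")
        if self.wave_speed <= 0:
            raise ValueError("wave_speed must be positive")


@dataclass
class UltrasoundSequence:
    """Stack of grayscale frames (n_frames, height, width) in [0, 1]."""

    frames: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) stack")
        if self.frames.shape[0] < 8:
            raise ValueError("a sequence needs at least 8 frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class ECGTrace:
    """Schematic ECG sampled once per frame; cycle starts at the R peaks."""

    samples: np.ndarray
    r_peaks: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        if self.r_peaks.size and (
            self.r_peaks[0] < 0 or self.r_peaks[-1] >= self.samples.size
        ):
            raise ValueError("r_peaks out of range")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated sequence.

    ``boundary[t, x]`` is the sub-pixel row of the lumen-wall interface;
    ``radial_signal_true[t, x]`` is the mean-removed radial displacement in
    pixels, positive toward the lumen; ``wall_mask`` is the band at its
    time-averaged position.
    """

    wall_mask: np.ndarray
    boundary: np.ndarray
    radial_signal_true: np.ndarray
    config: PhantomConfig = field(repr=False, default=None)


def _pqrst(tau: np.ndarray) -> np.ndarray:
    """Schematic PQRST template on the unit cycle, R spike at tau = 0."""
    out = np.zeros_like(tau, dtype=float)
    # (center, amplitude, width) of Gaussian bumps, cycle-wrapped.
    for c, a, w in (
        (0.0, 1.0, 0.03),  # R
        (0.97, -0.12, 0.02),  # Q
        (0.05, -0.18, 0.025),  # S
        (0.33, 0.30, 0.06),  # T
        (0.82, 0.16, 0.05),  # P
    ):
        d = tau - c
        d -= np.round(d)  # wrap to [-0.5, 0.5)
        out += a * np.exp(-((d / w) ** 2))
    return out


def generate_ecg(n_frames: int, n_cycles: int, frame_rate: float = 30.0) -> ECGTrace:
    """Generate a schematic ECG with ``n_cycles`` beats over ``n_frames``."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if n_frames < 4 * n_cycles:
        raise ValueError("n_frames must be >= 4 * n_cycles")
    bounds = np.round(np.arange(n_cycles + 1) * n_frames / n_cycles).astype(int)
    r_peaks = bounds[:-1]
    frames = np.arange(n_frames)
    cycle = np.searchsorted(bounds, frames, side="right") - 1
    tau = (frames - bounds[cycle]) / (bounds[cycle + 1] - bounds[cycle])
    return ECGTrace(samples=_pqrst(tau), r_peaks=r_peaks)


def _base_waveform(category: str, tau: np.ndarray) -> np.ndarray:
    lam = _DAMPING[category]
    k = _N_OSC[category]
    return np.exp(-lam * tau) * np.sin(2 * np.pi * k * tau)


def _peak_norm(category: str) -> float:
    grid = np.linspace(0.0, 1.0, 4001, endpoint=False)
    return float(np.max(np.abs(_base_waveform(category, grid))))


_PEAK_NORM = {c: _peak_norm(c) for c in CATEGORIES}


def _cycle_jitter(seed: int, cycle_index: int, irregularity: float):
    """Deterministic per-cycle (amplitude, phase, frequency) jitter."""
    rng = np.random.default_rng([int(seed), 7919, int(cycle_index)])
    xi = np.clip(rng.standard_normal(3), -2.0, 2.0)
    amp = 1.0 + 0.3 * irregularity * xi[0]
    phase = 0.8 * irregularity * xi[1]
    nu = 1.0 + 0.35 * irregularity * xi[2]
    return amp, phase, nu


def motion_waveform(
    category: str,
    t,
    period: float = 1.0,
    cycle_index: int = 0,
    irregularity: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Radial displacement waveform at time ``t`` (seconds) within one cycle.

    Unit peak amplitude for ``irregularity == 0`` (the elderly class carries
    an intrinsic attenuation because its motion is weaker).  The ``cad``
    class perturbs amplitude, phase, and frequency per cycle; ``young`` and
    ``elderly`` ignore ``cycle_index``.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t >= period):
        raise ValueError("t must satisfy 0 <= t < period")
    tau = t / period
    scale = _INTRINSIC[category] / _PEAK_NORM[category]
    if category == "cad" and irregularity > 0:
        amp, phase, nu = _cycle_jitter(seed, cycle_index, irregularity)
        lam = _DAMPING["cad"]
        w = amp * np.exp(-lam * tau) * np.sin(2 * np.pi * _N_OSC["cad"] * nu * tau + phase)
        return scale * w
    return scale * _base_waveform(category, tau)


def _waveform_grid(cfg: PhantomConfig, phase: np.ndarray) -> np.ndarray:
    """Evaluate the category waveform on a grid of global cycle phases.

    ``phase`` counts cardiac cycles continuously (may be negative for delayed
    columns); the per-cycle jitter index wraps modulo ``n_cycles`` so that
    delayed columns replay the same irregular sequence.
    """
    cyc = np.floor(phase).astype(int)
    tau = phase - cyc
    cyc_mod = np.mod(cyc, cfg.n_cycles)
    scale = _INTRINSIC[cfg.category] / _PEAK_NORM[cfg.category]
    if cfg.category == "cad" and cfg.irregularity > 0:
        out = np.empty_like(tau)
        lam = _DAMPING["cad"]
        for c in np.unique(cyc_mod):
            amp, phi, nu = _cycle_jitter(cfg.seed, int(c), cfg.irregularity)
            m = cyc_mod == c
            out[m] = amp * np.exp(-lam * tau[m]) * np.sin(
                2 * np.pi * _N_OSC["cad"] * nu * tau[m] + phi
            )
        return scale * out
    return scale * _base_waveform(cfg.category, tau)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Smoothed, zero-mean, unit-std random field (speckle-like texture)."""
    f = gaussian_filter(rng.uniform(-1.0, 1.0, size=shape), sigma, mode="wrap")
    sd = f.std()
    if sd > 0:
        f = f / sd
    return np.clip(f, -2.5, 2.5)


def true_displacement(cfg: PhantomConfig) -> np.ndarray:
    """Radial displacement d(t, x) in pixels, positive toward the lumen.

    The displacement is the category waveform, delayed by ``x / wave_speed``
    and amplitude-modulated along the wall, plus (for ``heterogeneity > 0``)
    a band-limited broadband component whose local upper band edge grows
    with the dial — at 1.0 some positions cover nearly the whole spectrum,
    which is the signature of spectrally heterogeneous, CAD-like motion.
    """
    t = np.arange(cfg.n_frames, dtype=float)[:, None]
    x = np.arange(cfg.width, dtype=float)[None, :]
    t_delayed = t - x / cfg.wave_speed
    phase = t_delayed * cfg.n_cycles / cfg.n_frames  # cardiac-cycle units

    amp_profile = 1.0 + (
        _AMP_MOD_BASE + cfg.heterogeneity * _AMP_MOD
    ) * np.sin(3 * np.pi * x / cfg.width)
    d = amp_profile * _waveform_grid(cfg, phase)

    if cfg.heterogeneity > 0:
        f_hi = cfg.n_frames / (2.0 * cfg.n_cycles)  # Nyquist, cycles/cycle
        # Components on the DFT bin grid so the injected band is spectrally
        # contiguous rather than a sparse comb.
        freqs = np.arange(
            _BAND_LO, f_hi + 0.5 / cfg.n_cycles, 1.0 / cfg.n_cycles
        )
        rng = np.random.default_rng([int(cfg.seed), 104729])
        theta = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
        g_freq = 0.5 * (1.0 + np.sin(3 * np.pi * x / cfg.width + 0.5))
        b_amp = 0.65 + 0.35 * np.cos(4 * np.pi * x / cfg.width + 1.2)
        f_edge = _BAND_LO + (f_hi - _BAND_LO) * (
            cfg.heterogeneity**_BAND_EDGE_EXP
        ) * g_freq
        scale = _BAND_AMP * cfg.heterogeneity / np.sqrt(freqs.size)
        hf = np.zeros_like(phase)
        for fj, th in zip(freqs, theta):
            w = 1.0 / (1.0 + np.exp((fj - f_edge) / _BAND_SOFTNESS))
            hf += (b_amp * w) * np.sin(2 * np.pi * fj * phase + th)
        d = d + scale * hf
    return cfg.amplitude * d


def _wall_profile(u: np.ndarray) -> np.ndarray:
    """Layered radial intensity profile across the wall (u in [0, 1])."""
    return 1.0 - 0.45 * np.exp(-(((u - 0.45) / 0.22) ** 2))


def generate_phantom(
    config: PhantomConfig,
) -> tuple[UltrasoundSequence, ECGTrace, PhantomTruth]:
    """Render the phantom sequence together with its ECG and ground truth."""
    cfg = config
    H, W, T = cfg.height, cfg.width, cfg.n_frames

    disp = true_displacement(cfg)  # (T, W)
    boundary = cfg.wall_row - disp
    if boundary.min() < 1.0 or (boundary + cfg.wall_thickness).max() > H - 1.0:
        raise ValueError("displacement pushes the wall boundary out of frame")

    rng = np.random.default_rng(cfg.seed)
    # Wall texture lives in wall coordinates and moves rigidly with the band.
    q_pad = 2
    nq = int(np.ceil(cfg.wall_thickness)) + 2 * q_pad + 1
    wall_tex = _smooth_field(rng, (nq, W), 1.2)
    tissue_tex = _smooth_field(rng, (H, W), 1.2)
    speckle = _smooth_field(rng, (H, W), 1.0)

    rows = np.arange(H, dtype=float)[:, None]  # (H, 1)
    tissue_val = cfg.tissue_intensity * (1.0 + 0.12 * tissue_tex)
    gain = 1.0 + cfg.speckle_scale * speckle
    # Faint frame-to-frame electronic noise (well below the quantization
    # step) so spectra have a genuine, if tiny, broadband floor.
    sigma_n = 0.01 * cfg.speckle_scale

    frames = np.empty((T, H, W), dtype=float)
    col_idx = np.broadcast_to(np.arange(W), (H, W))
    for ti in range(T):
        b = boundary[ti][None, :]  # (1, W)
        cov_wall = np.clip(
            np.minimum(rows + 1.0, b + cfg.wall_thickness) - np.maximum(rows, b),
            0.0,
            1.0,
        )
        cov_lumen = np.clip(b - rows, 0.0, 1.0)
        cov_tissue = np.clip(1.0 - cov_wall - cov_lumen, 0.0, 1.0)

        q = rows + 0.5 - b  # depth inside the wall band
        qi = np.clip(q + q_pad, 0.0, nq - 1.001)
        q0 = np.floor(qi).astype(int)
        fr = qi - q0
        tex = (1 - fr) * wall_tex[q0, col_idx] + fr * wall_tex[q0 + 1, col_idx]
        wall_val = (
            cfg.wall_intensity
            * _wall_profile(np.clip(q / cfg.wall_thickness, 0.0, 1.0))
            * (1.0 + 0.18 * tex)
        )

        img = (
            cov_lumen * cfg.lumen_intensity
            + cov_wall * wall_val
            + cov_tissue * tissue_val
        )
        img = img * gain
        if sigma_n > 0:
            img = img + sigma_n * rng.standard_normal((H, W))
        frames[ti] = np.clip(img, 0.0, 1.0)

    ecg = generate_ecg(T, cfg.n_cycles, cfg.frame_rate)

    mean_b = boundary.mean(axis=0)  # (W,)
    centers = np.arange(H, dtype=float)[:, None] + 0.5
    wall_mask = (centers >= mean_b[None, :]) & (
        centers < mean_b[None, :] + cfg.wall_thickness
    )
    radial = disp - disp.mean(axis=0, keepdims=True)
    truth = PhantomTruth(
        wall_mask=wall_mask, boundary=boundary, radial_signal_true=radial, config=cfg
    )
    return UltrasoundSequence(frames=frames, frame_rate=cfg.frame_rate), ecg, truth
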