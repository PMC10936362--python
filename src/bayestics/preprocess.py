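"""Turn a raw time-lapse stack plus spot locations into analysis-ready ROI series.

Pipeline for one spot: crop the ROI, estimate the static fluorescent
background as the per-pixel temporal median over the last ``background_frames``
frames (the end of the sequence, where the user keeps the window free of
other diffusing spots), subtract it, locate the fusion frame t0 as the frame
of maximal total ROI intensity, truncate to the ``T_fit`` frames starting at
t0, and optionally apply the generalized Anscombe transform to stabilize
Poisson–Gaussian camera noise into approximately Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import tifffile

from .correlation import ROISeries

__all__ = [
    "ImageSequence",
    "PreprocessConfig",
    "read_stack",
    "write_stack",
    "extract_roi",
    "detect_t0",
    "estimate_background",
    "subtract_background",
    "truncate_series",
    "generalized_anscombe",
    "estimate_noise_params",
    "preprocess_roi",
]


@dataclass
class ImageSequence:
    """A T×H×W grayscale stack with frame-interval metadata; the raw observation."""

    data: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be T×H×W, got shape {self.data.shape}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing settings for one run.

    ``roi_size`` is (My, Mx); odd sizes center the spot on a pixel.  Even
    sizes are accepted with the half-pixel convention documented in
    :func:`extract_roi`.  ``t_fit`` is the number of frames retained after t0
    (100 suffices for the G1 model, 300 for G2).  ``anscombe`` enables the
    variance-stabilizing transform; its (gain, sigma_read, offset) default to
    a robust estimate from the darkest pixels when set to None.
    """

    roi_size: tuple[int, int] = (31, 31)
    background_frames: int = 20
    background_mode: str = "last"  # "last" | "first"
    background_subtract: bool = True
    t_fit: int = 100
    t0: int | None = None  # known release frame; None -> detect_t0
    anscombe: bool = False
    noise_params: tuple[float, float, float] | None = None  # (gain, sigma_read, offset)

    def __post_init__(self) -> None:
        my, mx = self.roi_size
        if my < 3 or mx < 3:
            raise ValueError("roi_size must be at least 3×3")
        if self.background_frames < 1:
            raise ValueError("background_frames must be >= 1")
        if self.t_fit < 2:
            raise ValueError("t_fit must be >= 2")
        if self.background_mode not in ("last", "first"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")


def read_stack(path, frame_interval: float = 1.0) -> ImageSequence:
    """Load a multi-page grayscale TIFF (8/16-bit integer or 32-bit float)."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageSequence(data, frame_interval=frame_interval)


def write_stack(path, seq: ImageSequence | np.ndarray) -> None:
    """Write a stack back to multi-page TIFF (float32) for inspection."""
    data = seq.data if isinstance(seq, ImageSequence) else np.asarray(seq)
    tifffile.imwrite(path, data.astype(np.float32), photometric="minisblack")


def extract_roi(seq: ImageSequence, center: tuple[int, int], size: tuple[int, int]) -> ROISeries:
    """Crop a (My, Mx) ROI around ``center`` from every frame.

    Half-open pixel ranges [origin, origin+size).  For odd sizes the center
    pixel is ``center``; for even sizes the ROI starts at
    ``center - size//2 + 1`` so ``center`` sits just below-left of the ROI
    midpoint (half-pixel convention).  An ROI crossing the image border is an
    error — no padding is invented.
    """
    my, mx = int(size[0]), int(size[1])
    row, col = int(center[0]), int(center[1])
    r0 = row - (my - 1) // 2
    c0 = col - (mx - 1) // 2
    _, h, w = seq.data.shape
    if r0 < 0 or c0 < 0 or r0 + my > h or c0 + mx > w:
        raise ValueError(
            f"ROI rows [{r0}, {r0 + my}) cols [{c0}, {c0 + mx}) crosses the "
            f"border of a {h}×{w} image"
        )
    crop = np.array(seq.data[:, r0 : r0 + my, c0 : c0 + mx], dtype=float)
    return ROISeries(crop, origin=(r0, c0), t0=0, frame_interval=seq.frame_interval)


def detect_t0(roi: ROISeries, mode: str = "peak") -> int:
    """Frame of maximal fluorescence intensity (the fusion flash); ties -> earliest.

    ``mode="peak"`` (default) takes the maximum 3×3-smoothed pixel value per
    frame: the peak of a diffusing spot decays like 1/s²(t), so the flash
    frame stands out sharply even under noise.  ``mode="total"`` uses the
    summed ROI intensity instead; note that 2D diffusion conserves the total
    within the ROI until the spot reaches the border, so this variant only
    discriminates when pre-release frames are dark (e.g. pHluorin, which
    lights up at fusion).
    """
    if mode == "total":
        scores = roi.data.sum(axis=(1, 2))
    elif mode == "peak":
        smoothed = np.array([_box3(frame) for frame in roi.data])
        scores = smoothed.max(axis=(1, 2))
    else:
        raise ValueError(f"unknown detect_t0 mode {mode!r}")
    return int(np.argmax(scores))


def _box3(frame: np.ndarray) -> np.ndarray:
    """3×3 box mean with edge replication."""
    padded = np.pad(frame, 1, mode="edge")
    out = np.zeros_like(frame, dtype=float)
    for dr in range(3):
        for dc in range(3):
            out += padded[dr : dr + frame.shape[0], dc : dc + frame.shape[1]]
    return out / 9.0


def estimate_background(roi: ROISeries, n_frames: int, mode: str = "last") -> np.ndarray:
    """Per-pixel temporal median over ``n_frames`` frames (default: the last ones).

    The end of the sequence is used because the diffusing spot has dissipated
    there; ``mode="first"`` is available for sequences whose start is clean
    instead.
    """
    if n_frames > roi.n_frames:
        raise ValueError(f"n_frames={n_frames} exceeds series length {roi.n_frames}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames = roi.data[-n_frames:] if mode == "last" else roi.data[:n_frames]
    return np.median(frames, axis=0)


def subtract_background(roi: ROISeries, background: np.ndarray) -> ROISeries:
    """Pixelwise subtraction; values may go negative (signed fluctuations are fine)."""
    background = np.asarray(background, dtype=float)
    if background.shape != roi.data.shape[1:]:
        raise ValueError(
            f"background shape {background.shape} does not match ROI {roi.data.shape[1:]}"
        )
    return ROISeries(
        roi.data - background, origin=roi.origin, t0=roi.t0, frame_interval=roi.frame_interval
    )


def truncate_series(roi: ROISeries, t0: int, t_fit: int) -> ROISeries:
    """Keep frames [t0, t0 + t_fit); the new series has its reference frame at index 0.

    If fewer than ``t_fit`` frames remain after t0, all available frames are
    kept and a warning is emitted.
    """
    if not 0 <= t0 < roi.n_frames:
        raise ValueError(f"t0={t0} outside [0, {roi.n_frames})")
    available = roi.n_frames - t0
    if t_fit > available:
        warnings.warn(
            f"t_fit={t_fit} exceeds the {available} frames after t0; keeping all of them",
            stacklevel=2,
        )
    end = t0 + min(t_fit, available)
    return ROISeries(
        np.array(roi.data[t0:end]), origin=roi.origin, t0=0, frame_interval=roi.frame_interval
    )


def generalized_anscombe(
    img, gain: float = 1.0, sigma_read: float = 0.0, offset: float = 0.0
) -> np.ndarray:
    """Generalized Anscombe transform for Poisson–Gaussian noise.

    f(x) = (2/g)·sqrt(g·x + 3/8·g² + σ_r² − g·m); the argument is clamped to
    zero below the formula's domain floor.  With g=1, σ_r=0, m=0 this is the
    classical Anscombe transform 2·sqrt(x + 3/8).  Monotone in x.
    """
    if not gain > 0:
        raise ValueError(f"gain must be positive, got {gain}")
    x = np.asarray(img, dtype=float)
    arg = gain * x + 0.375 * gain**2 + sigma_read**2 - gain * offset
    return 2.0 / gain * np.sqrt(np.maximum(arg, 0.0))


def estimate_noise_params(stack: np.ndarray) -> tuple[float, float, float]:
    """Crude Poisson–Gaussian noise parameters from the darkest 10% of pixels.

    Assumes unit gain (real TIRF metadata rarely records it); the read-noise
    sd and offset come from the spread and level of the darkest pixels.
    """
    flat = np.asarray(stack, dtype=float).ravel()
    dark = flat[flat <= np.percentile(flat, 10)]
    return 1.0, float(dark.std()), float(dark.mean())


def preprocess_roi(
    seq: ImageSequence, center: tuple[int, int], config: PreprocessConfig
) -> ROISeries:
    """Full per-spot pipeline: crop, background-subtract, find t0, truncate, stabilize.

    Deterministic: a given stack and config always yield the identical series.
    """
    roi = extract_roi(seq, center, config.roi_size)
    if config.anscombe:
        params = config.noise_params or estimate_noise_params(roi.data)
        roi = ROISeries(
            generalized_anscombe(roi.data, *params),
            origin=roi.origin, t0=roi.t0, frame_interval=roi.frame_interval,
        )
    if config.background_subtract:
        background = estimate_background(roi, config.background_frames, config.background_mode)
        roi = subtract_background(roi, background)
    t0 = detect_t0(roi) if config.t0 is None else int(config.t0)
    return truncate_series(roi, t0, config.t_fit)
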