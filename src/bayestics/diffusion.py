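"""Closed-form physics of an isolated 2D diffusing spot imaged through a Gaussian PSF.

A fusion event releases ``C0`` molecules at a point ``x0`` in the plasma
membrane at time ``t0``.  The molecules undergo free lateral Brownian motion
with diffusion coefficient ``D`` (pixel²/frame), so the concentration field is
the 2D heat kernel.  The microscope blurs this field with a point spread
function approximated by an isotropic 2D Gaussian of bandwidth ``sigma_psf``
(peak-normalized, i.e. h(x) = exp(-|x|²/(2σ²))), and the camera records an
intensity proportional to the blurred concentration with a lumped gain that
folds photon-collection efficiency, molecular absorption and quantum yield
into one factor.

Because a Gaussian convolved with a Gaussian is a Gaussian, the noiseless
image of the spot at elapsed time t after release is itself a 2D Gaussian
whose per-axis variance grows linearly, s²(t) = σ² + 2Dt, with a constant
spatial integral (mass conservation).

Conventions
-----------
* D is carried in pixel²/frame.  Use :func:`d_to_um2_per_s` to convert to
  µm²/s given pixel size and frame interval.
* Pixel coordinates are 0-based ``(row, col)``; a pixel's center is at
  integer coordinates.  The source position ``x0`` is continuous and may be
  off-center.
* Elapsed time inside the models is measured from the release frame with the
  first usable frame at t = 1 frame (the ``t_offset`` convention used
  throughout the package), which avoids the t = 0 singularity of the heat
  kernel.  The intensity itself is well defined at t = 0, where the profile
  is the PSF scaled by gain·C0.
* Frames are rendered by point-evaluation at pixel centers (PSF widths of
  ≥ 1 px make area integration over the pixel indistinguishable in practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiffusionParams",
    "OpticsParams",
    "concentration",
    "intensity",
    "render_frame",
    "profile_variance",
    "d_to_um2_per_s",
]

#: Default PSF bandwidth (pixels) used across the package when none is given.
#: Matches a slightly oversampled TIRF setup (FWHM ≈ 3 px).
DEFAULT_SIGMA_PSF = 1.3

#: Default elapsed-time offset (frames) assigned to the reference frame.
DEFAULT_T_OFFSET = 1.0


@dataclass(frozen=True)
class DiffusionParams:
    """Physical parameters of one diffusing spot.

    Parameters
    ----------
    D : float
        Diffusion coefficient, pixel²/frame.  Must be positive (use a static
        clutter spot in :mod:`bayestics.simulate` for D = 0 sources).
    C0 : float
        Number of molecules released at the source.
    x0 : tuple of float
        Source position ``(row, col)`` in continuous pixel coordinates.
    t0 : int
        Release frame index in the parent sequence.
    """

    D: float
    C0: float
    x0: tuple[float, float] = (0.0, 0.0)
    t0: int = 0

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if not self.C0 > 0:
            raise ValueError(f"C0 must be positive, got {self.C0}")


@dataclass(frozen=True)
class OpticsParams:
    """Imaging parameters: PSF bandwidth and lumped intensity gain.

    ``gain`` is the single proportionality factor combining the instrument's
    photon-collection efficiency, the molecular absorption coefficient and
    the fluorophore quantum yield; it is never decomposed.
    """

    sigma_psf: float = DEFAULT_SIGMA_PSF
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma_psf > 0:
            raise ValueError(f"sigma_psf must be positive, got {self.sigma_psf}")
        if not self.gain > 0:
            raise ValueError(f"gain must be positive, got {self.gain}")


def concentration(x, t, p: DiffusionParams):
    """Heat-kernel concentration (molecules/pixel²) at position ``x``, elapsed time ``t``.

    Free-space solution of Fick's second law with a delta initial condition of
    mass ``C0`` at ``x0``:

        C(x, t) = C0 / (4·π·D·t) · exp(-|x - x0|² / (4·D·t))

    ``x`` is an array whose last axis is ``(row, col)``; ``t`` must be > 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("concentration requires elapsed time t > 0")
    x = np.asarray(x, dtype=float)
    r2 = np.sum((x - np.asarray(p.x0, dtype=float)) ** 2, axis=-1)
    return p.C0 / (4.0 * np.pi * p.D * t) * np.exp(-r2 / (4.0 * p.D * t))


def profile_variance(t, p: DiffusionParams, o: OpticsParams):
    """Per-axis variance s²(t) = σ² + 2·D·t of the imaged spot profile."""
    return o.sigma_psf**2 + 2.0 * p.D * np.asarray(t, dtype=float)


def intensity(x, t, p: DiffusionParams, o: OpticsParams):
    """Noiseless fluorescence intensity (a.u.) of the spot at elapsed time ``t`` ≥ 0.

    The concentration convolved with the peak-normalized Gaussian PSF and
    scaled by the lumped gain:

        i(x, t) = gain · C0 · σ² / s²(t) · exp(-|x - x0|² / (2·s²(t))),
        s²(t) = σ² + 2·D·t.

    At t = 0 this is the PSF itself scaled by gain·C0.  Its spatial integral,
    gain·C0·2πσ², is independent of t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("intensity requires elapsed time t >= 0")
    x = np.asarray(x, dtype=float)
    s2 = profile_variance(t, p, o)
    r2 = np.sum((x - np.asarray(p.x0, dtype=float)) ** 2, axis=-1)
    return o.gain * p.C0 * o.sigma_psf**2 / s2 * np.exp(-r2 / (2.0 * s2))


def render_frame(shape: tuple[int, int], t, p: DiffusionParams, o: OpticsParams) -> np.ndarray:
    """Evaluate :func:`intensity` at the pixel centers of an ``(My, Mx)`` lattice.

    Deterministic; uses the separability of the Gaussian profile so large
    frames never materialize a (My, Mx, 2) coordinate array.
    """
    my, mx = int(shape[0]), int(shape[1])
    if my <= 0 or mx <= 0:
        raise ValueError(f"grid must be nonempty, got shape {shape}")
    s2 = float(profile_variance(t, p, o))
    rows = np.arange(my, dtype=float) - p.x0[0]
    cols = np.arange(mx, dtype=float) - p.x0[1]
    amp = o.gain * p.C0 * o.sigma_psf**2 / s2
    u = np.exp(-(rows**2) / (2.0 * s2))
    v = np.exp(-(cols**2) / (2.0 * s2))
    return amp * np.outer(u, v)


def d_to_um2_per_s(d_px2_per_frame: float, pixel_size_um: float, frame_interval_s: float) -> float:
    """Convert a diffusion coefficient from pixel²/frame to µm²/s."""
    return d_px2_per_frame * pixel_size_um**2 / frame_interval_s
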