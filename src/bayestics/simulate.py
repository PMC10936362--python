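"""Ground-truthed synthetic TIRF sequences: diffusing spots, clutter, noise.

Two independent renderers produce the same physical scene:

* :func:`render_analytic` evaluates the closed-form spot profile (heat kernel
  convolved with the Gaussian PSF) at pixel centers — fast, exact, used by
  the estimation pipeline's test scenes.
* :func:`render_particles` simulates ``n_particles`` Brownian walkers per
  spot (per-axis Gaussian steps of variance 2D per frame, all starting at
  x0) and renders each walker as a Gaussian PSF — a Monte-Carlo image
  formation that never touches the closed form, serving as its physical
  oracle.

SNR convention (the package's own definition, stated because it fixes every
noise level below): peak noiseless amplitude of the main spot at its first
post-fusion frame divided by the additive Gaussian noise sd.

Scene defaults emulate an isolated fusion event: a 61×61 px field, 300
frames, D = 0.5 px²/frame, σ_psf = 1.3 px, gain·C0 = 160 (peak ≈ 100 a.u.).
What they do not emulate: EMCCD gain-register noise, fixed-pattern noise,
photobleaching, blinking, anomalous diffusion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .diffusion import DEFAULT_T_OFFSET, OpticsParams
from .preprocess import ImageSequence, write_stack

__all__ = [
    "SpotSpec",
    "SceneSpec",
    "GroundTruth",
    "ScenarioCase",
    "render_analytic",
    "render_particles",
    "peak_amplitude",
    "snr_sweep",
    "scenario_suite",
    "write_scene",
]


@dataclass(frozen=True)
class SpotSpec:
    """One fluorescent spot.  ``D = 0`` marks a static (non-diffusing) cluster.

    A diffusing spot is dark before its release frame ``t0`` and follows the
    spreading-Gaussian profile afterwards; a static spot shows its PSF in
    every frame.
    """

    D: float
    C0: float
    x0: tuple[float, float]
    t0: int = 0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if not self.C0 > 0:
            raise ValueError(f"C0 must be positive, got {self.C0}")


@dataclass(frozen=True)
class SceneSpec:
    """Complete description of a synthetic sequence (the study conditions).

    ``background`` is (level, grad_row, grad_col): a constant plus a tilted
    plane, the simplest nonuniform field.  ``noise_sigma`` is the sd of the
    i.i.d. additive Gaussian noise.
    """

    image_dims: tuple[int, int] = (61, 61)
    T: int = 300
    spots: tuple[SpotSpec, ...] = (SpotSpec(D=0.5, C0=160.0, x0=(30.0, 30.0)),)
    optics: OpticsParams = field(default_factory=OpticsParams)
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError(f"T must be >= 2, got {self.T}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        h, w = self.image_dims
        for spot in self.spots:
            r, c = spot.x0
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"spot at {spot.x0} outside a {h}×{w} image")

    @property
    def main_spot(self) -> SpotSpec:
        return self.spots[0]


@dataclass
class GroundTruth:
    """Sidecar for a rendered scene: what the estimators should recover."""

    true_D: list
    x0: list
    t0: list
    noise_sigma: float
    snr: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def peak_amplitude(scene: SceneSpec, t_offset: float = DEFAULT_T_OFFSET) -> float:
    """Noiseless peak of the main spot at its first post-release frame."""
    spot = scene.main_spot
    s2 = scene.optics.sigma_psf**2 + 2.0 * spot.D * t_offset
    return scene.optics.gain * spot.C0 * scene.optics.sigma_psf**2 / s2


def _ground_truth(scene: SceneSpec) -> GroundTruth:
    snr = peak_amplitude(scene) / scene.noise_sigma if scene.noise_sigma > 0 else float("inf")
    return GroundTruth(
        true_D=[s.D for s in scene.spots],
        x0=[list(s.x0) for s in scene.spots],
        t0=[s.t0 for s in scene.spots],
        noise_sigma=scene.noise_sigma,
        snr=snr,
    )


def _background_field(scene: SceneSpec) -> np.ndarray:
    level, grad_row, grad_col = scene.background
    h, w = scene.image_dims
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    return level + grad_row * rows + grad_col * cols


def _spot_profile(spot: SpotSpec, frame: int, scene: SceneSpec) -> np.ndarray | None:
    """Analytic profile of one spot in one frame (None when not yet released)."""
    sigma = scene.optics.sigma_psf
    if spot.D == 0:
        s2 = sigma**2
    else:
        if frame < spot.t0:
            return None
        elapsed = frame - spot.t0 + DEFAULT_T_OFFSET
        s2 = sigma**2 + 2.0 * spot.D * elapsed
    h, w = scene.image_dims
    amp = scene.optics.gain * spot.C0 * sigma**2 / s2
    u = np.exp(-((np.arange(h, dtype=float) - spot.x0[0]) ** 2) / (2.0 * s2))
    v = np.exp(-((np.arange(w, dtype=float) - spot.x0[1]) ** 2) / (2.0 * s2))
    return amp * np.outer(u, v)


def render_analytic(scene: SceneSpec) -> tuple[ImageSequence, GroundTruth]:
    """Closed-form render: sum of spot profiles + background + Gaussian noise.

    Bit-identical for identical SceneSpec (the noise comes from
    ``default_rng(scene.seed)``).
    """
    h, w = scene.image_dims
    stack = np.empty((scene.T, h, w), dtype=float)
    background = _background_field(scene)
    for frame in range(scene.T):
        img = background.copy()
        for spot in scene.spots:
            profile = _spot_profile(spot, frame, scene)
            if profile is not None:
                img += profile
        stack[frame] = img
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        stack += rng.normal(0.0, scene.noise_sigma, size=stack.shape)
    return ImageSequence(stack), _ground_truth(scene)


def render_particles(
    scene: SceneSpec, n_particles: int, seed: int | None = None
) -> tuple[ImageSequence, GroundTruth]:
    """Monte-Carlo render: Brownian walkers imaged as Gaussian PSFs.

    Each spot contributes ``n_particles`` walkers of weight C0/n_particles
    starting at x0 at release; per-frame steps are N(0, 2D) on each axis, so
    the position variance after t frames is exactly 2·D·t per axis.  The
    frame rendered at index k uses t = k − t0 + 1 accumulated steps, matching
    the elapsed-time convention of the closed form.  Independent of
    :func:`render_analytic` except for the shared scene description.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    h, w = scene.image_dims
    sigma = scene.optics.sigma_psf
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    stack = np.tile(_background_field(scene)[None], (scene.T, 1, 1))
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    for spot in scene.spots:
        amp = scene.optics.gain * spot.C0 / n_particles
        pos = np.tile(np.asarray(spot.x0, dtype=float), (n_particles, 1))
        for frame in range(scene.T):
            if spot.D > 0:
                if frame < spot.t0:
                    continue
                # one step per frame, including the first rendered frame (t = 1)
                pos = pos + rng.normal(0.0, np.sqrt(2.0 * spot.D), size=pos.shape)
            u = np.exp(-((rows[:, None] - pos[None, :, 0]) ** 2) / (2.0 * sigma**2))
            v = np.exp(-((cols[:, None] - pos[None, :, 1]) ** 2) / (2.0 * sigma**2))
            stack[frame] += amp * (u @ v.T)
    if scene.noise_sigma > 0:
        stack += rng.normal(0.0, scene.noise_sigma, size=stack.shape)
    return ImageSequence(stack), _ground_truth(scene)


def snr_sweep(base: SceneSpec, snr_values) -> list[SceneSpec]:
    """Clone ``base`` once per SNR, setting noise_sigma = peak_amplitude/SNR.

    The default study sweep uses SNR ∈ {5, 8, 12, 18, 25}, spanning the usual
    spot-detection limit up to bright fusion events.
    """
    scenes = []
    peak = peak_amplitude(base)
    for i, snr in enumerate(snr_values):
        if not snr > 0:
            raise ValueError(f"SNR values must be positive, got {snr}")
        scenes.append(replace(base, noise_sigma=peak / snr, seed=base.seed + i))
    return scenes


#: Default SNR levels of the noise-robustness sweep.
DEFAULT_SNR_LEVELS = (5.0, 8.0, 12.0, 18.0, 25.0)


@dataclass(frozen=True)
class ScenarioCase:
    """One entry of the six-case robustness battery."""

    name: str
    scene: SceneSpec
    roi_center: tuple[int, int]
    roi_size: tuple[int, int]
    truth: GroundTruth


def scenario_suite(
    D: float = 0.5,
    C0: float = 160.0,
    T: int = 300,
    seed: int = 0,
) -> list[ScenarioCase]:
    """Six-case battery: off-center spots, varied ROI shapes, clutter, low→high SNR.

    Cases (a)–(f): ROI sizes 15×15, 21×21, 31×31, 31×41, 41×41, 25×31; the
    main spot sits off-center in most ROIs; three cases add clutter (one
    static + one diffusing neighbor); SNR rises from 5 to 25.  The exact
    dimensions are package defaults (arguments override D, C0, T).
    """
    h = w = 61
    cx = 30.0
    sizes = [(15, 15), (21, 21), (31, 31), (31, 41), (41, 41), (25, 31)]
    offsets = [(2.0, -1.0), (-3.0, 2.0), (4.0, 4.0), (0.0, -5.0), (-6.0, 3.0), (2.0, 2.0)]
    snrs = [5.0, 8.0, 12.0, 16.0, 20.0, 25.0]
    clutter_on = [False, False, True, True, True, False]
    cases = []
    for i, (size, off, snr, clutter) in enumerate(zip(sizes, offsets, snrs, clutter_on)):
        x0 = (cx + off[0], cx + off[1])
        spots = [SpotSpec(D=D, C0=C0, x0=x0)]
        if clutter:
            spots.append(SpotSpec(D=0.0, C0=0.5 * C0, x0=(cx - 12.0, cx + 10.0)))
            spots.append(SpotSpec(D=0.7 * D, C0=0.6 * C0, x0=(cx + 11.0, cx - 11.0), t0=0))
        scene = SceneSpec(
            image_dims=(h, w), T=T, spots=tuple(spots), noise_sigma=0.0, seed=seed + i
        )
        scene = replace(scene, noise_sigma=peak_amplitude(scene) / snr)
        # ROIs are centered on the field, so the spot sits off-center in the ROI
        cases.append(
            ScenarioCase(
                name=chr(ord("a") + i),
                scene=scene,
                roi_center=(int(cx), int(cx)),
                roi_size=size,
                truth=_ground_truth(scene),
            )
        )
    return cases


def write_scene(scene: SceneSpec, stack_path, truth_path, renderer=render_analytic) -> GroundTruth:
    """Render a scene and write the TIFF stack plus its JSON ground-truth sidecar."""
    seq, truth = renderer(scene)
    write_stack(stack_path, seq)
    with open(truth_path, "w") as fh:
        fh.write(truth.to_json())
    return truth
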