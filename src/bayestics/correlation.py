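"""Nonstationary temporal autocorrelation: empirical estimators and closed-form models.

A spot released at the reference frame decays and spreads, so the intensity
process in the ROI is not stationary and the usual delay-only autocorrelation
does not apply.  The package anchors the correlation at the reference frame
(the first post-fusion frame, elapsed time t_r): for each temporal lag τ the
empirical statistic is the spatial average over the ROI Ω of the product of
the reference frame with the frame τ later,

    Ĝ(τ) = (1 / (Mx·My)) · Σ_{x∈Ω} i(x, t_r) · i(x, t_r + τ).

Anchoring keeps one factor of the product narrow, so the product profile
stays localized inside the ROI at every lag; this is what makes the closed
forms below exact in practice and the estimate insensitive to ROI size.

For a single spot (uniform background) the model is exactly hyperbolic in τ:

    G1(τ; D, a) = a / (Mx·My · (2σ² + 2D·(2t_r + τ))),   a = 2π·gain²·C0²·σ⁴,

so 1/G1 is an affine function of τ — the basis of the quick linearization
diagnostic :func:`inverse_g1_line`.

For nonuniform/cluttered backgrounds the statistic is computed on
fluctuations δi = i − b̂, where b̂(x) is the per-pixel mean over the last
``tail_frames`` frames of the series (the same end-of-sequence window used
for background estimation, by which time the spot has dissipated).  The
corresponding model G2 equals G1 plus correction terms that depend on the
total observation time T and vanish like 1/T, so G2 reduces to G1 for long
sequences ("out of equilibrium" correction of the finite record).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.special import psi as _digamma

from .diffusion import DEFAULT_SIGMA_PSF, DEFAULT_T_OFFSET

__all__ = [
    "ROISeries",
    "AutocorrCurve",
    "Theta",
    "empirical_autocorr_uniform",
    "empirical_autocorr_fluctuation",
    "model_g1",
    "model_g2",
    "inverse_g1_line",
    "default_max_lag",
]

#: Number of end-of-sequence frames defining the fluctuation baseline b̂(x).
DEFAULT_TAIL_FRAMES = 20

#: Maximum number of pooled frame pairs per lag (see the estimator docstrings).
DEFAULT_N_REF = 10


@dataclass
class ROISeries:
    """A cropped T×My×Mx intensity sub-stack, the unit of analysis.

    Attributes
    ----------
    data : ndarray, shape (T, My, Mx)
        Intensities (a.u.).
    origin : (int, int)
        ``(row, col)`` of the ROI's top-left pixel in the parent image.
    t0 : int
        Reference frame index (release/fusion frame) within this series.
    frame_interval : float
        Seconds per frame; metadata only.
    """

    data: np.ndarray
    origin: tuple[int, int] = (0, 0)
    t0: int = 0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"ROISeries data must be T×My×Mx, got shape {self.data.shape}")
        t, my, mx = self.data.shape
        if t < 2:
            raise ValueError(f"need at least 2 frames, got {t}")
        if my < 3 or mx < 3:
            raise ValueError(f"ROI must be at least 3×3 pixels, got {my}×{mx}")
        if not 0 <= self.t0 < t:
            raise ValueError(f"t0={self.t0} outside [0, {t})")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def roi_dims(self) -> tuple[int, int]:
        """(Mx, My) — width, height."""
        return self.data.shape[2], self.data.shape[1]


@dataclass
class AutocorrCurve:
    """Temporal lags τ and autocorrelation values; both the ABC observation and simulation."""

    lags: np.ndarray
    values: np.ndarray
    variant: str = "uniform"  # "uniform" | "fluctuation" | model id
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have equal length")
        if self.lags.size and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.lags.size and self.lags[0] < 0:
            raise ValueError("lags must start at a nonnegative value")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("autocorrelation values must be finite")

    def to_csv(self) -> str:
        """Two-column CSV (lag_frames, value) with a header comment recording provenance."""
        buf = io.StringIO()
        meta = ", ".join(f"{k}={v}" for k, v in sorted(self.meta.items()))
        buf.write(f"# variant={self.variant}" + (f", {meta}" if meta else "") + "\n")
        buf.write("lag_frames,value\n")
        for lag, val in zip(self.lags, self.values):
            buf.write(f"{int(lag)},{float(val)!r}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "AutocorrCurve":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        variant = "uniform"
        meta: dict = {}
        if lines and lines[0].startswith("#"):
            for item in lines.pop(0).lstrip("# ").split(", "):
                if "=" in item:
                    k, v = item.split("=", 1)
                    if k == "variant":
                        variant = v
                    else:
                        meta[k] = v
        if lines and lines[0].lower().startswith("lag"):
            lines.pop(0)
        lags, values = [], []
        for ln in lines:
            a, b = ln.split(",")
            lags.append(int(float(a)))
            values.append(float(b))
        return cls(np.array(lags), np.array(values), variant=variant, meta=meta)


@dataclass(frozen=True)
class Theta:
    """The parameter pair fitted by ABC.

    ``D`` is the diffusion coefficient (pixel²/frame); ``a`` is the model's
    amplitude nuisance 2π·gain²·C0²·σ⁴ (a.u.²·pixel²) folding the lumped gain,
    the released-molecule count and the PSF width into one scalar.
    """

    D: float
    a: float

    def __post_init__(self) -> None:
        if not (self.D > 0 and self.a > 0):
            raise ValueError(f"Theta requires D > 0 and a > 0, got D={self.D}, a={self.a}")


def default_max_lag(n_frames: int) -> int:
    """Default fitted lag range: T/4 (at least 1)."""
    return max(1, n_frames // 4)


def _check_lags(max_lag: int, roi: ROISeries, tau_min: int) -> np.ndarray:
    if tau_min < 0:
        raise ValueError("tau_min must be >= 0")
    if max_lag >= roi.n_frames - roi.t0:
        raise ValueError(
            f"max_lag={max_lag} needs frame t0+max_lag={roi.t0 + max_lag}, "
            f"but the series has only {roi.n_frames} frames"
        )
    if max_lag < tau_min:
        raise ValueError("max_lag must be >= tau_min")
    return np.arange(tau_min, max_lag + 1)


def _pair_ks(lag: int, n_ref: int) -> range:
    """Pooled pair offsets for one lag: k in [0, min(n_ref, ceil(τ/2)))."""
    return range(min(n_ref, (int(lag) + 1) // 2))


def _pooled_products(frames: np.ndarray, t0: int, lags: np.ndarray, n_ref: int) -> np.ndarray:
    n_pixels = frames.shape[1] * frames.shape[2]
    values = np.empty(lags.size)
    for j, lag in enumerate(lags):
        if lag == 0:
            values[j] = np.sum(frames[t0] * frames[t0]) / n_pixels
            continue
        acc = 0.0
        ks = _pair_ks(lag, n_ref)
        for k in ks:
            acc += np.sum(frames[t0 + k] * frames[t0 + lag - k])
        values[j] = acc / (len(ks) * n_pixels)
    return values


def empirical_autocorr_uniform(
    roi: ROISeries, max_lag: int, tau_min: int = 1, n_ref: int = DEFAULT_N_REF
) -> AutocorrCurve:
    """Anchored empirical autocorrelation of the raw intensities (uniform background).

    The value at lag τ is the spatial average over the ROI of products of
    frame pairs anchored near the reference frame t0.  Because the model
    expectation of ⟨i(·, t)·i(·, t')⟩ depends on the two times only through
    their sum, every pair (t0+k, t0+τ−k) with 0 ≤ k < min(n_ref, ⌈τ/2⌉)
    estimates the same quantity; pooling them divides the noise variance by
    the pair count without changing the expectation.  ``n_ref=1`` recovers
    the plain single-reference product.  τ = 0 is excluded by default
    because it is dominated by the noise variance.  Deterministic.
    """
    lags = _check_lags(max_lag, roi, tau_min)
    mx, my = roi.roi_dims
    values = _pooled_products(roi.data, roi.t0, lags, n_ref)
    return AutocorrCurve(
        lags, values, variant="uniform",
        meta={"roi_dims": (mx, my), "T": roi.n_frames, "n_ref": n_ref},
    )


def empirical_autocorr_fluctuation(
    roi: ROISeries,
    max_lag: int,
    tau_min: int = 1,
    tail_frames: int = DEFAULT_TAIL_FRAMES,
    n_ref: int = DEFAULT_N_REF,
    debias: bool = True,
) -> AutocorrCurve:
    """Anchored autocorrelation of intensity fluctuations (nonuniform background).

    Fluctuations are δi(x, t) = i(x, t) − b̂(x) with b̂ the per-pixel mean over
    the last ``tail_frames`` frames, which removes any static background or
    static clutter spot exactly.  Frame pairs are pooled exactly as in
    :func:`empirical_autocorr_uniform` (the matching model,
    :func:`model_g2`, averages its correction terms over the same pairs).

    Measurement noise in the baseline adds a constant Var(b̂) = σ_n²/T_b to
    the expectation at every lag; with ``debias=True`` (default) σ_n² is
    estimated from the successive-frame differences of the tail window and
    the constant is removed.  Negative values are kept as-is (no clipping);
    the ABC distance handles signed curves.
    """
    lags = _check_lags(max_lag, roi, tau_min)
    tail = min(int(tail_frames), roi.n_frames)
    if tail < 1:
        raise ValueError("tail_frames must be >= 1")
    tail_data = roi.data[roi.n_frames - tail :]
    baseline = tail_data.mean(axis=0)
    delta = roi.data - baseline
    mx, my = roi.roi_dims
    values = _pooled_products(delta, roi.t0, lags, n_ref)
    noise_var = 0.0
    if debias and tail >= 2:
        # successive tail differences: Var(diff)/2 estimates the noise variance
        noise_var = float(np.var(np.diff(tail_data, axis=0)) / 2.0)
        values = values - noise_var / tail
    return AutocorrCurve(
        lags,
        values,
        variant="fluctuation",
        meta={
            "roi_dims": (mx, my), "T": roi.n_frames, "tail_frames": tail,
            "n_ref": n_ref, "noise_var": noise_var,
        },
    )


# ---------------------------------------------------------------------------
# Closed-form models.  Batched (_g1_values/_g2_values accept array D, a) so the
# ABC sampler can evaluate 1e5 parameter draws in one vectorized pass.
# ---------------------------------------------------------------------------


def _g1_values(D, a, lags, n_pixels, sigma_psf, t_offset):
    """G1 values; D, a broadcast against a trailing lag axis."""
    D = np.atleast_1d(np.asarray(D, dtype=float))[..., None]
    a = np.atleast_1d(np.asarray(a, dtype=float))[..., None]
    lags = np.asarray(lags, dtype=float)
    return a / (n_pixels * (2.0 * sigma_psf**2 + 2.0 * D * (2.0 * t_offset + lags)))


def _g2_values(D, a, lags, n_pixels, T, sigma_psf, t_offset, tail_frames, n_ref=DEFAULT_N_REF):
    """G2 = G1 − ⟨M(t) + M(t')⟩_pairs + V with digamma closed forms for the sums.

    With P(t, s) = pref/(c + t + s), c = σ²/D, pref = a/(N·2D), the cross term
    against the tail baseline is M(t) = (1/T_b)·Σ_{s∈tail} P(t, s) and the
    baseline self-term is V = (1/T_b²)·Σ_{s,s'∈tail} P(s, s'); Σ 1/(c+k) sums
    collapse to digamma differences.  The M-terms are averaged over the same
    pooled frame pairs (t_r+k, t_r+τ−k) the empirical estimator uses.
    """
    if T < 2:
        raise ValueError(f"G2 requires T >= 2, got {T}")
    D = np.atleast_1d(np.asarray(D, dtype=float))[..., None]
    a = np.atleast_1d(np.asarray(a, dtype=float))[..., None]
    lags = np.asarray(lags, dtype=float)
    tb = int(min(tail_frames, T))
    c = sigma_psf**2 / D
    pref = a / (n_pixels * 2.0 * D)
    g1 = pref / (c + 2.0 * t_offset + lags)
    # elapsed times of the tail window: s = j + t_offset, j in [T-tb, T-1]
    s_lo = T - tb + t_offset

    def tail_sum(t):
        # sum over the tail of 1/(c + t + s)
        return _digamma(c + t + s_lo + tb) - _digamma(c + t + s_lo)

    n_pairs = np.minimum(n_ref, (lags.astype(int) + 1) // 2).clip(min=1)
    m_acc = np.zeros(np.broadcast_shapes(D.shape, lags.shape))
    for k in range(int(n_pairs.max())):
        active = k < n_pairs
        pair_m = tail_sum(t_offset + k) + tail_sum(t_offset + lags - k)
        m_acc = m_acc + np.where(active, pair_m, 0.0)
    m_mean = pref / tb * m_acc / n_pairs
    j = np.arange(tb, dtype=float)
    v = pref / tb**2 * np.sum(
        _digamma(c[..., None] + s_lo + j + s_lo + tb) - _digamma(c[..., None] + s_lo + j + s_lo),
        axis=-1,
    )
    return g1 - m_mean + v


def model_g1(
    lags,
    theta: Theta,
    roi_dims: tuple[int, int],
    sigma_psf: float = DEFAULT_SIGMA_PSF,
    t_offset: float = DEFAULT_T_OFFSET,
) -> AutocorrCurve:
    """Uniform-background autocorrelation model (single isolated spot).

    G1(τ) = a / (Mx·My·(2σ² + 2D(2t_r + τ))): strictly decreasing in τ, the
    ROI-size factor 1/(Mx·My) scales the whole curve, and 1/G1 is affine in τ.
    """
    mx, my = roi_dims
    values = _g1_values(theta.D, theta.a, lags, mx * my, sigma_psf, t_offset)[0]
    return AutocorrCurve(
        np.asarray(lags),
        values,
        variant="g1",
        meta={"roi_dims": (mx, my), "sigma_psf": sigma_psf, "t_offset": t_offset},
    )


def model_g2(
    lags,
    theta: Theta,
    roi_dims: tuple[int, int],
    T: int,
    sigma_psf: float = DEFAULT_SIGMA_PSF,
    t_offset: float = DEFAULT_T_OFFSET,
    tail_frames: int = DEFAULT_TAIL_FRAMES,
    n_ref: int = DEFAULT_N_REF,
) -> AutocorrCurve:
    """Fluctuation autocorrelation model (nonuniform/cluttered background).

    Extends G1 with correction terms from the tail-window baseline; the
    corrections carry the total observation time T and decay like 1/T, so
    G2 → G1 as T → ∞.
    """
    mx, my = roi_dims
    values = _g2_values(
        theta.D, theta.a, lags, mx * my, int(T), sigma_psf, t_offset, tail_frames, n_ref
    )[0]
    return AutocorrCurve(
        np.asarray(lags),
        values,
        variant="g2",
        meta={
            "roi_dims": (mx, my),
            "T": int(T),
            "sigma_psf": sigma_psf,
            "t_offset": t_offset,
            "tail_frames": tail_frames,
            "n_ref": n_ref,
        },
    )


def inverse_g1_line(
    theta: Theta,
    roi_dims: tuple[int, int],
    sigma_psf: float = DEFAULT_SIGMA_PSF,
    t_offset: float = DEFAULT_T_OFFSET,
) -> tuple[float, float]:
    """Coefficients (slope, intercept) of the affine function 1/G1(τ).

    1/G1(τ) = N·(2σ² + 4D·t_r)/a + (2·N·D/a)·τ with N = Mx·My.  Useful as a
    fast least-squares diagnostic before running the full ABC fit.
    """
    mx, my = roi_dims
    n = mx * my
    slope = 2.0 * n * theta.D / theta.a
    intercept = n * (2.0 * sigma_psf**2 + 4.0 * theta.D * t_offset) / theta.a
    return slope, intercept
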