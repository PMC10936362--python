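# Methods

## The problem and the model

During the last step of exocytosis a vesicle fuses with the plasma membrane
and releases its fluorescently tagged cargo (e.g. pHluorin-tagged
transferrin receptor), which then diffuses laterally in the membrane.  In a
TIRF time-lapse this appears as a bright, point-like flash that spreads and
fades over a few hundred frames.  The package estimates the local lateral
diffusion coefficient `D` of one such spot from a small ROI around it,
without tracking individual molecules and without assuming the signal is
stationary in time.

The physical model is Fick's second law with all `C0` molecules concentrated
at a point `x0` at the release time, whose free-space solution is the 2D
heat kernel

    C(x, t) = C0 / (4πDt) · exp(−|x − x0|² / (4Dt)).

The microscope convolves this concentration with a point spread function
approximated by an isotropic 2D Gaussian of bandwidth `σ` (peak-normalized),
and the camera scales it by a lumped gain `g` folding collection efficiency,
absorption coefficient and quantum yield.  Since a Gaussian convolved with a
Gaussian is a Gaussian, the noiseless image of the spot at elapsed time `t`
is

    i(x, t) = g·C0·σ²/s²(t) · exp(−|x − x0|²/(2 s²(t))),   s²(t) = σ² + 2Dt,

a profile whose per-axis variance grows affinely in `t` with slope `2D` and
whose spatial integral `g·C0·2πσ²` is constant (mass conservation).  Both
properties are verified against quadrature and numeric-convolution oracles
in the test suite.

## The anchored temporal autocorrelation

Because the spot decays, the intensity process in the ROI is nonstationary
and a stationary (delay-only) autocorrelation is not defined.  The package
anchors the correlation at the reference frame — the first post-release
frame, assigned elapsed time `t_r = 1` frame (configurable `t_offset`; the
offset also avoids the `t = 0` singularity of the heat kernel).  For a lag τ
the basic statistic is the spatial average over the ROI Ω (Mx×My pixels,
N = Mx·My) of the product of two frames:

    Ĝ(τ) = (1/N) Σ_{x∈Ω} i(x, t_r) · i(x, t_r + τ).

For the single-spot model, the plane integral of a product of two Gaussian
profiles centered at the same point depends on the two times only through
s²(t) + s²(t′) = 2σ² + 2D(t + t′), giving the closed form (model **G1**)

    G1(τ; D, a) = a / (N·(2σ² + 2D(2 t_r + τ))),   a = 2π g² C0² σ⁴.

`a` is the single amplitude nuisance (gain, molecule count and PSF width
folded together); `(D, a)` are the two fitted parameters.  Three properties
follow directly and are exploited by the tests:

* `1/G1(τ)` is affine in τ (the linearization diagnostic `inverse_g1_line`);
* the ROI size enters only through the multiplicative factor `1/N`, which is
  why the estimate is insensitive to the window size;
* the curve is strictly decreasing in τ for `D > 0`.

**Pair pooling.**  Since the expectation of `⟨i(·,t) i(·,t′)⟩` depends only
on `t + t′`, every frame pair `(t_r + k, t_r + τ − k)` with
`0 ≤ k < min(n_ref, ⌈τ/2⌉)` estimates the same `G1(τ)`.  The empirical
estimator averages these pairs (default `n_ref = 10`), dividing the noise
variance by the pair count at larger lags without changing the expectation;
`n_ref = 1` recovers the plain single-reference product.  The pooled pairs
keep at least one factor narrow (the earliest frames), so the product
profile remains well inside the ROI at every lag and the infinite-plane
closed form stays exact: on a noise-free render the estimator matches G1 to
~1e−9 relative.

Lag grid: τ = 1 … max_lag in steps of 1 frame, with max_lag = T/4 by default
(τ = 0 is excluded because it is dominated by the noise variance; it can be
enabled via `tau_min=0`).

## Fluctuation autocorrelation and model G2

With a nonuniform background or neighboring spots, the statistic is computed
on fluctuations `δi(x,t) = i(x,t) − b̂(x)`, where `b̂` is the per-pixel mean
over the **last 20 frames** of the series (`tail_frames`).  By the time the
tail is reached the spot of interest has dissipated, so `b̂` captures any
static background or static clutter exactly and removes it; this mirrors
the background-estimation window of the real-data pipeline.  Substituting
the model intensity gives (model **G2**)

    G2(τ; D, a, T) = G1(τ) − ⟨M(t) + M(t′)⟩_pairs + V,

where `M(t) = (1/T_b) Σ_{s∈tail} P(t, s)`, `V = (1/T_b²) Σ_{s,s′∈tail}
P(s, s′)`, and `P(t, s) = a / (N·(2σ² + 2D(t + s)))` is the generic product
term.  The sums collapse to digamma differences, so evaluating G2 for 10⁵
parameter draws is vectorized and cheap.  The correction terms carry the
total observation time `T` and decay like `1/T`: G2 is an
"out-of-equilibrium" finite-record extension of G1, and the two agree
within 1% over the fitted lag range once `T ≈ 5000` frames (tested for
monotone convergence over T = 300 → 4800).

Because the estimated baseline also contains noise, the empirical
fluctuation curve is biased upward by the constant `Var(b̂) = σ_n²/T_b`.
The estimator removes it by default (`debias=True`), estimating `σ_n²` from
successive-difference variances of the tail frames.  Note this makes the
white-noise fluctuation curve fluctuate around zero rather than around the
`σ_n²/20` floor the raw statistic would show.

## ABC rejection estimation

The posterior of `(D, a)` is simulated likelihood-free: draw `N = 100 000`
pairs from independent uniform priors, evaluate the model curve for every
draw (vectorized; draws are independent, so batching cannot change
results), compute the squared-Euclidean distance to the observed curve on
the same lag grid, and keep either the best quantile (default 1%, i.e. the
best 1000 draws — the scale-free version of choosing ε to accept 1–5%) or
all draws within an absolute ε.  A deterministic 0–1 cutoff is used rather
than probabilistic acceptance.  The point estimates are:

* **MMSE** — mean of the accepted `D` samples (the `a` marginal mean is
  reported for diagnostics);
* **MAP** — center of the maximal bin of the accepted-`D` histogram over the
  prior interval, Freedman–Diaconis binning by default (configurable), ties
  resolved toward the lowest `D`.

**Priors.**  `D` is uniform on `[0.01, 2]` px²/frame by default — the
membrane-protein range at typical TIRF sampling (≈0.1 µm pixels, ≈10
frames/s) — and should be narrowed to the biology at hand.  The amplitude
prior is uniform on `(a₀/3, 3·a₀)` around a moment-matched scale `a₀`
obtained by inverting G1 at the first observed lag with the geometric
mid-prior `D`; the first curve value pins the amplitude to within roughly a
factor 2 across the `D` prior, so this span genuinely brackets the truth.
These defaults matter: with the best 1% of draws kept, a much more diffuse
prior (e.g. `D` up to 10 and `a` over four decades) leaves too few draws
near the amplitude–D ridge and the accepted set smears along it, destroying
the estimate.  Both priors are configurable per run.

**Known behaviour.**  With uniform priors and a finite acceptance quantile,
the accepted set is uniform over the acceptance region; its `D`-marginal is
slightly right-skewed because the acceptance band in the amplitude
direction widens as `D` grows.  Under the default conditions this puts
MMSE ≈ +10% above the true `D` on noise-free curves (the MAP mode sits
similarly high, with ±8% sampling jitter from estimating a mode on 1000
samples).  The upward tendency of the MMSE is an expected property of the
method, not a pipeline defect: the oracle-equivalence test shows the
observed curve itself is exact.

## Preprocessing (real-data pipeline)

For a recorded stack and a list of spot centers: crop an odd-sized ROI
(default 31×31; even sizes use a documented half-pixel center convention);
optionally variance-stabilize with the generalized Anscombe transform
`f(x) = (2/g)·√(gx + 3g²/8 + σ_r² − g·m)` (classical Anscombe in the pure
Poisson limit; parameters default to a crude estimate from the darkest 10%
of pixels); estimate the background as the per-pixel temporal **median over
the last 20 frames** and subtract it (no clipping of negatives); detect the
release frame `t0` as the frame of maximal 3×3-smoothed peak intensity (the
peak decays like `1/s²(t)`, making the flash frame sharp; a total-intensity
variant exists but only discriminates when pre-release frames are dark,
since 2D diffusion conserves the ROI total); truncate to `T_fit` frames from
`t0` (defaults 100 for G1, 300 for G2 — the minimum record lengths for
stable curves).

For **simulated** scenes the generator's ground truth is used instead of
detection (`t0` is known), background subtraction is off (the scenes
contain none, and subtracting an estimated background would inject the
spot's own late-time tail into the curve, a measured ~16% bias), and the
full sequence is analyzed (`t_fit = T`).

## Synthetic data generator

`render_analytic` sums closed-form spot profiles (plus an optional constant
+ tilted-plane background) and adds i.i.d. Gaussian noise;
`render_particles` is the independent physical oracle: `n` Brownian walkers
per spot with per-axis steps of variance `2D` per frame, all starting at
`x0`, each imaged as a Gaussian PSF of weight `C0/n`.  The seed-averaged
particle frames converge to the analytic render (law of large numbers),
closing the oracle triangle particle-render ↔ analytic-render ↔ G1.

**SNR definition** (package's own, stated because it fixes the noise
levels): peak noiseless amplitude of the main spot at its first
post-release frame divided by the noise sd.  Study defaults: 61×61 field,
T = 300 frames, `D = 0.5` px²/frame, `σ = 1.3` px, `g·C0 = 160` (peak ≈ 100
a.u.), sweep SNR ∈ {5, 8, 12, 18, 25} — from the usual spot-detection limit
up to bright fusion events.  The six-case scenario battery varies ROI shape
(15×15 … 41×41, one rectangular), spot off-center positions, clutter (one
static + one diffusing neighbor) and SNR.

What the generator does **not** emulate: Poisson shot noise as the primary
noise source (additive Gaussian is used, matching the modeling assumption
after variance stabilization), EMCCD gain-register and fixed-pattern noise,
photobleaching, blinking, axial motion, anomalous or confined diffusion.
Passing tests therefore demonstrate correctness of the method under its own
model class, and robustness to additive noise, window size and spot
position — not performance on arbitrary real data.

## Numerical choices

* Pixel values are point evaluations at pixel centers (PSF ≥ 1 px makes
  pixel-area integration indistinguishable).
* Digamma (`scipy.special.psi`) closed forms for all tail sums in G2.
* Quantile acceptance takes the k smallest distances with a stable sort and
  restores draw order, so results are independent of any batching.
* The histogram MAP uses FD binning clipped to [10, 2000] bins over the
  prior interval; identical samples fall in one bin; ties break to the
  lowest `D`.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical stacks and posteriors.
* Problem sizes in the test suite and acceptance script (e.g. 200 seed
  replicates × 1000 walkers for the oracle triangle, T = 30–300 frames) are
  chosen to keep every check comfortably within a couple of minutes while
  leaving Monte-Carlo error well below the tolerances checked.

## Known limitations

* **PSF width must be approximately known.**  With θ = (D, a) only, the
  model's width offset is `2σ² + 4D·t_r`; given an observed curve,
  `D̂/D = σ_assumed²/σ_true²`.  `σ` is a configuration parameter (default
  1.3 px, matching the generator); a miscalibrated σ biases `D`
  proportionally.
* **Low SNR.**  A single event at T = 300 carries limited information: the
  spread of any curve-based estimate of `D` is roughly ±50%/±30%/±15% at
  SNR 5/8/12.  Below SNR ≈ 8 single-spot estimates should be interpreted as
  posterior distributions, not point values.
* **G2 under noise** shows an additional upward bias of order 20–30% at
  moderate SNR (the noisy baseline couples into every lag); the G1 route is
  preferable whenever the background is removable.
* The anchored estimate leans on the detected `t0`: an off-by-one release
  frame shifts the effective width offset by `2D` and biases `D`
  accordingly.
* Free isotropic 2D diffusion only — no confined/directed motion, no axial
  component, no photobleaching correction.
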