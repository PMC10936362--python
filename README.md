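# bayestics

Local Bayesian estimation of diffusion coefficients of individual
fluorescent spots in time-lapse TIRF microscopy.

When a vesicle fuses with the plasma membrane, its fluorescently tagged
cargo (e.g. pHluorin-tagged transferrin receptor) is released at a point and
diffuses laterally, appearing in a TIRF movie as a bright flash that spreads
and fades.  `bayestics` estimates the local diffusion coefficient `D` of one
such spot from a small ROI, for cell biologists who want per-event, spatially
resolved diffusion maps rather than the single whole-image estimate that
FRAP/FCS-style methods provide.  It needs a single acquisition, no particle
tracking, and no stationarity assumption.

## Method in brief

Fick's law with a point release gives the spot's noiseless image as a
Gaussian of growing variance s²(t) = σ² + 2Dt (PSF bandwidth σ).  The
temporal autocorrelation of the ROI, anchored at the release frame,

    G1(τ; D, a) = a / (MxMy · (2σ² + 2D(2t_r + τ))),      a = 2π g² C0² σ⁴,

is fitted to the empirical curve by ABC rejection sampling: draw 100 000
(D, a) pairs from uniform priors, keep the 1% of draws whose model curves
fall closest (squared-Euclidean distance) to the observation, and report the
posterior of D with its MMSE (posterior mean) and MAP (histogram mode)
estimates.  A second model, G2, correlates mean-subtracted fluctuations and
adds finite-record correction terms that vanish as the sequence grows; it
handles nonuniform backgrounds and cluttered ROIs.  Derivations, parameter
meanings, defaults and limitations: [docs/methods.md](docs/methods.md).

The package also ships the synthetic-scene generator used to validate the
method (analytic renderer + an independent Brownian-walker renderer, SNR
sweeps, a six-case robustness battery), the real-data preprocessing pipeline
(median background over the last 20 frames, automatic release-frame
detection, frame truncation, generalized Anscombe transform), and a CLI.

## Worked example

Simulate a single diffusing spot (true D = 0.5 pixel²/frame, SNR 15, 300
frames) and estimate D back from the TIFF stack:

```sh
bayestics simulate --preset single-spot --snr 15 --t 300 --seed 7 --out demo
printf 'row,col\n30,30\n' > demo/rois.csv

cat > demo/config.yaml <<'YAML'
model: g1
seed: 7
preprocess:
  roi_size: [31, 31]
  background_subtract: false   # synthetic scene has no background
  t_fit: 300
  t0: 0                        # release frame known for simulated data
abc:
  n_samples: 100000
  accept_quantile: 0.01
YAML

bayestics -v estimate --stack demo/single_spot.tif --rois demo/rois.csv \
    --config demo/config.yaml --out demo/results
```

which prints

```
INFO bayestics: ROI (30,30): accepted 1.00% (eps=173), d_map=0.492 d_mmse=0.5341 [0.11s]
processed 1 ROI(s), 0 failed -> demo/results
```

`d_map = 0.492` and `d_mmse = 0.534` are the MAP and MMSE estimates of D in
pixel²/frame (true value 0.5; the MMSE typically sits slightly above the
truth — see the methods note).  `eps=173` is the realized distance cutoff
that accepted the best 1000 of 100 000 draws.  The output directory contains
the per-ROI JSON estimates (with config hash and seed for provenance), the
accepted-sample CSV, the observed autocorrelation curve, and a PNG showing
the observed curve with the best accepted model curves next to the posterior
histogram of D.  Multiply D by pixel_size²·frame_rate to convert to µm²/s
(`bayestics.d_to_um2_per_s`).

`bayestics simulate --preset snr-sweep` and `--preset scenario-suite` write
the noise-robustness and six-case robustness batteries with JSON ground
truth; `bayestics batch` aggregates many ROIs/stacks into one CSV.

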