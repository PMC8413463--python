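# Methods

## The problem and the model

`woodxrf` implements species identification of wood from energy-dispersive
X-ray fluorescence (XRF) spectra with a one-dimensional convolutional neural
network. A handheld XRF unit excites a wood surface at 50 kV and records,
per 20 s scan, counts in ~2048 detector channels whose index maps linearly
to photon energy. Wood is almost entirely C/H/O/N — which XRF barely sees —
so the taxon signal lives in faint characteristic lines of ash elements
(Na, Mg, Al, Si, P, S, K, Ca, Fe) superimposed on a bremsstrahlung continuum
whose shape tracks bulk density.

The pipeline follows the order acquisition → normalization → compression →
classification:

1. **Total-count normalization.** Each channel becomes a fraction of the
   spectrum's integrated counts, removing per-scan intensity variation
   (source drift, coupling distance). The denominator is the full detector
   range by default; an in-window variant is available as a config switch.
2. **Compression onto a fixed grid.** The normalized spectrum is summed
   into 100 eV bins over 0.7–37 keV — 363 bins, half-open `[e, e+0.1)` with
   a right-closed final bin so the window is exactly partitioned. Channels
   are assigned whole to the bin containing their center energy: counts are
   integers per channel, and splitting them would manufacture sub-channel
   information. Summing (not averaging) conserves in-window fractional mass
   exactly.
3. **Classification.** Three blocks of `conv1d → batch norm → ReLU →
   max-pool(2)` with 32/64/128 filters and kernels 5/3/2, flattened into
   dense layers of 512/256/128/64 units with ReLU and 60% dropout, then a
   softmax over the species vocabulary. Training: Nadam, learning rate
   1e-5, batch size 4, categorical crossentropy, a fixed epoch budget with
   no early stopping, last-epoch weights kept (a best-validation checkpoint
   exists but defaults off). 15% of rows are randomly masked for
   validation.

## The numpy network engine

The classifier is implemented directly in numpy (`woodxrf.nn`):
convolutions are lowered to BLAS matrix products via sliding-window views,
batch normalization uses batch statistics in training and exponential
running averages (momentum 0.99, eps 1e-3) at inference, dropout is
inverted (scaled at train time, identity at inference), and the Nadam
update runs as a single fused numba pass over each parameter array.
Gradients are verified against central finite differences in the test
suite. Everything is float32 and fully seeded — weight init, shuffling and
dropout masks derive from explicit generators — so a fixed seed reproduces
a run bit for bit, and save→load round-trips predictions exactly.

Design choices the architecture description leaves open, and what this
package does:

- batch norm after every convolution, before the ReLU;
- pool size 2, stride 1 convolutions, valid padding;
- dropout after each dense activation only (not between conv blocks);
- Glorot-uniform weight initialisation. This matters: with four stacked
  60% dropout layers and batch size 4, larger (He-scaled) dense weights
  saturate the train-mode logits early and destabilise the validation
  trajectory; Glorot matches the convention of the mainstream frameworks
  this architecture comes from.
- Retraining a loaded model continues its history but starts a fresh
  optimizer state.

## Splitting

`per_spectrum` (default) masks `ceil(0.15 n)` scans uniformly — replicate
scans of one physical wood blank then appear on both sides of the split, so
validation measures scan-level generalisation, not sample-level.
`per_sample` assigns whole sample groups to validation until the fraction
is met and exists precisely because replicate leakage motivates group-wise
validation; the training log states which strategy ran. Class imbalance is
reported, never reweighted.

## Evaluation

From the confusion matrix (rows true, columns predicted): per-class
one-vs-rest sensitivity TP/(TP+FN) and specificity TN/(TN+FP), unweighted
(macro) means over classes, accuracy = trace/total. Classes with no true
instances are excluded from macro means with a logged warning. A
majority-collapse predictor on balanced K-class data scores macro
specificity (K−1)/K·100 exactly — the closed form behind a deceptively high
specificity of a degenerate model.

"Optimization precision" has no universally agreed formula; three
definitions are selectable and the report always prints the one used:
`optimized_precision` (default): Acc − |Sp−Sn|/(Sp+Sn)·100; `youden`:
Sn + Sp − 100; `per_class_youden`: macro mean of Sn_k − (100 − Sp_k).

## Feature importance

Permutation importance (default): for each bin (or window of bins), the
values are shuffled jointly across spectra, the mean categorical
crossentropy is recomputed, and importance is the mean loss increase over
`n_permutations` repeats; occlusion (zeroing the window) is the
deterministic alternative. Importance is evaluated on the validation split
— training-split importance conflates memorization. Profiles are reported
against keV bin starts so localized structure (e.g. everything informative
below 2 keV) is directly visible. Whether such a profile derives from
training or validation data is a free choice in general; validation is this
package's default.

## Randomized-label control

`run_control` trains the identical architecture twice: on the true labels
and on labels drawn independently from a K-word vocabulary (default K=29;
weights uniform, explicit, or drawn from a flat Dirichlet — the uneven case
reproduces the majority-collapse behaviour of a control whose best move is
predicting the most frequent word). The verdict is `pass` iff the control's
validation accuracy is within 5 points of the majority-label frequency
*and* the reference beats the control by ≥30 points; both thresholds are
repository policy, stated in the report. A `leak_validation` switch
deliberately includes validation rows in control training — the planted bug
the detector must catch — and a reference stuck at its own chance level
yields a "no signal" diagnostic.

## The synthetic-data generator

No instrument spectra ship with the package; the simulator provides labeled
data with controllable class structure:

- **Continuum**: Kramers-type `E_max/E − 1`, zero at and above the 50 kV
  excitation, multiplied by a logistic detector-efficiency roll-off
  centered at 1 keV (width 0.15 keV), scaled by a per-species density
  factor. Any smooth, density-scalable shape would serve; this one is a
  config choice.
- **Lines**: Gaussian K-series peaks at standard reference energies
  (packaged in `data/xray_lines.csv`), width σ²(E) = σ_noise² + k·E
  calibrated to a 140 eV FWHM at 5.9 keV with a 100 eV electronic-noise
  floor — typical silicon-drift-detector resolution. Element signal shares
  split over Kα/Kβ by relative intensity; line areas are integrated exactly
  over channel edges (Gaussian CDF differences).
- **Noise**: channel-wise Poisson around the expectation, which is itself
  scaled to `mean_total_counts` (default 5×10⁵ per 20 s scan — a free
  parameter, chosen as a plausible handheld count rate; no instrument value
  was available).
- **Replication**: a plan of species × samples-per-species × scans-per-
  sample (default 260 scans, matching a raster-scanned blank); physical
  samples are drawn by jittering species weights (relative s.d.
  `profile_jitter`). Seeds spawn per (species, sample, scan), so subsets
  reproduce independently of iteration order.

Two panels matter for testing. The **planted-window panel** builds species
that differ *only* in emission lines inside a chosen energy window: all
species share the continuum and out-of-window weights, and a fixed total
in-window signal share (0.12) is distributed with near-orthogonal patterns
— each species concentrates 70% of it on its own *feature-grid bin group*.
Grouping by bin is essential: Na Kα and Na Kβ fall in the same 100 eV bin,
so patterns orthogonal over raw lines need not be orthogonal after
binning. Keeping the in-window total fixed makes expected spectra agree
outside the window up to sub-permille Gaussian tail leakage; a line landing
in the bin that starts at the window's upper edge counts as outside
(half-open rule). The **null panel** gives every species the identical
profile, so any classifier can only reach chance accuracy.

What the simulator does *not* emulate: escape peaks, pile-up, matrix
effects, secondary fluorescence, sum peaks, detector nonlinearity, surface
moisture or grain-orientation effects. Passing tests therefore demonstrate
that the pipeline recovers class structure of the planted kind and that its
controls behave; they say nothing about the discriminability of real wood
taxa.

## Problem sizes and numerical choices

The end-to-end checks run a deliberately scaled protocol: 5 species × 2
samples × 60 scans (600 spectra), the full 363-bin grid and full
architecture (~3.0 M parameters), 100 epochs. On these conditions the
reference model reaches and holds 100% validation accuracy well before
epoch 100, the uniform-random-label control stays at the 29-class chance
level, and ≥80% of positive permutation-importance mass falls inside the
planted 0.7–1.7 keV window. Degenerate inputs fail loudly: zero-count
spectra raise rather than emit NaNs, non-uniform energy grids are
calibration errors, and a grid that cannot survive three pooling stages is
an architecture error. The Nadam update flushes moment entries below
1e-30 to zero: dropout leaves many gradients exactly zero, the first
moment then decays geometrically into the float32 subnormal range, and
denormal arithmetic would otherwise dominate the epoch time. BLAS thread pools are capped at one thread in the
test and acceptance entry points; on single-CPU cgroups an auto-sized pool
oversubscribes the core.

## Known limitations

- The engine is CPU-only and optimised for this architecture's shapes;
  it is not a general deep-learning framework.
- `per_spectrum` validation — the default, kept for protocol fidelity —
  overstates accuracy relative to `per_sample` whenever replicate scans
  dominate; use `per_sample` for sample-level claims.
- Bit-exact reproducibility holds for a fixed BLAS/numba build; across
  different builds, results agree only to float32 round-off.
- The synthetic acquisition model is statistical, not metrological; its
  defaults (2048 channels, 20 eV/channel) are conventions, not measured
  instrument values.
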