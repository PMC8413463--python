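# woodxrf

Wood-species identification from energy-dispersive X-ray fluorescence
(XRF) spectra with a one-dimensional convolutional neural network.

Identifying the species of a piece of timber — a routine need in enforcing
logging regulations and in conservation work — usually requires anatomical
expertise or destructive sampling. Handheld XRF offers a non-invasive
alternative: although wood is mostly C/H/O/N, its faint ash-element lines
(Na, Mg, Al, Si, P, S, K, Ca, Fe) and the density-dependent scatter
continuum carry enough taxon signal for a classifier to exploit. `woodxrf`
is a complete, tested pipeline for that approach: per-scan spectrum
ingestion, total-count normalization, compression onto a fixed 0.7–37 keV
grid in 100 eV bins (363 inputs), a 1D CNN classifier, a confusion-matrix
metric suite, energy-resolved feature importance, and a randomized-label
control that distinguishes signal learning from memorization. A built-in
forward simulator (characteristic lines + bremsstrahlung + Poisson noise)
generates labeled spectra so every stage is testable without instrument
data.

## The model

Each scan `x` (integer counts per detector channel) is normalized to
fractions `x / Σx` and summed into half-open 100 eV bins over 0.7–37 keV.
The classifier is

```
3 × [conv1d(f, k) → batch norm → ReLU → max-pool(2)]   f = 32, 64, 128; k = 5, 3, 2
  → flatten
  → 4 × [dense(u) → ReLU → dropout(0.6)]               u = 512, 256, 128, 64
  → dense(K) → softmax
```

trained with Nadam (lr 1e-5), batch size 4, categorical crossentropy, a
fixed epoch budget, and a random 15% validation mask. Metrics are reported
per class (one-vs-rest sensitivity TP/(TP+FN), specificity TN/(TN+FP)) and
as unweighted macro means; feature importance is the increase in mean
crossentropy when an energy bin is permuted across spectra. The network is
implemented in numpy (BLAS-backed convolutions, a numba-fused Nadam
update); it trains this architecture on one CPU core in minutes and is
bit-for-bit reproducible under a fixed seed.

## Worked example

```python
import woodxrf as wx

# five synthetic species that differ only in 0.7-1.7 keV emission lines
panel = wx.make_planted_window_panel(5, window=(0.7, 1.7), seed=1)
plan = wx.SimulationPlan(species=panel, samples_per_species=2,
                         scans_per_sample=60, seed=1)
spectra, manifest = wx.simulate_dataset(plan, wx.AcquisitionModel())
dataset = wx.preprocess_dataset(spectra)          # 600 x 363 fractions

cfg = wx.CNNConfig(epochs=100, seed=1)
train_set, val_set = wx.split(dataset, cfg.val_fraction,
                              cfg.split_strategy, cfg.seed)
clf = wx.build(cfg, dataset.grid.n_bins, dataset.n_classes,
               grid=dataset.grid, vocabulary=dataset.vocabulary)
clf, hist = wx.train(clf, train_set, val_set, cfg)
cm, report = wx.evaluate(clf, val_set)
print(report.summary())

profile = wx.permutation_importance(clf, val_set, n_permutations=2, seed=1)
print(f"importance mass in 0.7-1.7 keV: "
      f"{100 * profile.positive_mass_fraction((0.7, 1.7)):.1f}%")
```

prints

```
n=90  accuracy=100.0%  mean sensitivity=100.0%  mean specificity=100.0%  optimization precision=100.0% [accuracy - |Sp - Sn| / (Sp + Sn) * 100]
importance mass in 0.7-1.7 keV: 99.9%
```

The 90 masked validation scans are all recovered (the five species'
expected spectra are well separated), and essentially all permutation
importance falls inside the window where the species actually differ — the
classifier found the signal where it was planted, not in the shared
continuum.

The same pipeline is available as shell commands
(`woodxrf simulate | preprocess | train | evaluate | importance | control |
window-ablate`), each driven by one YAML config and stamping its output
directory with the echoed config, seed, and software versions.

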