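"""Raw spectra -> fixed-length normalized feature vectors.

The pipeline order follows the acquisition-to-features convention of the
classifier: each spectrum is first normalized to total counts (every channel
becomes a fraction of the integrated signal) and then compressed onto a fixed
energy grid, by default 0.7–37 keV in 100 eV increments (363 bins).  Channels
are assigned to bins by their center energy with half-open bins
``[e, e + width)``; the last bin is right-closed so the grid exactly
partitions the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, CoverageError, DegenerateSpectrumError
from .spectra_io import EnergyCalibration, RawSpectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureGrid:
    """Uniform energy grid for the classifier input (energies in keV)."""

    e_min_kev: float = 0.7
    e_max_kev: float = 37.0
    bin_width_kev: float = 0.1

    def __post_init__(self):
        if self.e_min_kev >= self.e_max_kev:
            raise ConfigurationError("e_min must be below e_max")
        if self.bin_width_kev <= 0:
            raise ConfigurationError("bin width must be positive")
        n = (self.e_max_kev - self.e_min_kev) / self.bin_width_kev
        if abs(n - round(n)) > 1e-6:
            raise ConfigurationError(
                f"bin width {self.bin_width_kev} does not evenly divide "
                f"[{self.e_min_kev}, {self.e_max_kev}]"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.e_max_kev - self.e_min_kev) / self.bin_width_kev))

    def bin_starts_kev(self) -> np.ndarray:
        return self.e_min_kev + self.bin_width_kev * np.arange(self.n_bins)

    def bin_index(self, energy_kev: np.ndarray) -> np.ndarray:
        """Half-open bin assignment; energies exactly at e_max fall in the
        last bin (right-closed); energies outside the window get -1."""
        e = np.asarray(energy_kev, dtype=float)
        idx = np.floor((e - self.e_min_kev) / self.bin_width_kev).astype(int)
        idx[np.isclose(e, self.e_max_kev)] = self.n_bins - 1
        idx[(e < self.e_min_kev) | (e > self.e_max_kev)] = -1
        idx[idx >= self.n_bins] = -1
        return idx

    def to_dict(self) -> dict:
        return {
            "e_min_kev": self.e_min_kev,
            "e_max_kev": self.e_max_kev,
            "bin_width_kev": self.bin_width_kev,
        }


#: The default grid: 0.7–37 keV in 100 eV steps, 363 input bins.
DEFAULT_GRID = FeatureGrid()


@dataclass(frozen=True)
class FeatureVector:
    """Normalized, rebinned spectrum plus provenance metadata."""

    values: np.ndarray
    grid: FeatureGrid
    sample_id: str = ""
    species: str = ""
    orientation: str = "unknown"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if len(values) != self.grid.n_bins:
            raise ConfigurationError(
                f"{len(values)} values but grid has {self.grid.n_bins} bins"
            )
        if np.any(values < 0):
            raise ValueError("feature values must be non-negative")
        if values.sum() > 1 + 1e-9:
            raise ValueError("feature values cannot sum to more than 1")
        object.__setattr__(self, "values", values)


@dataclass
class LabeledDataset:
    """Feature matrix with aligned species labels and sample-group ids."""

    features: np.ndarray  # (n_scans, n_bins)
    labels: np.ndarray  # species per row
    groups: np.ndarray  # sample_id per row
    grid: FeatureGrid
    vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        n = len(self.features)
        if not (len(self.labels) == len(self.groups) == n):
            raise ConfigurationError("features, labels, groups must align")
        if self.features.ndim != 2 or self.features.shape[1] != self.grid.n_bins:
            raise ConfigurationError(
                f"feature matrix width {self.features.shape} does not match "
                f"grid ({self.grid.n_bins} bins)"
            )
        if not self.vocabulary:
            self.vocabulary = sorted(set(self.labels.tolist()))
        unknown = set(self.labels.tolist()) - set(self.vocabulary)
        if unknown:
            raise ConfigurationError(f"labels outside vocabulary: {sorted(unknown)}")

    def __len__(self):
        return len(self.features)

    @property
    def n_classes(self) -> int:
        return len(self.vocabulary)

    def label_indices(self) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.vocabulary)}
        return np.array([lut[lab] for lab in self.labels.tolist()])

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            features=self.features[rows],
            labels=self.labels[rows],
            groups=self.groups[rows],
            grid=self.grid,
            vocabulary=list(self.vocabulary),
        )


def normalize_total_counts(spectrum: RawSpectrum) -> np.ndarray:
    """Convert channel counts to fractions of the integrated signal.

    Every channel becomes a percentage of the total rather than raw counts;
    the output sums to 1 exactly (integer-count ratio).
    """
    total = spectrum.total_counts
    if total <= 0:
        raise DegenerateSpectrumError(
            f"spectrum {spectrum.sample_id or '<unnamed>'} has zero total counts"
        )
    return spectrum.counts / float(total)


def rebin(fractions: np.ndarray, calibration: EnergyCalibration,
          grid: FeatureGrid = DEFAULT_GRID) -> np.ndarray:
    """Compress per-channel fractions onto the feature grid by summation.

    Each channel's whole fraction is assigned to the bin containing its
    center energy (no sub-channel splitting), so in-window mass is conserved
    exactly.  Mass outside the window is dropped; a spectrum with no
    in-window mass yields an all-zero vector and a logged warning.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != calibration.n_channels:
        raise ConfigurationError("fraction vector does not match calibration")
    energies = calibration.channel_energies_kev()
    if energies[-1] < grid.e_min_kev or energies[0] > grid.e_max_kev:
        raise CoverageError(
            f"detector range {energies[0]:.3f}-{energies[-1]:.3f} keV does not "
            f"overlap grid window {grid.e_min_kev}-{grid.e_max_kev} keV"
        )
    idx = grid.bin_index(energies)
    inside = idx >= 0
    out = np.zeros(grid.n_bins)
    np.add.at(out, idx[inside], fractions[inside])
    if out.sum() == 0 and fractions.sum() > 0:
        logger.warning("all spectral mass lies outside the %s-%s keV window",
                       grid.e_min_kev, grid.e_max_kev)
    return out


def featurize(spectrum: RawSpectrum, grid: FeatureGrid = DEFAULT_GRID,
              normalization: str = "total_full_range") -> FeatureVector:
    """Normalize then rebin one spectrum.

    ``normalization`` chooses the denominator: ``total_full_range`` (default)
    divides by counts over all detector channels; ``total_in_window`` divides
    by in-window counts only, making the output sum to exactly 1.
    """
    if normalization not in ("total_full_range", "total_in_window"):
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    fractions = normalize_total_counts(spectrum)
    values = rebin(fractions, spectrum.calibration, grid)
    if normalization == "total_in_window":
        mass = values.sum()
        if mass <= 0:
            raise DegenerateSpectrumError(
                f"spectrum {spectrum.sample_id or '<unnamed>'} has no counts "
                "inside the grid window"
            )
        values = values / mass
    return FeatureVector(
        values=values,
        grid=grid,
        sample_id=spectrum.sample_id,
        species=spectrum.species,
        orientation=spectrum.orientation,
    )


def preprocess_dataset(spectra: list[RawSpectrum], grid: FeatureGrid = DEFAULT_GRID,
                       normalization: str = "total_full_range") -> LabeledDataset:
    """Featurize a collection of spectra into an aligned labeled dataset.

    Row order follows input (manifest) order.  A degenerate spectrum aborts
    the run with a message naming the offending scan.
    """
    if not spectra:
        raise ConfigurationError("cannot preprocess an empty collection")
    rows, labels, groups = [], [], []
    for i, spec in enumerate(spectra):
        try:
            fv = featurize(spec, grid, normalization)
        except DegenerateSpectrumError as exc:
            raise DegenerateSpectrumError(
                f"scan {i} (sample_id={spec.sample_id!r}): {exc}"
            ) from exc
        rows.append(fv.values)
        labels.append(spec.species)
        groups.append(spec.sample_id)
    return LabeledDataset(
        features=np.array(rows), labels=np.array(labels), groups=np.array(groups),
        grid=grid,
    )


def save_features(dataset: LabeledDataset, features_path, labels_path) -> None:
    """Persist the feature matrix as a dense table plus a sidecar label file."""
    import pandas as pd

    cols = [f"{e:.1f}" for e in dataset.grid.bin_starts_kev()]
    pd.DataFrame(dataset.features, columns=cols).to_csv(features_path, index=False)
    pd.DataFrame({"species": dataset.labels, "sample_id": dataset.groups}).to_csv(
        labels_path, index=False
    )


def load_features(features_path, labels_path, grid: FeatureGrid = DEFAULT_GRID) -> LabeledDataset:
    import pandas as pd

    feats = pd.read_csv(features_path)
    labels = pd.read_csv(labels_path, dtype=str).fillna("")
    if feats.shape[1] != grid.n_bins:
        raise ConfigurationError(
            f"feature table has {feats.shape[1]} columns, grid expects {grid.n_bins}"
        )
    return LabeledDataset(
        features=feats.to_numpy(),
        labels=labels["species"].to_numpy(),
        groups=labels["sample_id"].to_numpy(),
        grid=grid,
    )
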