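"""Shared fixtures: tiny grids, in-memory datasets, and small simulators.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk except what the tests themselves write to tmp_path.
"""

import os

# one BLAS thread: on a single-CPU cgroup OpenBLAS may otherwise spawn one
# thread per host core and oversubscribe the core (set before numpy loads)
for _var in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

import woodxrf as wx
from woodxrf.preprocess import FeatureGrid, LabeledDataset


@pytest.fixture(scope="session")
def line_library():
    return wx.load_line_library()


@pytest.fixture(scope="session")
def tiny_grid():
    """A 40-bin grid that still survives the three conv/pool stages."""
    return FeatureGrid(0.7, 4.7, 0.1)


@pytest.fixture(scope="session")
def tiny_config():
    """A scaled-down architecture for fast unit tests of the training loop."""
    return wx.CNNConfig(
        conv_filters=(4, 4, 4),
        conv_kernels=(5, 3, 2),
        dense_units=(16, 8),
        dropout_rate=0.2,
        epochs=60,
        batch_size=8,
        learning_rate=3e-4,
        seed=11,
    )


def make_blob_dataset(grid, n_classes=3, groups_per_class=2, rows_per_group=15,
                      separation=0.5, seed=5):
    """Simplex-valued feature rows with class-specific mean patterns.

    Cheap stand-in for full spectral simulation in unit tests of the model,
    evaluation and control layers.
    """
    rng = np.random.default_rng(seed)
    n_bins = grid.n_bins
    base = rng.dirichlet(np.ones(n_bins) * 5)
    rows, labels, group_ids = [], [], []
    for c in range(n_classes):
        bump = np.zeros(n_bins)
        bump[rng.choice(n_bins, size=3, replace=False)] = separation / 3
        mean = (1 - separation) * base + bump
        for g in range(groups_per_class):
            for _ in range(rows_per_group):
                noisy = np.clip(mean + rng.normal(0, 0.002, n_bins), 0, None)
                rows.append(noisy / noisy.sum())
                labels.append(f"sp{c}")
                group_ids.append(f"sp{c}-g{g}")
    return LabeledDataset(
        features=np.array(rows), labels=np.array(labels),
        groups=np.array(group_ids), grid=grid,
    )


@pytest.fixture(scope="session")
def blob_dataset(tiny_grid):
    return make_blob_dataset(tiny_grid)


@pytest.fixture(scope="session")
def trained_tiny(blob_dataset, tiny_config):
    """A quickly trained small model on separable blob data, shared across
    inference/evaluation/importance tests."""
    tr, va = wx.split(blob_dataset, tiny_config.val_fraction,
                      tiny_config.split_strategy, tiny_config.seed)
    clf = wx.build(tiny_config, blob_dataset.grid.n_bins, blob_dataset.n_classes,
                   grid=blob_dataset.grid, vocabulary=blob_dataset.vocabulary)
    clf, hist = wx.train(clf, tr, va, tiny_config)
    return clf, tr, va, hist


@pytest.fixture(scope="session")
def small_acq():
    """Acquisition model with a short detector for fast simulator tests."""
    return wx.AcquisitionModel(
        mean_total_counts=1e5,
        calibration=wx.EnergyCalibration(gain_ev=20.0, offset_ev=0.0, n_channels=1024),
    )
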