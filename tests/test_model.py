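"""Split protocol, architecture assembly, training loop, and persistence."""

import numpy as np
import pytest

import woodxrf as wx
from woodxrf.errors import (
    ArchitectureError,
    ConfigurationError,
    GridMismatchError,
    IntegrityError,
    StratificationError,
)
from conftest import make_blob_dataset


class TestSplit:
    def test_per_spectrum_counts_and_disjointness(self, blob_dataset):
        n = len(blob_dataset)
        tr, va = wx.split(blob_dataset, 0.15, "per_spectrum", seed=0)
        assert len(va) == int(np.ceil(0.15 * n))
        assert len(tr) + len(va) == n

    def test_same_seed_reproduces_partition(self, blob_dataset):
        tr1, va1 = wx.split(blob_dataset, 0.15, "per_spectrum", seed=9)
        tr2, va2 = wx.split(blob_dataset, 0.15, "per_spectrum", seed=9)
        np.testing.assert_array_equal(va1.features, va2.features)
        tr3, va3 = wx.split(blob_dataset, 0.15, "per_spectrum", seed=10)
        assert not np.array_equal(va1.features, va3.features)

    def test_per_sample_keeps_groups_whole(self, blob_dataset):
        tr, va = wx.split(blob_dataset, 0.15, "per_sample", seed=1)
        assert set(tr.groups.tolist()).isdisjoint(set(va.groups.tolist()))
        assert len(tr) + len(va) == len(blob_dataset)

    def test_per_sample_six_equal_groups_takes_exactly_one(self, tiny_grid):
        ds = make_blob_dataset(tiny_grid, n_classes=3, groups_per_class=2,
                               rows_per_group=20, seed=8)
        tr, va = wx.split(ds, 0.15, "per_sample", seed=3)
        # 6 equal groups of 20: one group (16.7%) is the smallest superset of 15%
        assert len(set(va.groups.tolist())) == 1
        assert len(va) == 20

    def test_too_few_rows_per_class_is_a_stratification_error(self, tiny_grid):
        ds = make_blob_dataset(tiny_grid, n_classes=2, groups_per_class=1,
                               rows_per_group=1)
        with pytest.raises(StratificationError, match="sp0"):
            wx.split(ds, 0.15, "per_spectrum", seed=0)
        with pytest.raises(StratificationError):
            wx.split(ds, 0.15, "per_sample", seed=0)


class TestBuild:
    def test_output_rows_lie_on_simplex(self, tiny_config, tiny_grid):
        clf = wx.build(tiny_config, tiny_grid.n_bins, 5, grid=tiny_grid)
        rng = np.random.default_rng(0)
        p = clf.predict_proba(rng.random((7, tiny_grid.n_bins)))
        assert p.shape == (7, 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_builds_identical_weights(self, tiny_config, tiny_grid):
        a = wx.build(tiny_config, tiny_grid.n_bins, 3, grid=tiny_grid)
        b = wx.build(tiny_config, tiny_grid.n_bins, 3, grid=tiny_grid)
        for (ka, va_), (kb, vb) in zip(sorted(a.net.state_arrays().items()),
                                       sorted(b.net.state_arrays().items())):
            assert ka == kb
            np.testing.assert_array_equal(va_, vb)

    def test_too_few_bins_for_pooling_depth_raises(self, tiny_config):
        with pytest.raises(ArchitectureError):
            wx.build(tiny_config, 4, 3)

    def test_parameter_count_is_deterministic_function_of_shapes(self, tiny_config,
                                                                 tiny_grid):
        clf = wx.build(tiny_config, tiny_grid.n_bins, 3, grid=tiny_grid)
        # conv chain: 40 ->(k5) 36 ->pool 18 ->(k3) 16 ->pool 8 ->(k2) 7 ->pool 3
        conv = (5 * 1 * 4 + 4) + (3 * 4 * 4 + 4) + (2 * 4 * 4 + 4)
        bnorm = 3 * (2 * 4)
        flat = 3 * 4
        dense = (flat * 16 + 16) + (16 * 8 + 8)
        out = 8 * 3 + 3
        assert clf.n_parameters == conv + bnorm + dense + out

    def test_full_architecture_parameter_count_reported(self):
        cfg = wx.CNNConfig()
        clf = wx.build(cfg, 363, 48)
        assert clf.n_parameters > 2_000_000  # flattened 43x128 into 512 dominates
        p = clf.predict_proba(np.random.default_rng(1).random((2, 363)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestTrain:
    def test_history_length_equals_epochs_and_appends_on_retrain(
            self, blob_dataset, tiny_config):
        tr, va = wx.split(blob_dataset, 0.15, "per_spectrum", tiny_config.seed)
        clf = wx.build(tiny_config, blob_dataset.grid.n_bins,
                       blob_dataset.n_classes, grid=blob_dataset.grid,
                       vocabulary=blob_dataset.vocabulary)
        import dataclasses

        one = dataclasses.replace(tiny_config, epochs=1)
        clf, hist = wx.train(clf, tr, va, one)
        assert len(hist) == 1
        clf, hist = wx.train(clf, tr, va, dataclasses.replace(tiny_config, epochs=2))
        assert len(hist) == 3  # retraining appends
        assert all(0 <= a <= 100 for a in hist.val_accuracy)

    def test_training_learns_separable_blobs(self, trained_tiny):
        clf, tr, va, hist = trained_tiny
        assert hist.val_accuracy[-1] >= 80.0

    def test_same_seed_training_is_reproducible(self, blob_dataset, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, epochs=2)
        accs = []
        for _ in range(2):
            tr, va = wx.split(blob_dataset, 0.15, "per_spectrum", cfg.seed)
            clf = wx.build(cfg, blob_dataset.grid.n_bins, blob_dataset.n_classes,
                           grid=blob_dataset.grid, vocabulary=blob_dataset.vocabulary)
            clf, hist = wx.train(clf, tr, va, cfg)
            accs.append(hist.val_accuracy[-1])
        assert abs(accs[0] - accs[1]) <= 0.5

    def test_grid_mismatch_rejected(self, blob_dataset, tiny_config, tiny_grid):
        other = wx.FeatureGrid(0.7, 2.7, 0.1)
        ds = make_blob_dataset(other, n_classes=2)
        clf = wx.build(tiny_config, tiny_grid.n_bins, 2, grid=tiny_grid)
        with pytest.raises(GridMismatchError):
            wx.train(clf, ds, ds, tiny_config)
        with pytest.raises(GridMismatchError):
            clf.predict_proba(np.zeros((1, other.n_bins)))


class TestPredict:
    def test_batch_order_and_duplicate_rows(self, trained_tiny):
        clf, tr, va, _ = trained_tiny
        x = va.features[:5]
        p = clf.predict_proba(x)
        assert p.shape == (5, 3)
        p2 = clf.predict_proba(np.vstack([x, x[0:1]]))
        np.testing.assert_array_equal(p2[-1], p2[0])
        np.testing.assert_array_equal(p, p2[:5])


class TestPersistence:
    def test_save_load_predictions_bit_identical(self, trained_tiny, tmp_path):
        clf, tr, va, _ = trained_tiny
        wx.save(clf, tmp_path / "m")
        back = wx.load(tmp_path / "m")
        probe = va.features[:8]
        np.testing.assert_array_equal(clf.predict_proba(probe),
                                      back.predict_proba(probe))
        assert back.vocabulary == clf.vocabulary
        assert back.grid == clf.grid
        assert len(back.history) == len(clf.history)

    def test_missing_sidecar_is_an_integrity_error(self, trained_tiny, tmp_path):
        clf, *_ = trained_tiny
        wx.save(clf, tmp_path / "m")
        (tmp_path / "m" / "model.json").unlink()
        with pytest.raises(IntegrityError):
            wx.load(tmp_path / "m")

    def test_loaded_model_can_be_retrained(self, trained_tiny, tmp_path,
                                           blob_dataset, tiny_config):
        import dataclasses

        clf, tr, va, _ = trained_tiny
        wx.save(clf, tmp_path / "m")
        back = wx.load(tmp_path / "m")
        n0 = len(back.history)
        back, hist = wx.train(back, tr, va, dataclasses.replace(tiny_config, epochs=2))
        assert len(hist) == n0 + 2


def test_config_invariants_enforced():
    with pytest.raises(ConfigurationError):
        wx.CNNConfig(conv_filters=(32, 64), conv_kernels=(5, 3, 2))
    with pytest.raises(ConfigurationError):
        wx.CNNConfig(dropout_rate=1.0)
    with pytest.raises(ConfigurationError):
        wx.CNNConfig(val_fraction=0.0)
    with pytest.raises(ConfigurationError):
        wx.CNNConfig(epochs=0)
    with pytest.raises(ConfigurationError):
        wx.CNNConfig(split_strategy="bogus")
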