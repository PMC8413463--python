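"""Normalization and rebinning contracts, with a brute-force rebin oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import woodxrf as wx
from woodxrf.errors import ConfigurationError, CoverageError, DegenerateSpectrumError
from woodxrf.preprocess import DEFAULT_GRID, FeatureGrid


def _spectrum(counts, gain_ev=20.0, offset_ev=0.0):
    return wx.RawSpectrum(
        counts=np.asarray(counts),
        calibration=wx.EnergyCalibration(gain_ev=gain_ev, offset_ev=offset_ev,
                                         n_channels=len(counts)),
    )


def brute_force_rebin(fractions, calibration, grid):
    """Independent oracle: assign each channel's fraction to the half-open
    bin containing its center energy, channel by channel."""
    out = np.zeros(grid.n_bins)
    for ch, frac in enumerate(fractions):
        e = (calibration.offset_ev + calibration.gain_ev * ch) / 1000.0
        if e < grid.e_min_kev or e > grid.e_max_kev:
            continue
        b = int(np.floor((e - grid.e_min_kev) / grid.bin_width_kev))
        if b == grid.n_bins and np.isclose(e, grid.e_max_kev):
            b = grid.n_bins - 1
        if 0 <= b < grid.n_bins:
            out[b] += frac
    return out


def test_default_grid_has_363_bins():
    assert DEFAULT_GRID.n_bins == 363
    assert DEFAULT_GRID.bin_starts_kev()[0] == pytest.approx(0.7)
    assert DEFAULT_GRID.bin_starts_kev()[-1] == pytest.approx(36.9)


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([0, 10, 0, 30], [0, 0.25, 0, 0.75]),
        ([0, 0, 7, 0], [0, 0, 1, 0]),
        ([3, 3, 3, 3], [0.25, 0.25, 0.25, 0.25]),
    ],
)
def test_normalize_total_counts_hand_cases(counts, expected):
    out = wx.normalize_total_counts(_spectrum(counts))
    np.testing.assert_allclose(out, expected)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_all_zero_spectrum_raises_not_nan():
    with pytest.raises(DegenerateSpectrumError):
        wx.normalize_total_counts(_spectrum([0, 0, 0]))


def test_rebin_localized_mass_lands_in_bin_3():
    # all mass in channels centered 1.00-1.09 keV -> window [1.0, 1.1) -> bin 3
    cal = wx.EnergyCalibration(gain_ev=10.0, offset_ev=0.0, n_channels=2048)
    fractions = np.zeros(2048)
    channels = [ch for ch in range(2048) if 1.00 <= 10.0 * ch / 1000 <= 1.09]
    fractions[channels] = 1.0 / len(channels)
    out = wx.rebin(fractions, cal, DEFAULT_GRID)
    assert out[3] == pytest.approx(1.0)
    assert np.count_nonzero(out) == 1


def test_rebin_matches_brute_force_oracle_on_random_spectra():
    rng = np.random.default_rng(17)
    cal = wx.EnergyCalibration(gain_ev=37.0, offset_ev=-13.0, n_channels=512)
    for _ in range(5):
        fractions = rng.dirichlet(np.ones(512))
        out = wx.rebin(fractions, cal, DEFAULT_GRID)
        np.testing.assert_allclose(out, brute_force_rebin(fractions, cal, DEFAULT_GRID),
                                   atol=1e-15)


def test_rebin_uniform_fractions_full_coverage():
    # grid covering the whole detector: every bin holds (channels in bin)/total
    cal = wx.EnergyCalibration(gain_ev=50.0, offset_ev=25.0, n_channels=200)
    grid = FeatureGrid(0.0, 10.0, 0.1)  # covers 0.025-9.975 keV fully
    fractions = np.full(200, 1 / 200)
    out = wx.rebin(fractions, cal, grid)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)
    # 50 eV channels, 100 eV bins -> exactly 2 channels per bin
    np.testing.assert_allclose(out[out > 0], 2 / 200)


def test_rebin_mass_below_window_is_dropped_with_zero_vector():
    cal = wx.EnergyCalibration(gain_ev=20.0, offset_ev=0.0, n_channels=100)
    fractions = np.zeros(100)
    fractions[5] = 1.0  # 0.1 keV, below the 0.7 keV window start
    out = wx.rebin(fractions, cal, DEFAULT_GRID)
    assert np.all(out == 0)


def test_rebin_no_overlap_is_a_coverage_error():
    cal = wx.EnergyCalibration(gain_ev=20.0, offset_ev=0.0, n_channels=30)
    with pytest.raises(CoverageError):
        wx.rebin(np.full(30, 1 / 30), cal, FeatureGrid(10.0, 20.0, 0.1))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_rebin_is_linear_and_conserves_in_window_mass(seed):
    rng = np.random.default_rng(seed)
    cal = wx.EnergyCalibration(gain_ev=20.0, offset_ev=0.0, n_channels=256)
    x = rng.random(256)
    y = rng.random(256)
    a, b = rng.random(2)
    grid = FeatureGrid(0.7, 4.7, 0.1)
    left = wx.rebin(a * x + b * y, cal, grid)
    right = a * wx.rebin(x, cal, grid) + b * wx.rebin(y, cal, grid)
    np.testing.assert_allclose(left, right, rtol=1e-12, atol=1e-15)
    # conservation: output total equals the in-window input mass
    centers = cal.channel_energies_kev()
    # the grid's upper edge is right-closed: a channel centered exactly at
    # e_max belongs to the last bin
    in_window = (centers >= 0.7) & (centers <= 4.7)
    assert wx.rebin(x, cal, grid).sum() == pytest.approx(x[in_window].sum(), rel=1e-12)


def test_normalize_then_rebin_equals_rebin_then_normalize_under_full_coverage():
    cal = wx.EnergyCalibration(gain_ev=50.0, offset_ev=25.0, n_channels=100)
    grid = FeatureGrid(0.0, 5.0, 0.1)  # covers all channel centers
    counts = np.random.default_rng(2).integers(1, 100, 100)
    spec = _spectrum(counts.tolist(), gain_ev=50.0, offset_ev=25.0)
    norm_first = wx.rebin(wx.normalize_total_counts(spec), cal, grid)
    rebin_first = wx.rebin(counts.astype(float), cal, grid)
    rebin_first = rebin_first / rebin_first.sum()
    np.testing.assert_allclose(norm_first, rebin_first, rtol=1e-12)


def test_preprocess_dataset_shapes_and_errors(tiny_grid):
    cal = wx.EnergyCalibration(gain_ev=20.0, offset_ev=0.0, n_channels=512)
    rng = np.random.default_rng(4)
    spectra = [
        wx.RawSpectrum(counts=rng.integers(1, 100, 512), calibration=cal,
                       species=f"sp{i % 2}", sample_id=f"s{i % 2}")
        for i in range(5)
    ]
    ds = wx.preprocess_dataset(spectra)
    assert ds.features.shape == (5, 363)
    assert list(ds.labels) == ["sp0", "sp1", "sp0", "sp1", "sp0"]

    with pytest.raises(ConfigurationError):
        wx.preprocess_dataset([])

    bad = spectra + [wx.RawSpectrum(counts=np.zeros(512, dtype=int), calibration=cal,
                                    species="spx", sample_id="deadscan")]
    with pytest.raises(DegenerateSpectrumError, match="deadscan"):
        wx.preprocess_dataset(bad)


def test_feature_table_round_trip(tmp_path, blob_dataset):
    from woodxrf.preprocess import load_features, save_features

    save_features(blob_dataset, tmp_path / "f.csv", tmp_path / "l.csv")
    back = load_features(tmp_path / "f.csv", tmp_path / "l.csv", blob_dataset.grid)
    np.testing.assert_allclose(back.features, blob_dataset.features, atol=1e-6)
    assert list(back.labels) == list(blob_dataset.labels)
    assert list(back.groups) == list(blob_dataset.groups)
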