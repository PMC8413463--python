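"""Simulator physics and bookkeeping: expectation structure, Poisson noise,
replication layout, and the planted-window panel construction."""

import numpy as np
import pytest

import woodxrf as wx
from woodxrf.errors import ConfigurationError
from woodxrf.preprocess import DEFAULT_GRID
from woodxrf.synthetic import _jitter_profile


def test_line_library_covers_the_wood_elements(line_library):
    elements = {l.element for l in line_library}
    assert elements == {"Na", "Mg", "Al", "Si", "P", "S", "K", "Ca", "Fe"}
    for line in line_library:
        assert 0 < line.energy_kev < 50


def test_expectation_integrates_to_mean_total_counts(small_acq, line_library):
    profile = wx.SpeciesProfile(name="x", element_weights={"Ca": 0.1, "Fe": 0.05})
    expect = wx.expected_spectrum(profile, small_acq, line_library)
    assert expect.sum() == pytest.approx(small_acq.mean_total_counts, rel=1e-6)
    assert np.all(expect >= 0)


def test_single_line_limit_is_one_gaussian(small_acq, line_library):
    # all signal on Si Ka, no continuum -> a single peak at 1.740 keV
    profile = wx.SpeciesProfile(name="si", line_weights={("Si", "Ka"): 1.0})
    expect = wx.expected_spectrum(profile, small_acq, line_library)
    centers = small_acq.calibration.channel_energies_kev()
    peak = centers[np.argmax(expect)]
    assert peak == pytest.approx(1.740, abs=small_acq.calibration.gain_ev / 1000)
    assert expect.sum() == pytest.approx(small_acq.mean_total_counts, rel=1e-6)
    # mass is local: 99%+ within 5 sigma of the line
    sigma = small_acq.sigma_kev(1.740)
    near = np.abs(centers - 1.740) < 5 * sigma
    assert expect[near].sum() / expect.sum() > 0.99


def test_pure_continuum_limit_vanishes_above_excitation(line_library):
    acq = wx.AcquisitionModel(
        excitation_kv=30.0,
        calibration=wx.EnergyCalibration(gain_ev=20.0, n_channels=2048),
    )
    profile = wx.SpeciesProfile(name="cont", element_weights={})
    expect = wx.expected_spectrum(profile, acq, line_library)
    centers = acq.calibration.channel_energies_kev()
    assert np.all(expect[centers >= 30.0] == 0)
    assert expect[(centers > 2) & (centers < 20)].min() > 0


def test_density_factor_doubles_continuum_to_peak_ratio(small_acq, line_library):
    def ratio(density):
        profile = wx.SpeciesProfile(name="r", element_weights={"Fe": 0.2},
                                    density_factor=density)
        expect = wx.expected_spectrum(profile, small_acq, line_library)
        centers = small_acq.calibration.channel_energies_kev()
        sigma = small_acq.sigma_kev(6.404)
        near_fe = np.abs(centers - 6.404) < 6 * sigma
        near_fe |= np.abs(centers - 7.058) < 6 * sigma
        cont = expect[~near_fe].sum()
        # peak area estimated after subtracting local continuum baseline
        base = np.interp(centers[near_fe], centers[~near_fe], expect[~near_fe])
        peak = (expect[near_fe] - base).sum()
        return cont / peak

    assert ratio(2.0) / ratio(1.0) == pytest.approx(2.0, rel=0.05)


def test_poisson_draws_are_reproducible_and_centered(small_acq, line_library):
    profile = wx.SpeciesProfile(name="p", element_weights={"Ca": 0.1})
    rng1 = np.random.default_rng(42)
    rng2 = np.random.default_rng(42)
    s1 = wx.simulate_spectrum(profile, small_acq, rng1, line_library)
    s2 = wx.simulate_spectrum(profile, small_acq, rng2, line_library)
    np.testing.assert_array_equal(s1.counts, s2.counts)
    assert s1.species == "p"

    # realized totals concentrate around the expectation (Poisson tail bound)
    mu = small_acq.mean_total_counts
    rng = np.random.default_rng(7)
    hits = 0
    for _ in range(100):
        s = wx.simulate_spectrum(profile, small_acq, rng, line_library)
        hits += abs(s.total_counts - mu) <= 5 * np.sqrt(mu)
    assert hits >= 99


def test_channelwise_variance_matches_poisson_mean(small_acq, line_library):
    profile = wx.SpeciesProfile(name="v", element_weights={"Ca": 0.1, "K": 0.05})
    expect = wx.expected_spectrum(profile, small_acq, line_library)
    rng = np.random.default_rng(11)
    draws = rng.poisson(expect, size=(1000, len(expect)))
    strong = expect >= 50
    ratio = draws.var(axis=0)[strong] / expect[strong]
    assert ratio.min() > 0.8 and ratio.max() < 1.2


def test_simulate_dataset_bookkeeping(small_acq):
    panel = wx.make_null_panel(3, seed=0)
    plan = wx.SimulationPlan(species=panel, samples_per_species=2,
                             scans_per_sample=10, seed=5)
    spectra, manifest = wx.simulate_dataset(plan, small_acq)
    assert len(spectra) == 60
    assert len(manifest) == 60
    assert len(manifest.sample_groups) == 6
    assert manifest.species_set == {p.name for p in panel}
    # seed contract: the same plan reproduces every scan exactly
    spectra2, _ = wx.simulate_dataset(plan, small_acq)
    np.testing.assert_array_equal(spectra[17].counts, spectra2[17].counts)


def test_zero_jitter_means_identical_sample_expectations(small_acq):
    panel = wx.make_null_panel(2, seed=0, profile_jitter=0.0)
    plan = wx.SimulationPlan(species=panel, samples_per_species=2,
                             scans_per_sample=40, seed=2)
    spectra, _ = wx.simulate_dataset(plan, small_acq)
    by_sample = {}
    for s in spectra:
        by_sample.setdefault(s.sample_id, []).append(s.counts)
    means = {k: np.mean(v, axis=0) for k, v in by_sample.items()}
    keys = sorted(means)
    # per-sample mean spectra agree within Poisson error of the shared truth
    diff = means[keys[0]] - means[keys[1]]
    scale = np.sqrt((means[keys[0]] + means[keys[1]]) / 40 + 1e-9)
    assert np.abs(diff / np.maximum(scale, 1e-3)).max() < 6


def test_jitter_perturbs_weights_proportionally():
    profile = wx.SpeciesProfile(name="j", element_weights={"Ca": 0.1},
                                profile_jitter=0.1)
    rng = np.random.default_rng(0)
    draws = [_jitter_profile(profile, np.random.default_rng(i)).element_weights["Ca"]
             for i in range(400)]
    assert np.mean(draws) == pytest.approx(0.1, rel=0.05)
    assert np.std(draws) == pytest.approx(0.01, rel=0.25)


def test_planted_panel_differs_only_inside_window(small_acq, line_library):
    panel = wx.make_planted_window_panel(5, window=(0.7, 1.7), seed=3)
    expects = [wx.expected_spectrum(p, small_acq, line_library) for p in panel]
    centers = small_acq.calibration.channel_energies_kev()
    outside = (centers < 0.7) | (centers >= 1.7)
    inside = ~outside
    for a in range(len(panel)):
        for b in range(a + 1, len(panel)):
            d_in = np.abs(expects[a] - expects[b])[inside].sum()
            d_out = np.abs(expects[a] - expects[b])[outside].sum()
            assert d_in > 0
            # outside-window difference only from sub-permille Gaussian tails
            assert d_out < 0.01 * d_in
    # varied lines are Na/Mg/Al only; Si Ka sits in the bin starting at the
    # window's upper edge and is excluded by the half-open rule
    varied = {k[0] for p in panel for k in p.line_weights}
    assert varied == {"Na", "Mg", "Al"}


def test_planted_panel_fe_window(small_acq, line_library):
    panel = wx.make_planted_window_panel(2, window=(6.3, 6.5), seed=3)
    varied = {k for p in panel for k in p.line_weights}
    assert varied == {("Fe", "Ka")}
    # Fe Kb stays shared (identical outside the window)
    assert all(p.element_weights == panel[0].element_weights for p in panel)


def test_planted_panel_empty_window_is_an_error():
    with pytest.raises(ConfigurationError):
        wx.make_planted_window_panel(3, window=(30.0, 31.0), seed=0)


def test_panel_expected_feature_vectors_are_separated(small_acq, line_library):
    # pairwise L1 distance of the expected spectra is bounded away from zero
    panel = wx.make_planted_window_panel(5, window=(0.7, 1.7), seed=1)
    expects = [wx.expected_spectrum(p, small_acq, line_library) for p in panel]
    norm = small_acq.mean_total_counts
    for a in range(5):
        for b in range(a + 1, 5):
            assert np.abs(expects[a] - expects[b]).sum() / norm > 0.01
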