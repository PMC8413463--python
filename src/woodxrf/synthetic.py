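"""Forward simulation of energy-dispersive XRF spectra of wood.

The simulator produces labeled spectra with controllable class structure so
the whole pipeline (ingestion, preprocessing, training, evaluation,
importance) can be exercised without access to instrument data.  A spectrum
is modeled as

* a Kramers-type bremsstrahlung continuum ``c * (E_max / E - 1)``, cut off
  at the excitation voltage and multiplied by a smooth detector-efficiency
  roll-off below ~1 keV, scaled by a per-species density factor (wood-density
  proxy);
* Gaussian characteristic K lines for the elements observed in wood
  (Na, Mg, Al, Si, P, S, K, Ca, Fe), with detector resolution
  ``sigma^2(E) = sigma_noise^2 + k * E`` (electronic noise plus Fano-like
  broadening);
* Poisson counting noise channel by channel.

The simulator targets the statistical structure of the classification
problem, not metrological fidelity: no escape peaks, pile-up, matrix effects
or secondary fluorescence.

Randomness contract: one root seed per :class:`SimulationPlan`; independent
child streams are derived per (species, sample, scan), so any subset of the
dataset is reproducible regardless of iteration order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError
from .preprocess import DEFAULT_GRID, FeatureGrid
from .spectra_io import EnergyCalibration, Manifest, RawSpectrum

__all__ = [
    "ElementLine",
    "SpeciesProfile",
    "AcquisitionModel",
    "SimulationPlan",
    "load_line_library",
    "expected_spectrum",
    "simulate_spectrum",
    "simulate_dataset",
    "make_planted_window_panel",
    "make_null_panel",
]


@dataclass(frozen=True)
class ElementLine:
    """One characteristic emission line."""

    element: str
    line: str  # "Ka" or "Kb"
    energy_kev: float
    relative_intensity: float  # within-element, Ka == 1

    def __post_init__(self):
        if self.energy_kev <= 0:
            raise ConfigurationError("line energy must be positive")
        if self.relative_intensity <= 0:
            raise ConfigurationError("relative intensity must be positive")


def load_line_library() -> list[ElementLine]:
    """K-line energies/intensities packaged with the simulator."""
    text = resources.files("woodxrf.data").joinpath("xray_lines.csv").read_text()
    df = pd.read_csv(io.StringIO(text), comment="#")
    return [
        ElementLine(r.element, r.line, float(r.energy_kev), float(r.relative_intensity))
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class SpeciesProfile:
    """Spectral signature of one (synthetic) wood species.

    ``element_weights`` give each element's expected share of the total
    signal (line areas, summed over that element's lines); the remainder of
    the signal budget is continuum, scaled by ``density_factor``.
    ``line_weights`` optionally pins individual lines ``(element, line)`` to
    explicit signal shares, overriding the element-level split — used by the
    planted-window panels, which must control single lines.
    ``profile_jitter`` is the relative standard deviation applied to the
    weights when physical samples are drawn from the species.
    """

    name: str
    element_weights: dict = field(default_factory=dict)
    density_factor: float = 1.0
    profile_jitter: float = 0.0
    line_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(w < 0 for w in self.element_weights.values()):
            raise ConfigurationError("element weights must be non-negative")
        if any(w < 0 for w in self.line_weights.values()):
            raise ConfigurationError("line weights must be non-negative")
        if self.density_factor <= 0:
            raise ConfigurationError("density factor must be positive")
        if self.profile_jitter < 0:
            raise ConfigurationError("jitter must be non-negative")

    def resolve_line_weights(self, library: list[ElementLine]) -> dict[tuple[str, str], float]:
        """Signal share per line: element weights split by relative
        intensity, then explicit per-line weights override."""
        out: dict[tuple[str, str], float] = {}
        for element, w in self.element_weights.items():
            lines = [l for l in library if l.element == element]
            if not lines:
                raise ConfigurationError(f"element {element!r} not in line library")
            total_ri = sum(l.relative_intensity for l in lines)
            for l in lines:
                out[(l.element, l.line)] = w * l.relative_intensity / total_ri
        out.update(self.line_weights)
        return out


@dataclass(frozen=True)
class AcquisitionModel:
    """Instrument model: 50 kV excitation, 20 s live time by default."""

    excitation_kv: float = 50.0
    live_time_s: float = 20.0
    mean_total_counts: float = 5e5
    fwhm_ref_ev: float = 140.0  # detector FWHM at the reference energy
    ref_energy_kev: float = 5.9  # Mn Ka, the conventional resolution reference
    noise_fwhm_ev: float = 100.0  # electronic-noise floor
    roll_off_kev: float = 1.0  # efficiency roll-off center
    roll_off_width_kev: float = 0.15
    calibration: EnergyCalibration = field(default_factory=EnergyCalibration)

    def __post_init__(self):
        if self.excitation_kv <= 0:
            raise ConfigurationError("excitation voltage must be positive")
        if self.mean_total_counts <= 0:
            raise ConfigurationError("mean total counts must be positive")
        if self.noise_fwhm_ev >= self.fwhm_ref_ev:
            raise ConfigurationError("noise floor must lie below reference FWHM")

    def sigma_kev(self, energy_kev: np.ndarray) -> np.ndarray:
        """Gaussian peak width: sigma^2 = sigma_noise^2 + k * E."""
        s_noise = (self.noise_fwhm_ev / 1000.0) / 2.3548
        s_ref = (self.fwhm_ref_ev / 1000.0) / 2.3548
        k = (s_ref**2 - s_noise**2) / self.ref_energy_kev
        return np.sqrt(s_noise**2 + k * np.asarray(energy_kev, dtype=float))

    def continuum_density(self, energy_kev: np.ndarray) -> np.ndarray:
        """Kramers-like shape with smooth low-energy efficiency roll-off;
        zero at and above the excitation voltage."""
        e = np.asarray(energy_kev, dtype=float)
        out = np.zeros_like(e)
        ok = (e > 0) & (e < self.excitation_kv)
        kram = self.excitation_kv / e[ok] - 1.0
        eff = 1.0 / (1.0 + np.exp(-(e[ok] - self.roll_off_kev) / self.roll_off_width_kev))
        out[ok] = kram * eff
        return out


@dataclass(frozen=True)
class SimulationPlan:
    """What to simulate: a species panel and the replication structure."""

    species: tuple
    samples_per_species: int = 1
    scans_per_sample: int = 260
    seed: int = 0

    def __post_init__(self):
        if not self.species:
            raise ConfigurationError("species panel is empty")
        if self.samples_per_species < 1 or self.scans_per_sample < 1:
            raise ConfigurationError("replication counts must be >= 1")


def expected_spectrum(profile: SpeciesProfile, acq: AcquisitionModel,
                      library: list[ElementLine] | None = None) -> np.ndarray:
    """Deterministic per-channel expected counts for one profile.

    The continuum (unit area, scaled by ``density_factor`` and the signal
    budget left over from the lines) and the Gaussian lines are combined and
    rescaled so the expectation integrates to ``acq.mean_total_counts``.
    """
    if library is None:
        library = load_line_library()
    cal = acq.calibration
    centers = cal.channel_energies_kev()
    gain_kev = cal.gain_ev / 1000.0
    edges = np.concatenate([centers - gain_kev / 2, [centers[-1] + gain_kev / 2]])

    cont = acq.continuum_density(centers) * gain_kev
    total_cont = cont.sum()
    line_weights = profile.resolve_line_weights(library)
    w_lines = sum(line_weights.values())

    raw = np.zeros_like(centers)
    if total_cont > 0:
        raw += profile.density_factor * max(0.0, 1.0 - w_lines) * cont / total_cont
    by_key = {(l.element, l.line): l for l in library}
    for key, w in line_weights.items():
        if w == 0:
            continue
        line = by_key.get(key)
        if line is None:
            raise ConfigurationError(f"unknown line {key!r}")
        if line.energy_kev >= acq.excitation_kv:
            continue  # cannot be excited
        sigma = float(acq.sigma_kev(line.energy_kev))
        mass = np.diff(norm.cdf(edges, loc=line.energy_kev, scale=sigma))
        raw += w * mass

    total = raw.sum()
    if total <= 0:
        raise ConfigurationError("expected spectrum has zero integral")
    return raw * (acq.mean_total_counts / total)


def simulate_spectrum(profile: SpeciesProfile, acq: AcquisitionModel,
                      rng: np.random.Generator,
                      library: list[ElementLine] | None = None,
                      sample_id: str = "",
                      expectation: np.ndarray | None = None) -> RawSpectrum:
    """Draw one scan: channel-wise Poisson noise around the expectation."""
    if expectation is None:
        expectation = expected_spectrum(profile, acq, library)
    counts = rng.poisson(expectation)
    return RawSpectrum(
        counts=counts,
        calibration=acq.calibration,
        sample_id=sample_id or profile.name,
        species=profile.name,
        live_time_s=acq.live_time_s,
    )


def _jitter_profile(profile: SpeciesProfile, rng: np.random.Generator) -> SpeciesProfile:
    """Draw one physical sample from a species: multiplicative weight noise."""
    j = profile.profile_jitter
    if j == 0:
        return profile
    ew = {k: max(0.0, w * rng.normal(1.0, j)) for k, w in profile.element_weights.items()}
    lw = {k: max(0.0, w * rng.normal(1.0, j)) for k, w in profile.line_weights.items()}
    return replace(profile, element_weights=ew, line_weights=lw)


def simulate_dataset(plan: SimulationPlan, acq: AcquisitionModel | None = None,
                     library: list[ElementLine] | None = None
                     ) -> tuple[list[RawSpectrum], Manifest]:
    """Simulate the full replication structure of a study.

    For each species, ``samples_per_species`` physical-sample profiles are
    drawn by jittering the species profile, and ``scans_per_sample`` scans
    are drawn from each.  Spectra come back in deterministic
    (species, sample, scan) order together with a matching manifest.
    """
    if acq is None:
        acq = AcquisitionModel()
    if library is None:
        library = load_line_library()
    spectra: list[RawSpectrum] = []
    rows: list[dict] = []
    for si, species in enumerate(plan.species):
        for pj in range(plan.samples_per_species):
            srng = np.random.default_rng(
                np.random.SeedSequence((plan.seed, si, pj, 0xA11))
            )
            sample_profile = _jitter_profile(species, srng)
            sample_id = f"{species.name}-s{pj}"
            expect = expected_spectrum(sample_profile, acq, library)
            for sc in range(plan.scans_per_sample):
                rng = np.random.default_rng(
                    np.random.SeedSequence((plan.seed, si, pj, sc))
                )
                spec = simulate_spectrum(
                    sample_profile, acq, rng, library,
                    sample_id=sample_id, expectation=expect,
                )
                spec = replace(spec, species=species.name)
                rows.append(
                    {
                        "file": f"scan_{len(spectra):06d}.csv",
                        "species": species.name,
                        "sample_id": sample_id,
                        "orientation": "unknown",
                    }
                )
                spectra.append(spec)
    return spectra, Manifest(rows=rows)


#: Shared out-of-window composition for the planted panels: modest levels of
#: the elements commonly reported in wood ash, leaving most of the signal to
#: the continuum.
_BASE_ELEMENT_WEIGHTS = {
    "Si": 0.02,
    "P": 0.01,
    "S": 0.015,
    "K": 0.05,
    "Ca": 0.06,
    "Fe": 0.02,
}


def _lines_in_window(window: tuple[float, float], grid: FeatureGrid,
                     library: list[ElementLine]) -> list[ElementLine]:
    """Lines whose feature-grid bin lies fully inside the window.

    The line is placed in the half-open bin containing its energy; it counts
    as in-window only if that whole bin fits in [lo, hi] — a line landing in
    the bin that starts at the window's upper edge is outside.
    """
    lo, hi = window
    w = grid.bin_width_kev
    selected = []
    for line in library:
        b = grid.bin_index(np.array([line.energy_kev]))[0]
        if b < 0:
            continue
        b_start = grid.e_min_kev + b * w
        if b_start >= lo - 1e-12 and b_start + w <= hi + 1e-12:
            selected.append(line)
    return selected


def make_planted_window_panel(n_species: int, window: tuple[float, float] = (0.7, 1.7),
                              seed: int = 0, grid: FeatureGrid = DEFAULT_GRID,
                              in_window_mass: float = 0.12,
                              dominant_share: float = 0.7,
                              profile_jitter: float = 0.0,
                              library: list[ElementLine] | None = None
                              ) -> tuple[SpeciesProfile, ...]:
    """Species that differ *only* in line weights inside ``window``.

    All species share the continuum and the out-of-window element weights.
    A fixed total signal share (``in_window_mass``) is distributed over the
    lines inside the window with a near-orthogonal pattern per species.
    Because the classifier sees 100 eV bins, lines are first grouped by the
    feature-grid bin they fall in (Na Ka and Na Kb share a bin, for
    instance); each species concentrates ``dominant_share`` of the mass on
    its own bin group (species beyond the group count split it over a pair),
    the rest spread evenly, so species remain separable *after* binning.
    The seed shuffles the species-to-group pairing.  Keeping the in-window
    total fixed makes the expected spectra agree outside the window up to
    sub-permille Gaussian tail leakage; a single-group window instead varies
    that group's magnitude across species.
    """
    if n_species < 2:
        raise ConfigurationError("a panel needs at least two species")
    if not 0 < dominant_share <= 1:
        raise ConfigurationError("dominant_share must be in (0, 1]")
    if library is None:
        library = load_line_library()
    lines = _lines_in_window(window, grid, library)
    if not lines:
        raise ConfigurationError(
            f"no library lines fall inside the {window[0]}-{window[1]} keV window"
        )
    varied_elements = {l.element for l in lines}
    base = {e: w for e, w in _BASE_ELEMENT_WEIGHTS.items() if e not in varied_elements}

    # group in-window lines by the grid bin their energy falls in
    groups: dict[int, list[ElementLine]] = {}
    for line in lines:
        b = int(grid.bin_index(np.array([line.energy_kev]))[0])
        groups.setdefault(b, []).append(line)
    group_bins = sorted(groups)
    ng = len(group_bins)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBA)))
    order = rng.permutation(ng)

    patterns: list[np.ndarray] = []
    for i in range(n_species):
        if ng == 1:
            # magnitude coding: species differ in the single group's strength
            patterns.append(np.array([(i + 1) / n_species]))
            continue
        w = np.full(ng, (1.0 - dominant_share) / (ng - 1))
        a = order[i % ng]
        if i < ng:
            w[a] = dominant_share
        else:
            b = order[(i + 1 + i // ng) % ng]
            if b == a:
                b = order[(i + 2 + i // ng) % ng]
            w[a] = w[b] = dominant_share / 2
        patterns.append(w)
    for i in range(n_species):
        for j in range(i + 1, n_species):
            if np.abs(patterns[i] - patterns[j]).sum() < 1e-9:
                raise ConfigurationError(
                    f"cannot construct {n_species} distinct binned patterns over "
                    f"{ng} line groups in the {window[0]}-{window[1]} keV window"
                )
    panel = []
    for i, pattern in enumerate(patterns):
        lw: dict[tuple[str, str], float] = {}
        for gw, bin_id in zip(pattern, group_bins):
            members = groups[bin_id]
            total_ri = sum(l.relative_intensity for l in members)
            for l in members:
                lw[(l.element, l.line)] = (
                    in_window_mass * float(gw) * l.relative_intensity / total_ri
                )
        panel.append(
            SpeciesProfile(
                name=f"species_{i:02d}",
                element_weights=dict(base),
                line_weights=lw,
                density_factor=1.0,
                profile_jitter=profile_jitter,
            )
        )
    return tuple(panel)


def make_null_panel(n_species: int, seed: int = 0,
                    profile_jitter: float = 0.0) -> tuple[SpeciesProfile, ...]:
    """Statistically indistinguishable species: identical profiles under
    different labels.  A classifier can only reach chance accuracy here."""
    if n_species < 2:
        raise ConfigurationError("a panel needs at least two species")
    shared = dict(_BASE_ELEMENT_WEIGHTS, Na=0.01, Mg=0.01, Al=0.02)
    return tuple(
        SpeciesProfile(name=f"null_{i:02d}", element_weights=shared,
                       profile_jitter=profile_jitter)
        for i in range(n_species)
    )
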