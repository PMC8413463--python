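"""Reading and writing per-scan XRF spectra and dataset manifests.

A scan is stored as a small self-contained CSV: ``#``-prefixed header lines
carry ``key=value`` metadata (energy calibration, live time, sample and
species labels), followed by either ``channel,counts`` or ``energy_keV,counts``
columns.  A dataset is a manifest CSV with columns
``file,species,sample_id,orientation`` pointing at per-scan files.

Energies are electron-volts internally (calibration gain/offset) and keV at
user-facing interfaces.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationError, FormatError, ManifestError

ORIENTATIONS = ("tangential", "radial", "oblique", "unknown")

#: Default detector geometry for a handheld energy-dispersive unit:
#: 2048 channels at 20 eV/channel covers 0–40.96 keV, comfortably spanning
#: the 0.7–37 keV analysis window of a 50 kV excitation. Configurable, not
#: asserted.
DEFAULT_N_CHANNELS = 2048
DEFAULT_GAIN_EV = 20.0
DEFAULT_OFFSET_EV = 0.0


@dataclass(frozen=True)
class EnergyCalibration:
    """Linear map from detector channel index to photon energy.

    ``energy_ev(ch) = offset_ev + gain_ev * ch``
    """

    gain_ev: float = DEFAULT_GAIN_EV
    offset_ev: float = DEFAULT_OFFSET_EV
    n_channels: int = DEFAULT_N_CHANNELS

    def __post_init__(self):
        if self.gain_ev <= 0:
            raise CalibrationError(f"gain must be positive, got {self.gain_ev}")
        if self.n_channels < 2:
            raise CalibrationError(f"need at least 2 channels, got {self.n_channels}")

    def channel_energies_kev(self) -> np.ndarray:
        """Center energy of every channel, in keV."""
        ch = np.arange(self.n_channels)
        return (self.offset_ev + self.gain_ev * ch) / 1000.0

    def isclose(self, other: "EnergyCalibration", rtol: float = 1e-9) -> bool:
        return (
            self.n_channels == other.n_channels
            and np.isclose(self.gain_ev, other.gain_ev, rtol=rtol)
            and np.isclose(self.offset_ev, other.offset_ev, rtol=rtol, atol=1e-9)
        )


@dataclass(frozen=True)
class RawSpectrum:
    """One acquisition: integer counts per channel plus scan metadata."""

    counts: np.ndarray
    calibration: EnergyCalibration
    sample_id: str = ""
    species: str = ""
    orientation: str = "unknown"
    live_time_s: float = 20.0

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(counts) != self.calibration.n_channels:
            raise CalibrationError(
                f"{len(counts)} count entries but calibration declares "
                f"{self.calibration.n_channels} channels"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class Manifest:
    """Rows of (file path, species, sample_id, orientation)."""

    rows: list[dict] = field(default_factory=list)

    def __post_init__(self):
        paths = [r["file"] for r in self.rows]
        if len(paths) != len(set(paths)):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ManifestError(f"duplicate file entries in manifest: {dupes}")
        sample_species: dict[str, str] = {}
        for r in self.rows:
            if not r["species"]:
                raise ManifestError(f"empty species for file {r['file']}")
            sid = r["sample_id"]
            if sid in sample_species and sample_species[sid] != r["species"]:
                raise ManifestError(
                    f"sample_id {sid!r} maps to both {sample_species[sid]!r} "
                    f"and {r['species']!r}"
                )
            sample_species[sid] = r["species"]

    def __len__(self):
        return len(self.rows)

    @property
    def species_set(self) -> set[str]:
        return {r["species"] for r in self.rows}

    @property
    def sample_groups(self) -> set[str]:
        return {r["sample_id"] for r in self.rows}


_META_KEYS = ("gain_eV", "offset_eV", "live_time_s", "sample_id", "species", "orientation")


def _parse_header(path: Path) -> tuple[dict, int]:
    """Parse leading '#'-comment key=value lines; return metadata + line count."""
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta, n_header


def read_spectrum_csv(path: str | Path) -> RawSpectrum:
    """Read one per-scan CSV into a :class:`RawSpectrum`.

    Two column layouts are accepted:

    * ``channel,counts`` with the calibration (``gain_eV``, ``offset_eV``)
      in ``#`` header lines (defaults applied if absent);
    * ``energy_keV,counts`` with the calibration recovered from the energy
      column, which must be uniformly spaced to 1e-9 relative tolerance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    meta, n_header = _parse_header(path)
    try:
        df = pd.read_csv(path, skiprows=n_header)
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    cols = {c.strip().lower(): c for c in df.columns}
    if "counts" not in cols:
        raise FormatError(f"{path}: missing 'counts' column (found {list(df.columns)})")
    counts = df[cols["counts"]].to_numpy()
    if np.any(pd.isna(counts)):
        raise FormatError(f"{path}: counts column contains missing values")
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative counts")

    if "channel" in cols:
        gain = float(meta.get("gain_eV", DEFAULT_GAIN_EV))
        offset = float(meta.get("offset_eV", DEFAULT_OFFSET_EV))
        cal = EnergyCalibration(gain_ev=gain, offset_ev=offset, n_channels=len(counts))
    elif "energy_kev" in cols:
        energy_ev = df[cols["energy_kev"]].to_numpy(dtype=float) * 1000.0
        if len(energy_ev) < 2:
            raise FormatError(f"{path}: need at least two rows to fit a calibration")
        steps = np.diff(energy_ev)
        gain = steps[0]
        if gain <= 0 or not np.allclose(steps, gain, rtol=1e-9, atol=1e-9 * max(abs(gain), 1)):
            raise CalibrationError(f"{path}: energy column is not a uniform grid")
        cal = EnergyCalibration(gain_ev=gain, offset_ev=energy_ev[0], n_channels=len(counts))
    else:
        raise FormatError(
            f"{path}: expected a 'channel' or 'energy_keV' column, found {list(df.columns)}"
        )

    return RawSpectrum(
        counts=counts,
        calibration=cal,
        sample_id=meta.get("sample_id", ""),
        species=meta.get("species", ""),
        orientation=meta.get("orientation", "unknown"),
        live_time_s=float(meta.get("live_time_s", 20.0)),
    )


def write_spectrum_csv(spectrum: RawSpectrum, path: str | Path) -> None:
    """Write a per-scan CSV (channel layout) with full metadata header."""
    path = Path(path)
    cal = spectrum.calibration
    with open(path, "w", newline="") as fh:
        fh.write(f"# gain_eV={cal.gain_ev!r}\n")
        fh.write(f"# offset_eV={cal.offset_ev!r}\n")
        fh.write(f"# live_time_s={spectrum.live_time_s!r}\n")
        fh.write(f"# sample_id={spectrum.sample_id}\n")
        fh.write(f"# species={spectrum.species}\n")
        fh.write(f"# orientation={spectrum.orientation}\n")
        writer = csv.writer(fh)
        writer.writerow(["channel", "counts"])
        for ch, c in enumerate(spectrum.counts):
            writer.writerow([ch, int(c)])


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"file", "species", "sample_id", "orientation"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: manifest missing columns {sorted(missing)}")
    return Manifest(rows=df[list(("file", "species", "sample_id", "orientation"))].to_dict("records"))


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    pd.DataFrame(manifest.rows).to_csv(path, index=False)


def read_dataset(manifest_path: str | Path) -> list[RawSpectrum]:
    """Read every spectrum referenced by a manifest, manifest labels winning.

    Returns one :class:`RawSpectrum` per manifest row, in manifest order.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    spectra = []
    for row in manifest.rows:
        fpath = Path(row["file"])
        if not fpath.is_absolute():
            fpath = base / fpath
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing file: {fpath}")
        spec = read_spectrum_csv(fpath)
        spectra.append(
            replace(
                spec,
                species=row["species"],
                sample_id=row["sample_id"],
                orientation=row["orientation"] or "unknown",
            )
        )
    return spectra


def write_dataset(spectra: list[RawSpectrum], directory: str | Path,
                  manifest_name: str = "manifest.csv") -> Path:
    """Write per-scan CSVs plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(spectra):
        fname = f"scan_{i:06d}.csv"
        write_spectrum_csv(spec, directory / fname)
        rows.append(
            {
                "file": fname,
                "species": spec.species,
                "sample_id": spec.sample_id,
                "orientation": spec.orientation,
            }
        )
    manifest = Manifest(rows=rows)
    mpath = directory / manifest_name
    write_manifest(manifest, mpath)
    return mpath
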