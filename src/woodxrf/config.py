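"""Structured run configuration for the command-line pipeline.

One YAML file configures every stage; unknown keys are rejected with the
offending section and field named, and the parsed configuration is echoed
into every output directory together with the seed and software versions so
a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .model import CNNConfig
from .preprocess import FeatureGrid
from .synthetic import AcquisitionModel

__all__ = ["RunConfig", "PanelConfig", "PlanConfig"]


@dataclass(frozen=True)
class PanelConfig:
    """Which synthetic species panel to simulate."""

    type: str = "planted_window"  # or "null"
    n_species: int = 5
    window: tuple = (0.7, 1.7)
    in_window_mass: float = 0.12
    profile_jitter: float = 0.0

    def __post_init__(self):
        if self.type not in ("planted_window", "null"):
            raise ConfigurationError(f"unknown panel type {self.type!r}")
        object.__setattr__(self, "window", tuple(self.window))


@dataclass(frozen=True)
class PlanConfig:
    samples_per_species: int = 2
    scans_per_sample: int = 60


@dataclass(frozen=True)
class EvaluationConfig:
    optimization_precision: str = "optimized_precision"


@dataclass(frozen=True)
class ImportanceConfig:
    method: str = "permutation"  # or "occlusion"
    n_permutations: int = 3
    window_bins: int = 1

    def __post_init__(self):
        if self.method not in ("permutation", "occlusion"):
            raise ConfigurationError(f"unknown importance method {self.method!r}")


@dataclass(frozen=True)
class ControlConfig:
    k: int = 29
    label_weights: str | None = None  # None -> Dirichlet; "uniform" -> flat


_SECTIONS = {
    "grid": FeatureGrid,
    "acquisition": AcquisitionModel,
    "panel": PanelConfig,
    "plan": PlanConfig,
    "cnn": CNNConfig,
    "evaluation": EvaluationConfig,
    "importance": ImportanceConfig,
    "control": ControlConfig,
}


def _build_section(name: str, cls, payload: dict):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(payload) - fields
    if unknown:
        raise ConfigurationError(
            f"unknown keys in section {name!r}: {sorted(unknown)} "
            f"(allowed: {sorted(fields)})"
        )
    payload = dict(payload)
    if name == "acquisition" and isinstance(payload.get("calibration"), dict):
        from .spectra_io import EnergyCalibration

        payload["calibration"] = _build_section(
            "acquisition.calibration", EnergyCalibration, payload["calibration"]
        )
    try:
        return cls(**payload)
    except TypeError as exc:
        raise ConfigurationError(f"section {name!r}: {exc}") from exc


@dataclass
class RunConfig:
    """Everything one pipeline run needs, in one place."""

    seed: int = 0
    output_dir: str = "runs/out"
    grid: FeatureGrid = field(default_factory=FeatureGrid)
    acquisition: AcquisitionModel = field(default_factory=AcquisitionModel)
    panel: PanelConfig = field(default_factory=PanelConfig)
    plan: PlanConfig = field(default_factory=PlanConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    importance: ImportanceConfig = field(default_factory=ImportanceConfig)
    control: ControlConfig = field(default_factory=ControlConfig)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload or {})
        kwargs = {}
        kwargs["seed"] = int(payload.pop("seed", 0))
        kwargs["output_dir"] = str(payload.pop("output_dir", "runs/out"))
        for name, section_cls in _SECTIONS.items():
            section = payload.pop(name, None)
            if section is None:
                kwargs[name] = section_cls()
            elif isinstance(section, dict):
                if name == "cnn":
                    section = dict(section)
                    section.setdefault("seed", kwargs["seed"])
                kwargs[name] = _build_section(name, section_cls, section)
            else:
                raise ConfigurationError(f"section {name!r} must be a mapping")
        if payload:
            raise ConfigurationError(
                f"unknown top-level config keys: {sorted(payload)}"
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            payload = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "output_dir": self.output_dir}
        for name in _SECTIONS:
            value = getattr(self, name)
            out[name] = asdict(value) if hasattr(value, "__dataclass_fields__") else value
        return out

    def stamp(self, directory: str | Path) -> None:
        """Echo config, seed, and software versions into an output directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "run_config.yaml").write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        (directory / "versions.json").write_text(
            json.dumps(
                {
                    "python": platform.python_version(),
                    "numpy": np.__version__,
                    "woodxrf": _package_version(),
                    "seed": self.seed,
                },
                indent=2,
            )
        )


def _package_version() -> str:
    from . import __version__

    return __version__
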