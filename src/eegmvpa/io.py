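"""Epochs container file format and pipeline configuration.

Epochs round-trip through a self-describing HDF5 container (versioned
schema string; named arrays for data, time axis, labels, channel names and
validity mask; metadata as attributes).  Pipeline configuration is a YAML
document with one section per analysis stage; unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import yaml

from .containers import EpochSet
from .decode import DecodeParams
from .permstats import ClusterTestParams
from .preprocess import PreprocessParams
from .simulate import SimulationConfig

__all__ = [
    "EPOCHS_SCHEMA",
    "SchemaError",
    "write_epochs",
    "read_epochs",
    "RsaParams",
    "PipelineConfig",
    "load_config",
]

EPOCHS_SCHEMA = "eegmvpa-epochs-1"

_REQUIRED_DATASETS = ("data", "times_ms", "labels", "channel_names", "valid_mask")


class SchemaError(ValueError):
    """A container or configuration file violates the expected schema."""


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to the HDF5 epochs container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = EPOCHS_SCHEMA
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["sampling_rate_hz"] = float(epochs.sampling_rate)
        f.attrs["units"] = epochs.units
        f.attrs["meta_json"] = json.dumps(epochs.meta, default=str)
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times_ms", data=epochs.times)
        f.create_dataset("labels", data=np.asarray(epochs.labels, dtype=np.int64))
        f.create_dataset(
            "channel_names",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
        )
        f.create_dataset("valid_mask", data=epochs.valid_mask)


def read_epochs(path: str | Path) -> EpochSet:
    """Read an epochs container, validating the schema field by field."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema") != EPOCHS_SCHEMA:
            raise SchemaError(
                f"{path}: unknown or missing schema (expected {EPOCHS_SCHEMA!r})"
            )
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise SchemaError(f"{path}: missing dataset {name!r}")
        data = f["data"][()]
        times = f["times_ms"][()]
        labels = f["labels"][()]
        channel_names = [
            s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_names"][()]
        ]
        valid_mask = f["valid_mask"][()].astype(bool)
        meta = json.loads(f.attrs.get("meta_json", "{}"))
        try:
            return EpochSet(
                data=data,
                times=times,
                labels=labels,
                channel_names=channel_names,
                sampling_rate=float(f.attrs["sampling_rate_hz"]),
                subject_id=str(f.attrs.get("subject_id", "")),
                valid_mask=valid_mask,
                units=str(f.attrs.get("units", "uV")),
                meta=meta,
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc}") from exc


@dataclass
class RsaParams:
    """RSA-stage settings: analysis windows and noise-ceiling resolution."""

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"early": (80.0, 200.0), "late": (200.0, 400.0)}
    )
    n_splits: int = 100
    n_null: int = 1000
    n_model_features: int = 2000

    def __post_init__(self) -> None:
        self.windows = {
            str(k): (float(v[0]), float(v[1])) for k, v in self.windows.items()
        }
        for name, (lo, hi) in self.windows.items():
            if not hi > lo:
                raise ValueError(f"empty window {name!r}")
        if self.n_splits < 1 or self.n_null < 1:
            raise ValueError("n_splits and n_null must be positive")


@dataclass
class PipelineConfig:
    """Top-level configuration tying the stages together."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    decode: DecodeParams = field(default_factory=DecodeParams)
    stats: ClusterTestParams = field(default_factory=ClusterTestParams)
    rsa: RsaParams = field(default_factory=RsaParams)
    seed: int = 0


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "preprocess": PreprocessParams,
    "decode": DecodeParams,
    "stats": ClusterTestParams,
    "rsa": RsaParams,
}


def _build_section(cls: type, raw: dict[str, Any], section: str) -> Any:
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(
            f"config section {section!r}: unknown keys {sorted(unknown)}"
        )
    coerced = dict(raw)
    for f in fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            value = coerced[f.name]
            if len(value) == 2 and all(isinstance(v, (int, float)) for v in value):
                coerced[f.name] = (float(value[0]), float(value[1]))
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"config section {section!r}: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config must be a mapping of sections")
    unknown = set(raw) - set(_SECTION_TYPES) - {"seed"}
    if unknown:
        raise SchemaError(f"unknown config sections {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            if not isinstance(raw[section], dict):
                raise SchemaError(f"config section {section!r} must be a mapping")
            kwargs[section] = _build_section(cls, raw[section], section)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return PipelineConfig(**kwargs)
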