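"""File formats and run configuration.

NPZ is the canonical signal container: array ``values`` of shape
(n_samples, n_channels, n_timesteps) in float32 plus an optional int64
``labels`` vector.  Wide CSV (one single-channel signal per row) is
accepted for convenience.  Run configuration round-trips through YAML
with unknown keys rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .diffusion import TrainConfig
from .signal_sim import SimConfig
from .types import SignalSet
from .unet import UNetConfig

__all__ = ["read_signal_set", "write_signal_set", "RunConfig"]


def read_signal_set(path) -> SignalSet:
    """Read a SignalSet from NPZ (values [+ labels]) or wide CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        table = np.loadtxt(path, delimiter=",", ndmin=2)
        values = table[:, None, :].astype(np.float32)
        labels = None
    else:
        with np.load(path) as npz:
            if "values" not in npz.files:
                raise KeyError(f"{path} has no 'values' array (found {npz.files})")
            values = npz["values"].astype(np.float32)
            labels = npz["labels"].astype(np.int64) if "labels" in npz.files else None
    if values.ndim == 2:
        values = values[:, None, :]
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[:10]
        raise ValueError(f"{path} contains non-finite values at indices {bad.tolist()}")
    return SignalSet(values=values, labels=labels)


def write_signal_set(signal_set: SignalSet, path, label_csv: bool = False) -> None:
    """Write a SignalSet as NPZ (deterministic bytes for a fixed input)."""
    if signal_set.n_samples == 0:
        raise ValueError("refusing to write an empty SignalSet")
    path = Path(path)
    arrays = {"values": signal_set.values.astype(np.float32)}
    if signal_set.labels is not None:
        arrays["labels"] = signal_set.labels.astype(np.int64)
    np.savez(path, **arrays)
    if label_csv and signal_set.labels is not None:
        csv_path = path.with_suffix(".labels.csv")
        np.savetxt(csv_path, signal_set.labels, fmt="%d", header="label", comments="")


def _from_mapping(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Top-level configuration tying simulator, training and model together."""

    mode: str = "uncond"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)

    def __post_init__(self):
        if self.mode not in ("uncond", "label", "signal"):
            raise ValueError(f"mode must be uncond|label|signal, got {self.mode!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown RunConfig keys: {sorted(unknown)}")
        for key, sub in (("sim", SimConfig), ("train", TrainConfig), ("unet", UNetConfig)):
            if key in data and isinstance(data[key], dict):
                sub_data = dict(data[key])
                if key == "unet" and "channel_mults" in sub_data:
                    sub_data["channel_mults"] = tuple(sub_data["channel_mults"])
                if key == "unet" and sub_data.get("attention") is not None:
                    sub_data["attention"] = tuple(sub_data["attention"])
                data[key] = _from_mapping(sub, sub_data)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["unet"]["channel_mults"] = list(d["unet"]["channel_mults"])
        if d["unet"]["attention"] is not None:
            d["unet"]["attention"] = list(d["unet"]["attention"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
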