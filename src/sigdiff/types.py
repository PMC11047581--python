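"""Core data container shared by every module."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SignalSet"]


@dataclass
class SignalSet:
    """A batch of multichannel signals with optional integer class labels.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_channels, n_timesteps)``.
    labels
        Optional integer vector of length ``n_samples``.
    channel_names
        Optional channel identifiers (length ``n_channels``).
    """

    values: np.ndarray
    labels: np.ndarray | None = None
    channel_names: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(
                f"values must be (n_samples, n_channels, n_timesteps), got shape {self.values.shape}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[:10]
            raise ValueError(f"non-finite values at indices {bad.tolist()}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match n_samples {self.values.shape[0]}")
        if self.channel_names is not None and len(self.channel_names) != self.values.shape[1]:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[2]

    def subset(self, indices) -> "SignalSet":
        idx = np.asarray(indices)
        return SignalSet(
            values=self.values[idx],
            labels=None if self.labels is None else self.labels[idx],
            channel_names=self.channel_names,
        )

    def class_counts(self) -> dict[int, int]:
        if self.labels is None:
            raise ValueError("SignalSet has no labels")
        uniq, counts = np.unique(self.labels, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}
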