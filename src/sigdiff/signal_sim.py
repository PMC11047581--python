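"""Synthetic cylinder/bell/funnel (CBF) signal generator and degradations.

The simulator produces the five-class benchmark family used throughout the
package: each signal is a flat baseline carrying one or two events built
from the three classical CBF primitives (plateau, linear ramp-up, linear
ramp-down).  Class identity is carried by the event shape; per-signal
variation comes from jittered event boundaries, a random event amplitude
and additive white noise.

Degradations model the noise families encountered in biosignal recording:
thermal (white) noise, baseline wander from varying electrode contact,
sparse motion-artifact spikes, masked gaps (missing samples), and reduced
sampling rate.  Degraded signals keep the original array shape so they can
be used directly as conditioning inputs to the diffusion model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import SignalSet

__all__ = [
    "SimConfig", "DegradationSpec", "class_template", "generate_simulated",
    "degrade", "make_imbalanced", "CLASS_NAMES",
]

CLASS_NAMES = ["cylinder", "bell", "funnel", "bell_funnel", "two_cylinders"]


@dataclass
class SimConfig:
    """Parameters of the simulated CBF dataset.

    Defaults give 512-timestep, single-channel signals in five classes.
    ``amp_var`` and ``pattern_var`` are variances (amplitude units squared
    and samples squared); ``noise_sd`` is a standard deviation.
    """

    n_per_class: int = 100
    length: int = 512
    n_channels: int = 1
    n_classes: int = 5
    amp_mean: float = 1.0
    amp_var: float = 0.04
    pattern_var: float = 25.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.length < 16:
            raise ValueError(f"length must be >= 16, got {self.length}")
        if not 1 <= self.n_classes <= 5:
            raise ValueError(f"n_classes must be in [1, 5], got {self.n_classes}")
        if self.amp_var < 0 or self.pattern_var < 0 or self.noise_sd < 0:
            raise ValueError("variances and noise_sd must be non-negative")
        if self.n_per_class < 1 or self.n_channels < 1:
            raise ValueError("n_per_class and n_channels must be positive")


@dataclass
class DegradationSpec:
    """One named degradation with its kind-specific parameters."""

    kind: str
    magnitude: float = 0.0
    gap_fraction: float = 0.0
    factor: int = 2
    seed: int = 0

    _KINDS = ("thermal", "baseline_wander", "motion_artifact", "mask_gaps", "downsample")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown degradation kind {self.kind!r}; choose from {self._KINDS}")
        if self.kind == "mask_gaps" and not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must lie in [0, 1)")
        if self.kind == "downsample" and self.factor < 2:
            raise ValueError("downsample factor must be >= 2")


def _event_window(length: int) -> tuple[float, float]:
    return 0.25 * length, 0.70 * length


def class_template(label: int, length: int, amp: float = 1.0,
                   onset: float | None = None, offset: float | None = None) -> np.ndarray:
    """Noiseless, jitter-free shape of one class (single channel).

    Class 0: cylinder (plateau); 1: bell (linear rise then drop);
    2: funnel (jump then linear decay); 3: bell followed by funnel;
    4: two separated cylinders.
    """
    t = np.arange(length, dtype=np.float64)
    a_def, b_def = _event_window(length)
    a = a_def if onset is None else onset
    b = b_def if offset is None else offset
    a = float(np.clip(a, 1, length - 3))
    b = float(np.clip(b, a + 2, length - 1))
    x = np.zeros(length)
    inside = (t >= a) & (t < b)
    if label == 0:          # cylinder
        x[inside] = amp
    elif label == 1:        # bell: ramp 0 -> amp, then drop
        x[inside] = amp * (t[inside] - a) / (b - a)
    elif label == 2:        # funnel: jump to amp, decay -> 0
        x[inside] = amp * (b - t[inside]) / (b - a)
    elif label == 3:        # bell then funnel, split window
        mid = 0.5 * (a + b)
        first = (t >= a) & (t < mid)
        second = (t >= mid) & (t < b)
        x[first] = amp * (t[first] - a) / (mid - a)
        x[second] = amp * (b - t[second]) / (b - mid)
    elif label == 4:        # two cylinders with a gap between
        w = (b - a) / 3.0
        x[(t >= a) & (t < a + w)] = amp
        x[(t >= b - w) & (t < b)] = amp
    else:
        raise ValueError(f"label must be in [0, 5), got {label}")
    return x


def generate_simulated(config: SimConfig) -> SignalSet:
    """Generate the simulated CBF dataset described by ``config``.

    Returns ``n_classes * n_per_class`` signals with labels
    ``0..n_classes-1``, grouped by class along the first axis.  Event
    boundaries are jittered with sd ``sqrt(pattern_var)`` samples, the
    amplitude is drawn from N(amp_mean, amp_var) and white noise with sd
    ``noise_sd`` is added to every channel.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_classes * config.n_per_class
    values = np.empty((n, config.n_channels, config.length), dtype=np.float64)
    labels = np.repeat(np.arange(config.n_classes), config.n_per_class)
    jitter_sd = float(np.sqrt(config.pattern_var))
    amp_sd = float(np.sqrt(config.amp_var))
    a_def, b_def = _event_window(config.length)
    for i, lab in enumerate(labels):
        amp = rng.normal(config.amp_mean, amp_sd)
        onset = a_def + rng.normal(0.0, jitter_sd)
        offset = b_def + rng.normal(0.0, jitter_sd)
        base = class_template(int(lab), config.length, amp, onset, offset)
        noise = rng.normal(0.0, config.noise_sd,
                           size=(config.n_channels, config.length))
        values[i] = base[None, :] + noise
    return SignalSet(values=values, labels=labels)


def degrade(signals: SignalSet, spec: DegradationSpec
            ) -> tuple[SignalSet, np.ndarray | None]:
    """Apply one degradation; returns (degraded set, observation mask or None).

    The mask (1 = observed, 0 = masked) is returned only for ``mask_gaps``.
    Output arrays always have the input's shape.
    """
    rng = np.random.default_rng(spec.seed)
    x = signals.values.astype(np.float64)
    n, c, L = x.shape
    mask = None
    if spec.kind == "thermal":
        out = x + rng.normal(0.0, 1.0, size=x.shape) * spec.magnitude
    elif spec.kind == "baseline_wander":
        t = np.arange(L)
        out = x.copy()
        for i in range(n):
            n_comp = 3
            weights = rng.dirichlet(np.ones(n_comp)) * spec.magnitude
            periods = rng.uniform(L / 4.0, 2.0 * L, size=n_comp)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_comp)
            drift = sum(w * np.sin(2.0 * np.pi * t / p + ph)
                        for w, p, ph in zip(weights, periods, phases))
            out[i] += drift[None, :]
    elif spec.kind == "motion_artifact":
        out = x.copy()
        rate = max(1.0, L / 128.0)   # a handful of spikes per signal
        for i in range(n):
            for ch in range(c):
                k = rng.poisson(rate)
                for _ in range(k):
                    pos = rng.integers(0, L)
                    width = rng.integers(1, 4)
                    amp = spec.magnitude * rng.gamma(4.0, 0.25)
                    sign = rng.choice([-1.0, 1.0])
                    out[i, ch, pos:pos + width] += sign * amp
    elif spec.kind == "mask_gaps":
        out = x.copy()
        mask = np.ones_like(x)
        total_gap = int(round(spec.gap_fraction * L))
        if total_gap > 0:
            for i in range(n):
                for ch in range(c):
                    m = _gap_mask(L, total_gap, rng)
                    mask[i, ch] = m
                    out[i, ch] *= m
    elif spec.kind == "downsample":
        if spec.factor >= L:
            raise ValueError(f"downsample factor {spec.factor} >= length {L}")
        kept_t = np.union1d(np.arange(0, L, spec.factor), [L - 1])
        full_t = np.arange(L)
        out = np.empty_like(x)
        for i in range(n):
            for ch in range(c):
                out[i, ch] = np.interp(full_t, kept_t, x[i, ch, kept_t])
    else:  # pragma: no cover - spec validation makes this unreachable
        raise ValueError(spec.kind)
    return SignalSet(values=out, labels=signals.labels,
                     channel_names=signals.channel_names), mask


def _gap_mask(length: int, total_gap: int, rng: np.random.Generator) -> np.ndarray:
    """Binary mask with 1-3 contiguous zero runs totalling exactly total_gap."""
    n_runs = int(rng.integers(1, min(3, total_gap) + 1))
    cuts = np.sort(rng.choice(np.arange(1, total_gap), size=n_runs - 1, replace=False)) \
        if n_runs > 1 else np.array([], dtype=int)
    run_lengths = np.diff(np.concatenate([[0], cuts, [total_gap]]))
    free = length - total_gap
    # distribute the observed samples into n_runs+1 segments around the gaps
    seg = rng.multinomial(free, np.ones(n_runs + 1) / (n_runs + 1))
    mask = np.ones(length)
    pos = 0
    for s, g in zip(seg[:-1], run_lengths):
        pos += int(s)
        mask[pos:pos + int(g)] = 0.0
        pos += int(g)
    return mask


def make_imbalanced(signals: SignalSet, keep_fractions: dict[int, float] | list[float],
                    seed: int = 0) -> SignalSet:
    """Subsample classes without replacement to the given keep fractions."""
    if signals.labels is None:
        raise ValueError("make_imbalanced requires a labelled SignalSet")
    rng = np.random.default_rng(seed)
    counts = signals.class_counts()
    if not isinstance(keep_fractions, dict):
        keep_fractions = {cls: f for cls, f in zip(sorted(counts), keep_fractions)}
    keep_idx: list[np.ndarray] = []
    for cls in sorted(counts):
        frac = float(keep_fractions.get(cls, 1.0))
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"keep fraction for class {cls} must be in (0, 1], got {frac}")
        cls_idx = np.flatnonzero(signals.labels == cls)
        n_keep = int(round(frac * len(cls_idx)))
        if n_keep == 0:
            raise ValueError(f"class {cls} would become empty (fraction {frac})")
        keep_idx.append(np.sort(rng.choice(cls_idx, size=n_keep, replace=False)))
    return signals.subset(np.concatenate(keep_idx))
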