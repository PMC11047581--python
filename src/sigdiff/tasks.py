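"""Applied pipelines built on the conditional diffusion models.

* Signal-conditional restoration: denoising, gap imputation (with exact
  copy-back of observed samples) and upsampling of low-resolution signals.
* Label-conditional augmentation: synthesising the deficit of
  under-represented classes and re-training a fixed small 1D-CNN
  classifier to measure the effect on per-class F1.

Signal-conditional training pairs are formed on the fly: every epoch each
clean signal is degraded afresh by the task's degradation spec, so the
model learns the degradation family rather than a fixed pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diffusion import ModelCheckpoint, TrainConfig, sample, train
from .metrics import ClassMetrics, classification_report
from .nn import Adam, Conv1d, Linear, Module, Tensor
from .signal_sim import DegradationSpec, degrade
from .types import SignalSet

__all__ = [
    "TaskResult", "AugmentationPlan", "CNNClassifierConfig",
    "train_signal_conditional", "denoise", "impute", "upsample",
    "balance_with_synthesis", "imbalance_experiment", "train_cnn_classifier",
]


@dataclass
class TaskResult:
    restored: SignalSet
    reference: SignalSet | None
    mse_before: float
    mse_after: float


@dataclass
class AugmentationPlan:
    per_class_target: dict[int, int]
    generated_counts: dict[int, int] = field(default_factory=dict)


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)) ** 2))


# ------------------------------------------------------ signal-conditional train
def train_signal_conditional(dataset: SignalSet, specs: list[DegradationSpec],
                             config: TrainConfig, model) -> ModelCheckpoint:
    """Train a signal-mode diffusion model on (clean, degraded) pairs.

    Each epoch every clean signal is degraded by one spec drawn uniformly
    from ``specs`` with a fresh seed, so conditioning covers the whole
    degradation family.
    """

    def condition_fn(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        spec = specs[int(rng.integers(len(specs)))]
        spec_seeded = DegradationSpec(kind=spec.kind, magnitude=spec.magnitude,
                                      gap_fraction=spec.gap_fraction,
                                      factor=spec.factor,
                                      seed=int(rng.integers(2**31)))
        degraded, _ = degrade(SignalSet(values), spec_seeded)
        return degraded.values.astype(np.float64)

    ckpt = train(dataset, config, mode="signal", model=model,
                 condition_fn=condition_fn)
    ckpt.history["degradations"] = [
        {"kind": s.kind, "magnitude": s.magnitude,
         "gap_fraction": s.gap_fraction, "factor": s.factor} for s in specs]
    return ckpt


def _require_signal_mode(checkpoint: ModelCheckpoint) -> None:
    if checkpoint.mode != "signal":
        raise ValueError(f"task requires a signal-mode model, got {checkpoint.mode!r}")


# ------------------------------------------------------------------ restoration
def _conditional_restore(cond_set: SignalSet, checkpoint: ModelCheckpoint,
                         seed: int, n_avg: int) -> SignalSet:
    """Posterior-mean restoration: average ``n_avg`` conditional samples."""
    draws = [sample(checkpoint, cond_set.n_samples,
                    condition={"signal": cond_set.values}, seed=seed + 1000 * k).values
             for k in range(n_avg)]
    return SignalSet(np.mean(draws, axis=0), labels=cond_set.labels,
                     channel_names=cond_set.channel_names)


def denoise(noisy: SignalSet, checkpoint: ModelCheckpoint,
            reference: SignalSet | None = None, seed: int = 0,
            n_avg: int = 4) -> TaskResult:
    """Restore noisy signals by conditional sampling on the noisy input."""
    _require_signal_mode(checkpoint)
    restored = _conditional_restore(noisy, checkpoint, seed, n_avg)
    mse_before = _mse(noisy.values, reference.values) if reference else np.nan
    mse_after = _mse(restored.values, reference.values) if reference else np.nan
    return TaskResult(restored=restored, reference=reference,
                      mse_before=mse_before, mse_after=mse_after)


def impute(gappy: SignalSet, mask: np.ndarray, checkpoint: ModelCheckpoint,
           reference: SignalSet | None = None, seed: int = 0,
           n_avg: int = 4) -> TaskResult:
    """Fill masked gaps by conditional sampling; observed samples are
    copied back from the input verbatim, so only gaps are synthesised."""
    _require_signal_mode(checkpoint)
    mask = np.asarray(mask)
    if mask.shape != gappy.values.shape:
        raise ValueError(f"mask shape {mask.shape} != signals {gappy.values.shape}")
    restored = _conditional_restore(gappy, checkpoint, seed, n_avg)
    out = restored.values.copy()
    observed = mask > 0
    out[observed] = gappy.values[observed]
    restored = SignalSet(out, labels=gappy.labels, channel_names=gappy.channel_names)
    mse_before = _mse(gappy.values, reference.values) if reference else np.nan
    mse_after = _mse(restored.values, reference.values) if reference else np.nan
    return TaskResult(restored=restored, reference=reference,
                      mse_before=mse_before, mse_after=mse_after)


def upsample(lowres: SignalSet, factor: int, checkpoint: ModelCheckpoint,
             reference: SignalSet | None = None, seed: int = 0,
             n_avg: int = 4) -> TaskResult:
    """Super-resolve signals that were downsampled by ``factor`` and
    linearly re-interpolated to the model's native length."""
    _require_signal_mode(checkpoint)
    trained = checkpoint.history.get("degradations")
    if trained is not None:
        factors = [d["factor"] for d in trained if d["kind"] == "downsample"]
        if factors and factor not in factors:
            raise ValueError(
                f"model was trained for downsample factors {factors}, got {factor}")
    restored = _conditional_restore(lowres, checkpoint, seed, n_avg)
    mse_before = _mse(lowres.values, reference.values) if reference else np.nan
    mse_after = _mse(restored.values, reference.values) if reference else np.nan
    return TaskResult(restored=restored, reference=reference,
                      mse_before=mse_before, mse_after=mse_after)


# ----------------------------------------------------------------- augmentation
def balance_with_synthesis(train_set: SignalSet, checkpoint: ModelCheckpoint,
                           plan: AugmentationPlan, seed: int = 0) -> SignalSet:
    """Top up each class to its target count with label-conditional samples.

    The result is the input plus synthetic deficit samples, shuffled with
    the given seed; per-class counts equal the plan targets exactly.
    """
    if checkpoint.mode != "label":
        raise ValueError("balance_with_synthesis requires a label-mode model")
    if train_set.labels is None:
        raise ValueError("training set must be labelled")
    counts = train_set.class_counts()
    n_model_classes = checkpoint.model.config.n_classes
    values = [train_set.values]
    labels = [train_set.labels]
    plan.generated_counts = {}
    rng = np.random.default_rng(seed)
    for cls, target in sorted(plan.per_class_target.items()):
        have = counts.get(cls, 0)
        if cls >= n_model_classes:
            raise ValueError(f"class {cls} outside the model's label set")
        deficit = int(target) - have
        if deficit < 0:
            raise ValueError(
                f"class {cls} already has {have} > target {target} samples")
        plan.generated_counts[cls] = deficit
        if deficit == 0:
            continue
        synth = sample(checkpoint, deficit, condition={"label": cls},
                       seed=int(rng.integers(2**31)))
        values.append(synth.values)
        labels.append(np.full(deficit, cls, dtype=np.int64))
    if all(d == 0 for d in plan.generated_counts.values()):
        return train_set  # nothing to synthesise
    merged = SignalSet(np.concatenate(values), np.concatenate(labels),
                       channel_names=train_set.channel_names)
    order = rng.permutation(merged.n_samples)
    return merged.subset(order)


# ------------------------------------------------------------- CNN classifier
@dataclass
class CNNClassifierConfig:
    """Fixed small 1D-CNN: two conv-pool blocks and a dense head."""

    channels: tuple[int, int] = (16, 32)
    kernel: int = 5
    hidden: int = 64
    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0


class _CNN1d(Module):
    def __init__(self, in_channels: int, length: int, n_classes: int,
                 cfg: CNNClassifierConfig, rng: np.random.Generator):
        c1, c2 = cfg.channels
        pad = cfg.kernel // 2
        self.conv1 = Conv1d(in_channels, c1, cfg.kernel, rng, padding=pad)
        self.conv2 = Conv1d(c1, c2, cfg.kernel, rng, padding=pad)
        flat = c2 * (length // 4)
        self.fc1 = Linear(flat, cfg.hidden, rng)
        self.fc2 = Linear(cfg.hidden, n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu().maxpool1d(2)
        h = self.conv2(h).relu().maxpool1d(2)
        h = h.reshape(h.shape[0], h.shape[1] * h.shape[2])
        return self.fc2(self.fc1(h).relu())


def train_cnn_classifier(train_set: SignalSet, n_classes: int,
                         cfg: CNNClassifierConfig | None = None):
    """Train the fixed 1D-CNN; returns a ``predict(values) -> labels`` callable."""
    cfg = cfg or CNNClassifierConfig()
    if train_set.labels is None:
        raise ValueError("classifier training requires labels")
    rng = np.random.default_rng(cfg.seed)
    x = train_set.values.astype(np.float64)
    mu, sd = x.mean(), x.std() + 1e-8
    xs = (x - mu) / sd
    y = train_set.labels
    model = _CNN1d(train_set.n_channels, train_set.n_timesteps, n_classes,
                   cfg, np.random.default_rng(cfg.seed + 1))
    opt = Adam(model.parameters(), lr=cfg.lr, grad_clip=5.0)
    onehot = np.eye(n_classes)[y]
    for _ in range(cfg.epochs):
        order = rng.permutation(len(y))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model(Tensor(xs[idx]))
            loss = -(logits.log_softmax(axis=1) * Tensor(onehot[idx])).sum() * (1.0 / len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()

    def predict(values: np.ndarray) -> np.ndarray:
        v = (np.asarray(values, dtype=np.float64) - mu) / sd
        out = np.empty(len(v), dtype=np.int64)
        for start in range(0, len(v), 256):
            out[start:start + 256] = model(Tensor(v[start:start + 256])).data.argmax(axis=1)
        return out

    return predict


def imbalance_experiment(train_set: SignalSet, test_set: SignalSet,
                         checkpoint: ModelCheckpoint, plan: AugmentationPlan,
                         classifier_config: CNNClassifierConfig | None = None,
                         seed: int = 0) -> dict[str, ClassMetrics]:
    """Per-class F1 before/after rebalancing the training set with synthesis.

    The same fixed CNN architecture and seed are used for both fits, and
    both are evaluated on the untouched test set.  Any signal appearing in
    both train and test (exact duplicate rows) is treated as leakage.
    """
    if train_set.labels is None or test_set.labels is None:
        raise ValueError("both sets must be labelled")
    train_rows = {row.tobytes() for row in
                  np.ascontiguousarray(train_set.values.reshape(train_set.n_samples, -1))}
    for row in np.ascontiguousarray(test_set.values.reshape(test_set.n_samples, -1)):
        if row.tobytes() in train_rows:
            raise ValueError("leakage: a test signal also appears in the training set")
    n_classes = int(max(train_set.labels.max(), test_set.labels.max())) + 1
    cfg = classifier_config or CNNClassifierConfig()
    cfg_seeded = CNNClassifierConfig(**{**vars(cfg), "seed": seed})

    predict_before = train_cnn_classifier(train_set, n_classes, cfg_seeded)
    before = classification_report(test_set.labels,
                                   predict_before(test_set.values), n_classes)

    balanced = balance_with_synthesis(train_set, checkpoint, plan, seed=seed)
    predict_after = train_cnn_classifier(balanced, n_classes, cfg_seeded)
    after = classification_report(test_set.labels,
                                  predict_after(test_set.values), n_classes)
    return {"before": before, "after": after}
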