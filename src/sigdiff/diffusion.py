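"""Denoising-diffusion mathematics, training and ancestral sampling.

The forward process corrupts a signal x0 with Gaussian noise over T steps,

    q(x_t | x_{t-1}) = N(x_t; sqrt(1 - beta_t) x_{t-1}, beta_t I),

whose closed-form marginal is x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps
with abar_t the cumulative product of alpha_t = 1 - beta_t.  The learned
reverse kernel p(x_{t-1} | x_t) is Gaussian with mean

    mu = (x_t - beta_t / sqrt(1 - abar_t) * eps_theta) / sqrt(alpha_t)

and a diagonal variance log-interpolated between the posterior variance
btilde_t = (1 - abar_{t-1}) / (1 - abar_t) * beta_t and beta_t by a
network output v in [0, 1].  Training minimises the hybrid objective
L_simple + lambda * L_vlb, where L_simple is the mean squared error of the
noise prediction and L_vlb is the per-step KL term of the evidence lower
bound, evaluated with the mean detached so that it trains only the
variance head.

Timesteps are 1..T in the mathematics; arrays are stored 0..T-1, so the
table entry for step t lives at index t-1.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Adam, Tensor
from .types import SignalSet

__all__ = [
    "DiffusionSchedule", "NoiseModelOutput", "ReverseMoments", "LossBreakdown",
    "TrainConfig", "Normalizer", "ModelCheckpoint", "make_schedule", "q_sample",
    "iterate_forward", "reverse_moments", "gaussian_kl", "elbo_loss", "train",
    "sample", "save_checkpoint", "load_checkpoint",
]


# --------------------------------------------------------------------- schedule
@dataclass
class DiffusionSchedule:
    """Precomputed beta/alpha tables for a T-step diffusion."""

    T: int
    beta: np.ndarray          # beta_t,        index t-1
    alpha: np.ndarray         # 1 - beta_t
    alpha_bar: np.ndarray     # prod_{s<=t} alpha_s
    beta_tilde: np.ndarray    # posterior variance, beta_tilde_1 = 0

    @property
    def log_beta(self) -> np.ndarray:
        return np.log(self.beta)

    @property
    def log_beta_tilde_clipped(self) -> np.ndarray:
        """log beta_tilde with the t=1 entry floored at beta_tilde_2.

        beta_tilde_1 is exactly zero, whose log is -inf; the first entry is
        replaced by the t=2 value so the variance interpolation stays finite.
        The t=1 reverse step itself is taken deterministically.
        """
        bt = self.beta_tilde.copy()
        if self.T >= 2:
            bt[0] = bt[1]
        else:
            bt[0] = self.beta[0]
        return np.log(bt)


def make_schedule(T: int, schedule_kind: str = "linear") -> DiffusionSchedule:
    """Build a linear (1e-4 -> 0.02) or squared-cosine beta schedule."""
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    if schedule_kind == "linear":
        beta = np.linspace(1e-4, 0.02, T)
    elif schedule_kind == "cosine":
        s = 0.008
        steps = np.arange(T + 1, dtype=np.float64)
        f = np.cos((steps / T + s) / (1.0 + s) * np.pi / 2.0) ** 2
        abar = f / f[0]
        beta = np.clip(1.0 - abar[1:] / abar[:-1], 0.0, 0.999)
    else:
        raise ValueError(f"unknown schedule_kind {schedule_kind!r}")
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    abar_prev = np.concatenate([[1.0], alpha_bar[:-1]])
    beta_tilde = (1.0 - abar_prev) / (1.0 - alpha_bar) * beta
    return DiffusionSchedule(T=T, beta=beta, alpha=alpha,
                             alpha_bar=alpha_bar, beta_tilde=beta_tilde)


def _check_t(t: np.ndarray | int, T: int) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=np.int64))
    if (t < 1).any() or (t > T).any():
        raise ValueError(f"t must lie in [1, {T}]")
    return t


def q_sample(x0: np.ndarray, t: np.ndarray | int, eps: np.ndarray,
             schedule: DiffusionSchedule) -> np.ndarray:
    """Closed-form forward marginal: sqrt(abar_t) x0 + sqrt(1-abar_t) eps."""
    t = _check_t(t, schedule.T)
    abar = schedule.alpha_bar[t - 1].reshape((-1,) + (1,) * (np.ndim(x0) - 1))
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps


def iterate_forward(x0: np.ndarray, t: int, schedule: DiffusionSchedule,
                    rng: np.random.Generator) -> np.ndarray:
    """Apply the single-step forward kernel t times (test oracle for q_sample)."""
    _check_t(t, schedule.T)
    x = np.asarray(x0, dtype=np.float64)
    for step in range(1, int(t) + 1):
        b = schedule.beta[step - 1]
        x = np.sqrt(1.0 - b) * x + np.sqrt(b) * rng.standard_normal(x.shape)
    return x


# ------------------------------------------------------------------ reverse step
@dataclass
class NoiseModelOutput:
    """Per-step network outputs: predicted noise and variance weight in [0,1]."""

    eps_pred: np.ndarray | Tensor
    v_pred: np.ndarray | Tensor


@dataclass
class ReverseMoments:
    mu: np.ndarray
    log_var: np.ndarray


def reverse_moments(xt: np.ndarray, t: int, out: NoiseModelOutput,
                    schedule: DiffusionSchedule) -> ReverseMoments:
    """Mean and log-variance of the learned reverse kernel at step t.

    The variance is the log-linear interpolation
    ``exp(v log beta_t + (1-v) log beta_tilde_t)``; at t=1 the clipped
    posterior variance is used in the interpolation, and sampling treats the
    final step as deterministic.
    """
    _check_t(t, schedule.T)
    ti = int(t) - 1
    eps = out.eps_pred.data if isinstance(out.eps_pred, Tensor) else np.asarray(out.eps_pred)
    v = out.v_pred.data if isinstance(out.v_pred, Tensor) else np.asarray(out.v_pred)
    v = np.clip(v, 0.0, 1.0)
    beta = schedule.beta[ti]
    abar = schedule.alpha_bar[ti]
    mu = (xt - beta / np.sqrt(1.0 - abar) * eps) / np.sqrt(schedule.alpha[ti])
    log_var = v * np.log(beta) + (1.0 - v) * schedule.log_beta_tilde_clipped[ti]
    return ReverseMoments(mu=mu, log_var=log_var)


def posterior_moments(x0: np.ndarray, xt: np.ndarray, t: int,
                      schedule: DiffusionSchedule) -> tuple[np.ndarray, float]:
    """Mean and variance of the true posterior q(x_{t-1} | x_t, x0)."""
    _check_t(t, schedule.T)
    ti = int(t) - 1
    beta = schedule.beta[ti]
    abar = schedule.alpha_bar[ti]
    abar_prev = 1.0 if ti == 0 else schedule.alpha_bar[ti - 1]
    coef0 = np.sqrt(abar_prev) * beta / (1.0 - abar)
    coeft = np.sqrt(schedule.alpha[ti]) * (1.0 - abar_prev) / (1.0 - abar)
    return coef0 * x0 + coeft * xt, float(schedule.beta_tilde[ti])


def gaussian_kl(mu_q, log_var_q, mu_p, log_var_p):
    """Elementwise KL( N(mu_q, var_q) || N(mu_p, var_p) ) for diagonal Gaussians."""
    return 0.5 * (log_var_p - log_var_q
                  + np.exp(log_var_q - log_var_p)
                  + (mu_q - mu_p) ** 2 * np.exp(-log_var_p) - 1.0)


# ------------------------------------------------------------------------- loss
@dataclass
class LossBreakdown:
    total: Tensor
    simple: float
    vlb: float
    per_term_kl: np.ndarray | None = None


def elbo_loss(x0: np.ndarray, model, schedule: DiffusionSchedule,
              rng: np.random.Generator, lambda_vlb: float = 1e-3,
              condition=None) -> LossBreakdown:
    """Hybrid diffusion loss on one batch.

    ``simple`` is the mean squared error between the drawn noise and the
    network prediction at a uniformly sampled step per example.  ``vlb`` is
    the per-step KL between the Gaussian posterior q(x_{t-1}|x_t,x0) and the
    learned reverse kernel (Gaussian NLL of x0 at t=1), computed with the
    predicted mean detached so it trains only the variance output.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    B = x0.shape[0]
    t = rng.integers(1, schedule.T + 1, size=B)
    eps = rng.standard_normal(x0.shape)
    xt = q_sample(x0, t, eps, schedule)
    out = model(xt, t, condition)
    eps_pred, v_pred = out.eps_pred, out.v_pred

    diff = eps_pred - Tensor(eps)
    simple = (diff * diff).mean()

    ti = t - 1
    shape1 = (-1,) + (1,) * (x0.ndim - 1)
    beta = schedule.beta[ti].reshape(shape1)
    alpha = schedule.alpha[ti].reshape(shape1)
    abar = schedule.alpha_bar[ti].reshape(shape1)
    log_beta = np.log(beta)
    log_btilde = schedule.log_beta_tilde_clipped[ti].reshape(shape1)

    eps_det = eps_pred.data  # stop-gradient on the mean
    mu_p = (xt - beta / np.sqrt(1.0 - abar) * eps_det) / np.sqrt(alpha)
    log_var_p = v_pred * Tensor(log_beta) + (1.0 - v_pred) * Tensor(log_btilde)

    abar_prev = np.concatenate([[1.0], schedule.alpha_bar[:-1]])[ti].reshape(shape1)
    coef0 = np.sqrt(abar_prev) * beta / (1.0 - abar)
    coeft = np.sqrt(alpha) * (1.0 - abar_prev) / (1.0 - abar)
    mu_q = coef0 * x0 + coeft * xt
    var_q = schedule.beta_tilde[ti].reshape(shape1)

    delta = Tensor(mu_q - mu_p)
    is_t1 = (t == 1).reshape(shape1)
    # KL(q || p) for t > 1 (var_q > 0); Gaussian NLL of x0 under p at t = 1
    log_var_q = np.log(np.where(var_q > 0, var_q, 1.0))
    kl = 0.5 * (log_var_p - Tensor(log_var_q)
                + (Tensor(var_q) + delta * delta) * (-1.0 * log_var_p).exp()
                - 1.0)
    nll = 0.5 * (Tensor(np.log(2.0 * np.pi)) + log_var_p
                 + Tensor((x0 - mu_p) ** 2) * (-1.0 * log_var_p).exp())
    w1 = Tensor(is_t1.astype(np.float64))
    vlb = (w1 * nll + (1.0 - w1) * kl).mean()

    total = simple + lambda_vlb * vlb
    if not np.isfinite(total.data):
        raise FloatingPointError(
            f"non-finite diffusion loss (simple={simple.data}, vlb={vlb.data}, "
            f"t range [{t.min()}, {t.max()}])")
    return LossBreakdown(total=total, simple=float(simple.data),
                         vlb=float(vlb.data))


# ------------------------------------------------------------------ train config
@dataclass
class TrainConfig:
    T: int = 100
    schedule_kind: str = "linear"
    lr: float = 2e-3
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 10
    lambda_vlb: float = 1e-3
    val_fraction: float = 0.1
    ema_decay: float | None = None
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.T < 10:
            raise ValueError("T must be >= 10 for training")


@dataclass
class Normalizer:
    """Per-channel affine map of the training data onto [-1, 1]."""

    low: np.ndarray    # (n_channels,)
    high: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "Normalizer":
        low = values.min(axis=(0, 2)).astype(np.float64)
        high = values.max(axis=(0, 2)).astype(np.float64)
        flat = high - low < 1e-12
        # a constant channel is centred (maps to 0) rather than pinned at -1
        low = np.where(flat, low - 1.0, low)
        high = np.where(flat, high + 1.0, high)
        return cls(low=low, high=high)

    def forward(self, values: np.ndarray) -> np.ndarray:
        lo = self.low[None, :, None]
        hi = self.high[None, :, None]
        return 2.0 * (values - lo) / (hi - lo) - 1.0

    def inverse(self, values: np.ndarray) -> np.ndarray:
        lo = self.low[None, :, None]
        hi = self.high[None, :, None]
        return (values + 1.0) / 2.0 * (hi - lo) + lo


@dataclass
class ModelCheckpoint:
    model: object                  # sigdiff.unet.UNet1d
    schedule: DiffusionSchedule
    config: TrainConfig
    normalizer: Normalizer
    mode: str                      # uncond | label | signal
    history: dict = field(default_factory=dict)


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train(dataset: SignalSet, config: TrainConfig, mode: str = "uncond",
          model=None, condition_fn=None, verbose: bool = False) -> ModelCheckpoint:
    """Train a noise-prediction model with early stopping on validation loss.

    Parameters
    ----------
    dataset
        Training signals (labels required for ``mode='label'``).
    mode
        ``uncond``, ``label`` (class-conditional) or ``signal``
        (condition on a degraded copy of each example).
    model
        A network with signature ``model(xt, t, condition) -> NoiseModelOutput``
        built by :func:`sigdiff.unet.build_unet`.  Required.
    condition_fn
        For ``mode='signal'``: callable ``(values, rng) -> cond_values``
        producing the degraded conditioning signals (in original units)
        for a batch of clean signals; called afresh every epoch so the
        model sees the degradation family rather than fixed pairs.
    """
    if model is None:
        raise ValueError("train() requires a model (see sigdiff.unet.build_unet)")
    if mode not in ("uncond", "label", "signal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "label" and dataset.labels is None:
        raise ValueError("label mode requires a labelled dataset")
    if mode == "signal" and condition_fn is None:
        raise ValueError("signal mode requires condition_fn")

    rng = np.random.default_rng(config.seed)
    schedule = make_schedule(config.T, config.schedule_kind)
    norm = Normalizer.fit(dataset.values)
    x_all = norm.forward(dataset.values.astype(np.float64))
    n = x_all.shape[0]
    n_val = max(1, int(round(config.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    opt = Adam(model.parameters(), lr=config.lr, grad_clip=config.grad_clip)
    ema_state = ({k: v.copy() for k, v in model.state_dict().items()}
                 if config.ema_decay else None)
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    since_improve = 0
    history = {"train_total": [], "train_simple": [], "val_total": [], "val_simple": []}

    def batch_condition(idx, epoch_rng):
        if mode == "uncond":
            return None
        if mode == "label":
            return {"label": dataset.labels[idx]}
        cond = condition_fn(dataset.values[idx].astype(np.float64), epoch_rng)
        return {"signal": norm.forward(cond)}

    for epoch in range(config.max_epochs):
        ep_rng = np.random.default_rng(rng.integers(2**31))
        tot, simp, nb = 0.0, 0.0, 0
        for idx in _epoch_batches(len(train_idx), config.batch_size, ep_rng):
            bidx = train_idx[idx]
            cond = batch_condition(bidx, ep_rng)
            try:
                loss = elbo_loss(x_all[bidx], model, schedule, ep_rng,
                                 config.lambda_vlb, condition=cond)
            except FloatingPointError:
                warnings.warn("training diverged; returning last good checkpoint")
                model.load_state_dict(best_state)
                return ModelCheckpoint(model, schedule, config, norm, mode, history)
            opt.zero_grad()
            loss.total.backward()
            opt.step()
            if ema_state is not None:
                d = config.ema_decay
                for name, p in model.named_parameters():
                    ema_state[name] *= d
                    ema_state[name] += (1.0 - d) * p.data
            tot += float(loss.total.data)
            simp += loss.simple
            nb += 1
        history["train_total"].append(tot / nb)
        history["train_simple"].append(simp / nb)

        # fixed validation RNG: the same (t, eps) draws each epoch make the
        # validation curve comparable across epochs for early stopping
        val_rng = np.random.default_rng(config.seed + 10_000)
        cond = batch_condition(val_idx, val_rng)
        vloss = elbo_loss(x_all[val_idx], model, schedule, val_rng,
                          config.lambda_vlb, condition=cond)
        history["val_total"].append(float(vloss.total.data))
        history["val_simple"].append(vloss.simple)
        if verbose:
            print(f"epoch {epoch + 1}: train {tot / nb:.5f}  val {vloss.total.data:.5f}")

        if float(vloss.total.data) < best_val - 1e-6:
            best_val = float(vloss.total.data)
            best_state = ({k: v.copy() for k, v in ema_state.items()}
                          if ema_state is not None else model.state_dict())
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break

    model.load_state_dict(best_state)
    history["best_epoch"] = best_epoch
    history["epochs_run"] = len(history["train_total"])
    return ModelCheckpoint(model=model, schedule=schedule, config=config,
                           normalizer=norm, mode=mode, history=history)


# --------------------------------------------------------------------- sampling
def sample(checkpoint: ModelCheckpoint, n: int, condition=None,
           seed: int = 0) -> SignalSet:
    """Ancestral sampling: x_T ~ N(0, I), then iterate the reverse kernel.

    ``condition`` is ``None`` (uncond mode), ``{"label": int or array}``
    (label mode) or ``{"signal": values in original units}`` (signal mode).
    Returned values are mapped back to original units.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = checkpoint.model
    schedule = checkpoint.schedule
    rng = np.random.default_rng(seed)
    C, L = model.in_channels, model.length
    cond = _prepare_condition(checkpoint, n, condition)
    x = rng.standard_normal((n, C, L))
    for t in range(schedule.T, 0, -1):
        out = model(x, np.full(n, t), cond)
        mom = reverse_moments(x, t, out, schedule)
        if t > 1:
            x = mom.mu + np.exp(0.5 * mom.log_var) * rng.standard_normal(x.shape)
        else:
            x = mom.mu
    values = checkpoint.normalizer.inverse(x)
    labels = None
    if cond is not None and "label" in cond:
        labels = np.asarray(cond["label"], dtype=np.int64)
    return SignalSet(values=values, labels=labels)


def _prepare_condition(checkpoint: ModelCheckpoint, n: int, condition):
    mode = checkpoint.mode
    if mode == "uncond":
        if condition:
            raise ValueError("unconditional model accepts no condition")
        return None
    if mode == "label":
        if not condition or "label" not in condition:
            raise ValueError("label-mode sampling requires {'label': ...}")
        lab = np.asarray(condition["label"], dtype=np.int64)
        if lab.ndim == 0:
            lab = np.full(n, int(lab))
        if lab.shape != (n,):
            raise ValueError(f"label vector must have length {n}")
        return {"label": lab}
    if not condition or "signal" not in condition:
        raise ValueError("signal-mode sampling requires {'signal': ...}")
    sig = np.asarray(condition["signal"], dtype=np.float64)
    if sig.shape[0] != n:
        raise ValueError(f"conditioning batch must have {n} signals")
    if sig.shape[-1] != checkpoint.model.length:
        raise ValueError(
            f"conditioning length {sig.shape[-1]} != model length {checkpoint.model.length}")
    return {"signal": checkpoint.normalizer.forward(sig)}


# ------------------------------------------------------------------ persistence
def save_checkpoint(checkpoint: ModelCheckpoint, path) -> None:
    """Write a checkpoint as a single NPZ archive (weights + metadata)."""
    from .unet import UNetConfig  # local import to avoid a cycle

    meta = {
        "mode": checkpoint.mode,
        "train_config": asdict(checkpoint.config),
        "unet_config": asdict(checkpoint.model.config),
        "history": {k: v for k, v in checkpoint.history.items()},
    }
    arrays = {f"param::{k}": v for k, v in checkpoint.model.state_dict().items()}
    arrays.update(
        beta=checkpoint.schedule.beta,
        norm_low=checkpoint.normalizer.low,
        norm_high=checkpoint.normalizer.high,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelCheckpoint:
    from .unet import UNetConfig, build_unet

    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    tcfg = TrainConfig(**meta["train_config"])
    ucfg_d = meta["unet_config"]
    ucfg_d["channel_mults"] = tuple(ucfg_d["channel_mults"])
    ucfg = UNetConfig(**ucfg_d)
    model = build_unet(ucfg, seed=0)
    state = {k[len("param::"):]: v for k, v in arrays.items() if k.startswith("param::")}
    model.load_state_dict(state)
    schedule = make_schedule(tcfg.T, tcfg.schedule_kind)
    if not np.allclose(schedule.beta, arrays["beta"]):
        schedule = DiffusionSchedule(
            T=len(arrays["beta"]), beta=arrays["beta"], alpha=1.0 - arrays["beta"],
            alpha_bar=np.cumprod(1.0 - arrays["beta"]),
            beta_tilde=np.concatenate([[0.0], (1.0 - np.cumprod(1.0 - arrays["beta"])[:-1])
                                       / (1.0 - np.cumprod(1.0 - arrays["beta"])[1:])
                                       * arrays["beta"][1:]]))
    norm = Normalizer(low=arrays["norm_low"], high=arrays["norm_high"])
    return ModelCheckpoint(model=model, schedule=schedule, config=tcfg,
                           normalizer=norm, mode=meta["mode"],
                           history=meta.get("history", {}))
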