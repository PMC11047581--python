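"""Validation metrics for synthetic signal sets.

Four complementary views of real-vs-synthetic similarity:

* **Wavelet coherence** - time-scale-resolved normalised cross-spectrum of
  a signal pair in [0, 1], aggregated over random pairs into a 0-100 set
  score.  Smoothing in time (scale-dependent Gaussian) and across scales
  (3-point boxcar) is essential: the unsmoothed single-realisation
  coherence is identically one.
* **Discriminative score** - |held-out accuracy - 0.5| of a 2-layer LSTM
  trained to tell real from synthetic; 0 means indistinguishable, 0.5
  perfectly separable.
* **UMAP overlay** - a joint 2-D embedding of both sets for visual
  comparison of their occupied feature space.
* **Per-class precision/recall/F1** with macro averaging, used by the
  class-imbalance experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .nn import Adam, LSTMClassifier, Tensor
from .types import SignalSet

__all__ = [
    "CoherenceMap", "CoherenceReport", "DiscriminativeReport", "ClassMetrics",
    "WaveletParams", "DiscriminativeConfig", "wavelet_coherence_pair",
    "set_coherence_score", "discriminative_score", "umap_overlay",
    "classification_report",
]


# ---------------------------------------------------------------- wavelet score
@dataclass
class WaveletParams:
    """Morlet (omega0 = 6) continuous wavelet transform on a dyadic scale grid."""

    omega0: float = 6.0
    dj: float = 0.25          # scales per octave spacing
    s0: float = 2.0           # smallest scale, in samples
    scale_smooth: int = 3     # boxcar width across adjacent scales


@dataclass
class CoherenceMap:
    values: np.ndarray        # (n_scales, n_times) in [0, 1]
    scales: np.ndarray
    times: np.ndarray


@dataclass
class CoherenceReport:
    score: float              # 0-100
    n_pairs: int
    per_pair: np.ndarray | None = None


def _cwt(x: np.ndarray, scales: np.ndarray, omega0: float) -> np.ndarray:
    # pywt's 'cmorB-C' is (pi*B)^(-1/2) exp(2i*pi*C*t) exp(-t^2/B); B=2, C =
    # omega0/(2*pi) reproduce the standard Morlet exp(i*omega0*t) exp(-t^2/2)
    center = omega0 / (2.0 * np.pi)
    wavelet = f"cmor2.0-{center:.6f}"
    coef, _ = pywt.cwt(x, scales, wavelet)
    return coef


def _smooth(power: np.ndarray, scales: np.ndarray, scale_smooth: int) -> np.ndarray:
    out = np.empty_like(power)
    for i, s in enumerate(scales):
        out[i] = gaussian_filter1d(power[i].real, sigma=max(s, 0.5), mode="nearest")
        if np.iscomplexobj(power):
            out[i] = out[i] + 1j * gaussian_filter1d(power[i].imag, sigma=max(s, 0.5),
                                                     mode="nearest")
    if scale_smooth > 1:
        out = uniform_filter1d(out.real, scale_smooth, axis=0, mode="nearest") + (
            1j * uniform_filter1d(out.imag, scale_smooth, axis=0, mode="nearest")
            if np.iscomplexobj(power) else 0.0)
    return out


def wavelet_coherence_pair(x: np.ndarray, y: np.ndarray,
                           params: WaveletParams | None = None) -> CoherenceMap:
    """Smoothed magnitude-squared wavelet coherence of two 1-D signals.

    Coherence = |S(Wx conj(Wy))|^2 / (S(|Wx|^2) S(|Wy|^2)), with S the
    time- and scale-smoothing operator; values are clipped to [0, 1].
    Constant (zero-power) inputs yield coherence 0 with a warning.
    """
    params = params or WaveletParams()
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    L = x.size
    n_oct = np.log2(L / params.s0)
    scales = params.s0 * 2.0 ** (params.dj * np.arange(int(n_oct / params.dj) + 1))
    if x.std() < 1e-12 or y.std() < 1e-12:
        warnings.warn("constant signal: coherence defined as 0")
        return CoherenceMap(values=np.zeros((scales.size, L)), scales=scales,
                            times=np.arange(L))
    wx = _cwt(x - x.mean(), scales, params.omega0)
    wy = _cwt(y - y.mean(), scales, params.omega0)
    # 1/s weighting before smoothing, as usual for rectified wavelet spectra
    inv_s = (1.0 / scales)[:, None]
    s_xy = _smooth(wx * np.conj(wy) * inv_s, scales, params.scale_smooth)
    s_xx = _smooth((np.abs(wx) ** 2) * inv_s, scales, params.scale_smooth).real
    s_yy = _smooth((np.abs(wy) ** 2) * inv_s, scales, params.scale_smooth).real
    denom = s_xx * s_yy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(s_xy) ** 2 / denom
    coh[denom <= 1e-300] = 0.0
    return CoherenceMap(values=np.clip(coh, 0.0, 1.0), scales=scales,
                        times=np.arange(L))


def set_coherence_score(real: SignalSet, synth: SignalSet, n_pairs: int = 1000,
                        seed: int = 0, pairing: str = "random",
                        params: WaveletParams | None = None) -> CoherenceReport:
    """0-100 set-similarity score: mean wavelet coherence over signal pairs.

    ``pairing='random'`` draws ``n_pairs`` (real, synth) index pairs with a
    seeded generator; ``pairing='identity'`` pairs equal indices (sets must
    then have equal size).  Multichannel signals average over channels.
    """
    if real.n_samples == 0 or synth.n_samples == 0:
        raise ValueError("both signal sets must be non-empty")
    if real.n_channels != synth.n_channels or real.n_timesteps != synth.n_timesteps:
        raise ValueError("sets must share channel count and length")
    first, second = real, synth
    if pairing == "identity":
        if real.n_samples != synth.n_samples:
            raise ValueError("identity pairing requires equal set sizes")
        pairs = np.stack([np.arange(real.n_samples)] * 2, axis=1)
    elif pairing == "random":
        # canonical set order (by content digest) before drawing indices, so
        # the score is exactly invariant to the order of its two arguments
        import hashlib
        da = hashlib.md5(np.ascontiguousarray(real.values)).hexdigest()
        db = hashlib.md5(np.ascontiguousarray(synth.values)).hexdigest()
        if db < da:
            first, second = synth, real
        rng = np.random.default_rng(seed)
        k = min(n_pairs, first.n_samples * second.n_samples)
        pairs = np.stack([rng.integers(0, first.n_samples, size=k),
                          rng.integers(0, second.n_samples, size=k)], axis=1)
    else:
        raise ValueError("pairing must be 'random' or 'identity'")
    per_pair = np.empty(len(pairs))
    for j, (i_r, i_s) in enumerate(pairs):
        chans = [wavelet_coherence_pair(first.values[i_r, c], second.values[i_s, c],
                                        params).values.mean()
                 for c in range(first.n_channels)]
        per_pair[j] = float(np.mean(chans))
    return CoherenceReport(score=100.0 * float(per_pair.mean()),
                           n_pairs=len(pairs), per_pair=per_pair)


# --------------------------------------------------------- discriminative score
@dataclass
class DiscriminativeConfig:
    hidden: int = 64
    n_layers: int = 2
    max_epochs: int = 30
    patience: int = 5
    lr: float = 5e-3
    test_fraction: float = 0.2
    val_fraction: float = 0.2      # of the training part, for early stopping
    max_seq_len: int = 128         # longer sequences are strided down


@dataclass
class DiscriminativeReport:
    score: float                   # |test accuracy - 0.5| in [0, 0.5]
    test_accuracy: float
    n_train: int
    n_test: int


def _stratified_split(labels: np.ndarray, test_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def discriminative_score(real: SignalSet, synth: SignalSet,
                         config: DiscriminativeConfig | None = None,
                         seed: int = 0) -> DiscriminativeReport:
    """Train a 2-layer LSTM to separate real (label 1) from synthetic (0).

    The pooled set is split 80/20 stratified; the classifier early-stops on
    a held-out part of the training split; the reported score is
    |held-out test accuracy - 0.5|.
    """
    config = config or DiscriminativeConfig()
    if real.n_samples < 16 or synth.n_samples < 16:
        raise ValueError("discriminative score needs >= 16 signals per set")
    x = np.concatenate([real.values, synth.values], axis=0).astype(np.float64)
    y = np.concatenate([np.ones(real.n_samples), np.zeros(synth.n_samples)])
    stride = max(1, int(np.ceil(x.shape[2] / config.max_seq_len)))
    x = x[:, :, ::stride].transpose(0, 2, 1)        # (B, L, C)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _stratified_split(y, config.test_fraction, rng)
    fit_idx, val_idx = _stratified_split(y[train_idx], config.val_fraction, rng)
    fit_idx, val_idx = train_idx[fit_idx], train_idx[val_idx]

    mu = x[fit_idx].mean(axis=(0, 1), keepdims=True)
    sd = x[fit_idx].std(axis=(0, 1), keepdims=True)
    sd = np.where(sd < 1e-8, 1.0, sd)
    xs = (x - mu) / sd

    clf = LSTMClassifier(x.shape[2], config.hidden, config.n_layers,
                         np.random.default_rng(seed + 1))
    opt = Adam(clf.parameters(), lr=config.lr, grad_clip=5.0)

    def bce(idx) -> Tensor:
        z = clf(Tensor(xs[idx]))
        yt = Tensor(y[idx])
        return -(yt * z.logsigmoid() + (1.0 - yt) * (-1.0 * z).logsigmoid()).mean()

    best_val, best_state, since = np.inf, clf.state_dict(), 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(fit_idx)
        for start in range(0, len(order), 64):
            loss = bce(order[start:start + 64])
            opt.zero_grad()
            loss.backward()
            opt.step()
        vloss = float(bce(val_idx).data)
        if vloss < best_val - 1e-6:
            best_val, best_state, since = vloss, clf.state_dict(), 0
        else:
            since += 1
            if since >= config.patience:
                break
    clf.load_state_dict(best_state)

    z = clf(Tensor(xs[test_idx])).data
    acc = float(((z > 0).astype(float) == y[test_idx]).mean())
    return DiscriminativeReport(score=abs(acc - 0.5), test_accuracy=acc,
                                n_train=len(train_idx), n_test=len(test_idx))


# ---------------------------------------------------------------- UMAP overlay
def umap_overlay(real: SignalSet, synth: SignalSet, n_neighbors: int = 15,
                 min_dist: float = 0.1, seed: int = 0, plot_path=None):
    """Joint 2-D UMAP embedding of flattened real and synthetic signals.

    Returns a DataFrame with columns (sample_id, origin, dim1, dim2); if
    ``plot_path`` is given, also writes a two-colour scatter plot.
    """
    import pandas as pd
    from umap import UMAP

    if real.n_samples == 0 or synth.n_samples == 0:
        raise ValueError("both signal sets must be non-empty")
    feats = np.concatenate([
        real.values.reshape(real.n_samples, -1),
        synth.values.reshape(synth.n_samples, -1),
    ]).astype(np.float64)
    n = feats.shape[0]
    if n_neighbors >= n:
        warnings.warn(f"n_neighbors {n_neighbors} >= n_samples {n}; shrinking")
        n_neighbors = max(2, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = UMAP(n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
                   random_state=seed).fit_transform(feats)
    origin = np.array(["real"] * real.n_samples + ["synthetic"] * synth.n_samples)
    table = pd.DataFrame({
        "sample_id": np.arange(n), "origin": origin,
        "dim1": emb[:, 0], "dim2": emb[:, 1],
    })
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        for name, color in (("real", "tab:red"), ("synthetic", "tab:blue")):
            sub = table[table.origin == name]
            ax.scatter(sub.dim1, sub.dim2, s=10, alpha=0.6, label=name, c=color)
        ax.legend()
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return table


# ------------------------------------------------------------------- F1 report
@dataclass
class ClassMetrics:
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float


def classification_report(y_true, y_pred, n_classes: int) -> ClassMetrics:
    """Per-class one-vs-rest precision, recall and F1 = 2TP/(2TP+FP+FN).

    The 0/0 convention maps undefined ratios to 0.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    for c in range(n_classes):
        tp[c] = int(((y_pred == c) & (y_true == c)).sum())
        fp[c] = int(((y_pred == c) & (y_true != c)).sum())
        fn[c] = int(((y_pred != c) & (y_true == c)).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        r = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        f1 = np.where(2 * tp + fp + fn > 0,
                      2 * tp / np.maximum(2 * tp + fp + fn, 1), 0.0)
    return ClassMetrics(
        tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1,
        macro_precision=float(p.mean()), macro_recall=float(r.mean()),
        macro_f1=float(f1.mean()),
        accuracy=float((y_true == y_pred).mean()) if y_true.size else 0.0,
    )
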