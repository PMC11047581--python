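"""Evaluation metrics: coherence identities, discriminative score, F1, UMAP."""

import numpy as np
import pytest

from sigdiff.metrics import (classification_report, discriminative_score,
                             set_coherence_score, umap_overlay,
                             wavelet_coherence_pair, DiscriminativeConfig)
from sigdiff.signal_sim import SimConfig, class_template, generate_simulated
from sigdiff.types import SignalSet

rng = np.random.default_rng(0)


# ------------------------------------------------------------ wavelet coherence
def test_self_coherence_is_perfect():
    x = class_template(1, 512) + rng.normal(0, 0.05, 512)
    m = wavelet_coherence_pair(x, x)
    assert m.values.mean() > 0.99
    assert m.values.min() >= 0.0 and m.values.max() <= 1.0


def test_independent_white_noise_has_low_coherence():
    vals = [wavelet_coherence_pair(rng.normal(size=512), rng.normal(size=512)).values.mean()
            for _ in range(10)]
    assert np.mean(vals) < 0.6


def test_small_lag_preserves_high_coherence():
    x = class_template(1, 512) + rng.normal(0, 0.05, 512)
    y = np.roll(x, 5)
    lagged = wavelet_coherence_pair(x, y).values
    # long scales (bottom rows of the map) stay near-coherent under small lag
    assert lagged[-8:, :].mean() > 0.9


def test_coherence_bounds_on_arbitrary_input():
    x = np.zeros(256)
    x[64] = 100.0  # a single spike
    y = rng.standard_normal(256) * 50
    m = wavelet_coherence_pair(x, y)
    assert np.all(m.values >= 0.0) and np.all(m.values <= 1.0)


def test_constant_signal_yields_zero_coherence_with_warning():
    with pytest.warns(UserWarning):
        m = wavelet_coherence_pair(np.ones(128), rng.normal(size=128))
    assert np.all(m.values == 0.0)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        wavelet_coherence_pair(np.zeros(64), np.zeros(128))


@pytest.fixture(scope="module")
def cbf_sets():
    a = generate_simulated(SimConfig(n_per_class=16, n_classes=1, length=128, seed=1))
    b = generate_simulated(SimConfig(n_per_class=16, n_classes=1, length=128, seed=2))
    return a, b


def test_set_coherence_identity_pairing_is_100(cbf_sets):
    a, _ = cbf_sets
    rep = set_coherence_score(a, a, pairing="identity")
    assert abs(rep.score - 100.0) < 1e-9
    assert rep.n_pairs == a.n_samples


def test_set_score_separates_real_from_noise(cbf_sets):
    a, b = cbf_sets
    noise = SignalSet(rng.normal(size=(16, 1, 128)))
    within = set_coherence_score(a, b, n_pairs=40, seed=0).score
    vs_noise = set_coherence_score(a, noise, n_pairs=40, seed=0).score
    assert within > vs_noise + 10


def test_set_score_is_symmetric(cbf_sets):
    a, b = cbf_sets
    ab = set_coherence_score(a, b, n_pairs=30, seed=3).score
    ba = set_coherence_score(b, a, n_pairs=30, seed=3).score
    assert ab == pytest.approx(ba, abs=1e-12)


def test_set_score_rejects_empty_or_mismatched(cbf_sets):
    a, _ = cbf_sets
    short = SignalSet(rng.normal(size=(4, 1, 64)))
    with pytest.raises(ValueError):
        set_coherence_score(a, short)


# ---------------------------------------------------------- discriminative score
def test_disjoint_constant_sets_are_perfectly_separable():
    a = SignalSet(np.zeros((32, 1, 64)))
    b = SignalSet(np.ones((32, 1, 64)))
    rep = discriminative_score(a, b, seed=0)
    assert rep.test_accuracy == 1.0
    assert rep.score == 0.5


def test_discriminative_score_range_and_size_guard():
    a = SignalSet(np.zeros((8, 1, 32)))
    with pytest.raises(ValueError):
        discriminative_score(a, a)


# ------------------------------------------------------------------ UMAP overlay
def test_umap_overlay_shape_and_determinism(cbf_sets, tmp_path):
    a, b = cbf_sets
    t1 = umap_overlay(a, b, seed=0, plot_path=tmp_path / "overlay.png")
    assert list(t1.columns) == ["sample_id", "origin", "dim1", "dim2"]
    assert len(t1) == a.n_samples + b.n_samples
    assert (t1.origin == "real").sum() == a.n_samples
    assert (tmp_path / "overlay.png").exists()
    t2 = umap_overlay(a, b, seed=0)
    np.testing.assert_allclose(t1[["dim1", "dim2"]].values,
                               t2[["dim1", "dim2"]].values)


def test_umap_separates_distinct_classes():
    data = generate_simulated(SimConfig(n_per_class=24, n_classes=2, length=64,
                                        seed=5, pattern_var=4.0))
    cls0 = data.subset(np.flatnonzero(data.labels == 0))
    cls1 = data.subset(np.flatnonzero(data.labels == 1))
    table = umap_overlay(cls0, cls1, seed=1)
    xy = table[["dim1", "dim2"]].values
    c0, c1 = xy[:24], xy[24:]
    inter = np.linalg.norm(c0.mean(0) - c1.mean(0))
    intra = 0.5 * (np.linalg.norm(c0 - c0.mean(0), axis=1).mean()
                   + np.linalg.norm(c1 - c1.mean(0), axis=1).mean())
    assert inter > intra


# -------------------------------------------------------------------- F1 report
def _brute_force_report(y_true, y_pred, n_classes):
    """Confusion-matrix oracle computed by explicit enumeration."""
    conf = np.zeros((n_classes, n_classes), dtype=int)
    for yt, yp in zip(y_true, y_pred):
        conf[yt, yp] += 1
    tp = np.diag(conf)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    p = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
    r = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
    f1 = np.where(p + r > 0, 2 * p * r / np.where(p + r > 0, p + r, 1), 0.0)
    return tp, fp, fn, p, r, f1


def test_classification_report_matches_brute_force_oracle():
    g = np.random.default_rng(123)
    for _ in range(1000):
        n = int(g.integers(1, 40))
        k = int(g.integers(2, 6))
        y_true = g.integers(0, k, size=n)
        y_pred = g.integers(0, k, size=n)
        rep = classification_report(y_true, y_pred, k)
        tp, fp, fn, p, r, f1 = _brute_force_report(y_true, y_pred, k)
        np.testing.assert_array_equal(rep.tp, tp)
        np.testing.assert_array_equal(rep.fp, fp)
        np.testing.assert_array_equal(rep.fn, fn)
        np.testing.assert_allclose(rep.precision, p)
        np.testing.assert_allclose(rep.recall, r)
        np.testing.assert_allclose(rep.f1, f1)


def test_classification_report_matches_sklearn():
    from sklearn.metrics import precision_recall_fscore_support
    g = np.random.default_rng(7)
    for _ in range(10):
        y_true = g.integers(0, 4, size=60)
        y_pred = g.integers(0, 4, size=60)
        rep = classification_report(y_true, y_pred, 4)
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(4), zero_division=0)
        np.testing.assert_allclose(rep.precision, p)
        np.testing.assert_allclose(rep.recall, r)
        np.testing.assert_allclose(rep.f1, f1)


def test_classification_report_edge_cases():
    rep = classification_report([0, 1, 2], [0, 1, 2], 3)
    np.testing.assert_array_equal(rep.f1, [1.0, 1.0, 1.0])
    # a class never predicted and never true: 0/0 -> 0 convention
    rep = classification_report([0, 0], [0, 0], 2)
    assert rep.precision[1] == rep.recall[1] == rep.f1[1] == 0.0
    # tp=fp=fn -> p = r = f1 = 0.5
    rep = classification_report([0] * 5 + [1] * 5 + [0] * 5,
                                [0] * 5 + [0] * 5 + [1] * 5, 2)
    assert rep.precision[0] == rep.recall[0] == rep.f1[0] == 0.5
    with pytest.raises(ValueError):
        classification_report([0, 3], [0, 1], 3)
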