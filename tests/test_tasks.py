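"""Restoration and augmentation pipelines, using stub diffusion models.

A stub noise model (eps = 0, v = 0) exercises the task contracts - shape
handling, copy-back, count arithmetic, leakage detection - without the
cost of training; end-to-end restoration quality is covered by the
acceptance tests.
"""

import numpy as np
import pytest

from sigdiff.diffusion import (ModelCheckpoint, NoiseModelOutput, Normalizer,
                               TrainConfig, make_schedule)
from sigdiff.signal_sim import DegradationSpec, SimConfig, degrade, generate_simulated
from sigdiff.tasks import (AugmentationPlan, CNNClassifierConfig, TaskResult,
                           balance_with_synthesis, denoise, impute,
                           imbalance_experiment, train_cnn_classifier, upsample)
from sigdiff.types import SignalSet


class _StubConfig:
    def __init__(self, n_classes=None):
        self.n_classes = n_classes


class _StubModel:
    """Trivial noise model: predicts zero noise and posterior variance."""

    def __init__(self, channels=1, length=32, n_classes=None):
        self.in_channels = channels
        self.length = length
        self.config = _StubConfig(n_classes)

    def __call__(self, xt, t, condition=None):
        x = np.asarray(xt)
        return NoiseModelOutput(eps_pred=np.zeros_like(x), v_pred=np.zeros_like(x))


def _stub_checkpoint(mode, channels=1, length=32, n_classes=None):
    return ModelCheckpoint(
        model=_StubModel(channels, length, n_classes),
        schedule=make_schedule(10),
        config=TrainConfig(T=10, max_epochs=1),
        normalizer=Normalizer(low=np.zeros(channels), high=np.ones(channels)),
        mode=mode)


@pytest.fixture
def gappy_setup():
    data = generate_simulated(SimConfig(n_per_class=6, n_classes=1, length=32, seed=0))
    gappy, mask = degrade(data, DegradationSpec("mask_gaps", gap_fraction=0.25, seed=1))
    return data, gappy, mask


def test_impute_copies_observed_samples_back_verbatim(gappy_setup):
    data, gappy, mask = gappy_setup
    ckpt = _stub_checkpoint("signal")
    result = impute(gappy, mask, ckpt, reference=data, seed=0)
    observed = mask > 0
    np.testing.assert_array_equal(result.restored.values[observed],
                                  gappy.values[observed])
    assert result.mse_before >= 0 and np.isfinite(result.mse_after)


def test_impute_with_no_gaps_returns_input_exactly(gappy_setup):
    data, _, _ = gappy_setup
    ckpt = _stub_checkpoint("signal")
    full_mask = np.ones_like(data.values)
    result = impute(data, full_mask, ckpt, seed=0)
    np.testing.assert_array_equal(result.restored.values, data.values)


def test_impute_rejects_mismatched_mask(gappy_setup):
    data, gappy, mask = gappy_setup
    with pytest.raises(ValueError):
        impute(gappy, mask[:, :, :16], _stub_checkpoint("signal"))


def test_restoration_tasks_require_signal_mode(gappy_setup):
    data, _, _ = gappy_setup
    for fn in (lambda: denoise(data, _stub_checkpoint("uncond")),
               lambda: upsample(data, 2, _stub_checkpoint("label", n_classes=2))):
        with pytest.raises(ValueError):
            fn()


def test_denoise_and_upsample_shapes(gappy_setup):
    data, _, _ = gappy_setup
    ckpt = _stub_checkpoint("signal")
    res = denoise(data, ckpt, reference=data, seed=0)
    assert res.restored.values.shape == data.values.shape
    res = upsample(data, 4, ckpt, reference=data, seed=0)
    assert res.restored.n_timesteps == data.n_timesteps


def test_upsample_factor_mismatch_detected(gappy_setup):
    data, _, _ = gappy_setup
    ckpt = _stub_checkpoint("signal")
    ckpt.history["degradations"] = [{"kind": "downsample", "factor": 4,
                                     "magnitude": 0, "gap_fraction": 0}]
    with pytest.raises(ValueError):
        upsample(data, 2, ckpt)


# ----------------------------------------------------------------- augmentation
@pytest.fixture
def imbalanced_train():
    data = generate_simulated(SimConfig(n_per_class=100, n_classes=2, length=32, seed=3))
    from sigdiff.signal_sim import make_imbalanced
    return make_imbalanced(data, {0: 1.0, 1: 0.1}, seed=0)


def test_balance_with_synthesis_counts_and_labels(imbalanced_train):
    ckpt = _stub_checkpoint("label", n_classes=2)
    plan = AugmentationPlan(per_class_target={0: 100, 1: 100})
    balanced = balance_with_synthesis(imbalanced_train, ckpt, plan, seed=0)
    assert balanced.class_counts() == {0: 100, 1: 100}
    assert plan.generated_counts == {0: 0, 1: 90}


def test_balance_noop_plan_returns_input_reordered(imbalanced_train):
    ckpt = _stub_checkpoint("label", n_classes=2)
    plan = AugmentationPlan(per_class_target=imbalanced_train.class_counts())
    out = balance_with_synthesis(imbalanced_train, ckpt, plan, seed=0)
    assert out.class_counts() == imbalanced_train.class_counts()
    np.testing.assert_array_equal(
        np.sort(out.values.ravel()), np.sort(imbalanced_train.values.ravel()))


def test_balance_rejects_unknown_class(imbalanced_train):
    ckpt = _stub_checkpoint("label", n_classes=2)
    with pytest.raises(ValueError):
        balance_with_synthesis(imbalanced_train, ckpt,
                               AugmentationPlan(per_class_target={2: 10}), seed=0)


# ---------------------------------------------------------- imbalance experiment
def test_cnn_classifier_learns_separable_classes():
    data = generate_simulated(SimConfig(n_per_class=40, n_classes=2, length=32,
                                        seed=5, pattern_var=4.0))
    predict = train_cnn_classifier(data, 2, CNNClassifierConfig(epochs=10, seed=0))
    test = generate_simulated(SimConfig(n_per_class=20, n_classes=2, length=32,
                                        seed=6, pattern_var=4.0))
    acc = (predict(test.values) == test.labels).mean()
    assert acc > 0.9


def test_imbalance_experiment_leakage_detected(imbalanced_train):
    ckpt = _stub_checkpoint("label", n_classes=2)
    plan = AugmentationPlan(per_class_target=imbalanced_train.class_counts())
    with pytest.raises(ValueError, match="leakage"):
        imbalance_experiment(imbalanced_train, imbalanced_train.subset([0, 1]),
                             ckpt, plan)


def test_imbalance_experiment_identical_data_gives_identical_tables():
    train = generate_simulated(SimConfig(n_per_class=20, n_classes=2, length=32, seed=8))
    test = generate_simulated(SimConfig(n_per_class=10, n_classes=2, length=32, seed=9))
    ckpt = _stub_checkpoint("label", n_classes=2)
    plan = AugmentationPlan(per_class_target=train.class_counts())  # no synthesis
    cfg = CNNClassifierConfig(epochs=3)
    out = imbalance_experiment(train, test, ckpt, plan, cfg, seed=0)
    np.testing.assert_allclose(out["before"].f1, out["after"].f1)
    assert np.all(out["before"].f1 >= 0) and np.all(out["before"].f1 <= 1)
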