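"""Finite-difference verification of the autodiff engine.

Every primitive used by the U-Net, the LSTM discriminator and the CNN
classifier is checked against central differences on small random inputs.
"""

import numpy as np
import pytest

from sigdiff.nn import (Adam, Conv1d, Embedding, GroupNorm, LSTMClassifier,
                        Linear, SelfAttention1d, Tensor, concat)
from sigdiff.nn.tensor import embedding_lookup


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        fp = fn()
        flat[i] = old - eps
        fm = fn()
        flat[i] = old
        gf[i] = (fp - fm) / (2 * eps)
    return g


def check_grads(build_loss, tensors: list[Tensor], atol: float = 1e-6, rtol: float = 1e-4):
    loss = build_loss()
    loss.backward()
    for t in tensors:
        num = numeric_grad(lambda: build_loss().item(), t.data)
        assert t.grad is not None, "no gradient reached a parameter"
        np.testing.assert_allclose(t.grad, num, atol=atol, rtol=rtol)


rng = np.random.default_rng(0)


@pytest.mark.parametrize("op", [
    "add", "mul", "matmul", "bmm", "pow", "softmax", "log_softmax",
    "sigmoid", "tanh", "logsigmoid", "relu", "groupish", "getitem",
    "concat", "pad", "upsample", "maxpool",
])
def test_primitive_gradients_match_finite_differences(op):
    a = Tensor(rng.normal(size=(2, 3, 8)), requires_grad=True)
    b = Tensor(rng.normal(size=(2, 3, 8)), requires_grad=True)

    def build():
        if op == "add":
            out = a + b * 2.0 - 1.0
        elif op == "mul":
            out = a * b + a
        elif op == "matmul":
            out = a.reshape(6, 8) @ b.reshape(8, 6)
        elif op == "bmm":
            out = a @ b.swapaxes(1, 2)
        elif op == "pow":
            out = (a * a + 1.0) ** 0.5
        elif op == "softmax":
            out = a.softmax(axis=-1) * b
        elif op == "log_softmax":
            out = a.log_softmax(axis=-1) * b
        elif op == "sigmoid":
            out = a.sigmoid() * b
        elif op == "tanh":
            out = a.tanh() + b.sigmoid()
        elif op == "logsigmoid":
            out = a.logsigmoid() * b
        elif op == "relu":
            out = (a + 0.1).relu() * b  # offset keeps values away from the kink
        elif op == "groupish":
            m = a.mean(axis=2, keepdims=True)
            c = a - m
            out = c * ((c * c).mean(axis=2, keepdims=True) + 1e-3) ** -0.5
        elif op == "getitem":
            out = a[:, 1:, 2:5] * b[:, :2, :3]
        elif op == "concat":
            out = concat([a, b], axis=1) * 0.5
        elif op == "pad":
            out = a.pad_last(2, 3) ** 2
        elif op == "upsample":
            out = a.upsample_nearest(2) ** 2
        elif op == "maxpool":
            out = a.maxpool1d(2) * b.maxpool1d(2)
        return (out * out).sum()

    used = [a] if op in {"pow", "groupish", "pad", "upsample"} else [a, b]
    check_grads(build, used)


def test_conv1d_gradients_and_shapes():
    x = Tensor(rng.normal(size=(2, 3, 10)), requires_grad=True)
    lrng = np.random.default_rng(1)
    conv = Conv1d(3, 4, 3, lrng, stride=2, padding=1)
    out = conv(x)
    assert out.shape == (2, 4, 5)
    check_grads(lambda: (conv(x) ** 2).sum(), [x, conv.weight, conv.bias])


def test_groupnorm_attention_embedding_gradients():
    x = Tensor(rng.normal(size=(2, 4, 6)), requires_grad=True)
    lrng = np.random.default_rng(2)
    gn = GroupNorm(2, 4)
    att = SelfAttention1d(4, lrng, n_norm_groups=2)
    emb = Tensor(rng.normal(size=(5, 4)), requires_grad=True)
    idx = np.array([0, 3])

    def build():
        h = gn(x) + embedding_lookup(emb, idx).reshape(2, 4, 1)
        return (att(h) ** 2).sum()

    check_grads(build, [x, gn.weight, gn.bias, emb,
                        att.qkv.weight, att.qkv.bias], atol=1e-5)


def test_lstm_classifier_gradients():
    x = Tensor(rng.normal(size=(3, 5, 2)), requires_grad=True)
    lrng = np.random.default_rng(3)
    clf = LSTMClassifier(2, 4, 2, lrng)
    y = np.array([1.0, 0.0, 1.0])

    def build():
        z = clf(x)
        yt = Tensor(y)
        return -(yt * z.logsigmoid() + (1.0 - yt) * (-z).logsigmoid()).mean()

    params = [x] + clf.parameters()
    loss = build()
    loss.backward()
    grads = [p.grad.copy() if p.grad is not None else None for p in params]
    assert all(g is not None and np.any(g != 0) for g in grads), \
        "gradient did not reach every LSTM parameter"
    # spot-check a couple of parameters against finite differences
    for p in [x, clf.head.weight, clf.lstm.layers[0].ih.weight]:
        num = numeric_grad(lambda: build().item(), p.data)
        got = grads[params.index(p)]
        np.testing.assert_allclose(got, num, atol=1e-6, rtol=1e-4)


def test_adam_minimises_quadratic():
    w = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([w], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        loss = ((w - Tensor(np.array([1.0, 2.0]))) ** 2).sum()
        loss.backward()
        opt.step()
    np.testing.assert_allclose(w.data, [1.0, 2.0], atol=1e-3)


def test_embedding_rejects_out_of_range():
    e = Embedding(3, 4, np.random.default_rng(0))
    with pytest.raises(IndexError):
        e(np.array([3]))


def test_linear_build_is_deterministic_under_seed():
    a = Linear(4, 5, np.random.default_rng(7))
    b = Linear(4, 5, np.random.default_rng(7))
    np.testing.assert_array_equal(a.weight.data, b.weight.data)
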