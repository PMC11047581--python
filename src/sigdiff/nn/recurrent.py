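"""Stacked LSTM layers for sequence classification."""

from __future__ import annotations

import numpy as np

from .layers import Linear, Module
from .tensor import Tensor, concat

__all__ = ["LSTM", "LSTMClassifier"]


class _LSTMLayer(Module):
    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.ih = Linear(in_features, 4 * hidden, rng)
        self.hh = Linear(hidden, 4 * hidden, rng)
        # forget-gate bias at 1: standard trick for gradient flow early on
        self.hh.bias.data[hidden:2 * hidden] = 1.0

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        B = xs[0].shape[0]
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outputs: list[Tensor] = []
        for x in xs:
            gates = self.ih(x) + self.hh(h)
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h)
        return outputs


class LSTM(Module):
    """`n_layers` stacked LSTMs over input (B, L, F); returns last hidden state."""

    def __init__(self, in_features: int, hidden: int, n_layers: int,
                 rng: np.random.Generator):
        self.layers = [_LSTMLayer(in_features if i == 0 else hidden, hidden, rng)
                       for i in range(n_layers)]

    def __call__(self, x: Tensor) -> Tensor:
        B, L, F = x.shape
        xs = [x[:, t, :] for t in range(L)]
        for layer in self.layers:
            xs = layer(xs)
        return xs[-1]


class LSTMClassifier(Module):
    """Recurrent binary classifier; returns a logit per sequence."""

    def __init__(self, in_features: int, hidden: int, n_layers: int,
                 rng: np.random.Generator):
        self.lstm = LSTM(in_features, hidden, n_layers, rng)
        self.head = Linear(hidden, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(self.lstm(x))[:, 0]
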