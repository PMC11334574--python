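"""Counting head: regress a nonnegative scalar count from the merged tokens.

The merged token matrix T_all is flattened to one vector per image and passed
through

    x1 = ReLU(FC1(flatten(T_all)))
    x2 = FC2(Dropout(x1))
    C_hat = ReLU(mean(x2))

so the network predicts a set of K counts and aggregates them by average
pooling; the terminal ReLU guarantees C_hat >= 0 for any weights and input.
Dropout is active only in training mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class HeadConfig:
    hidden: int = 1024      # FC1 width
    dropout: float = 0.5
    k: int = 64             # size of the predicted count set (len of x2)

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class CountPrediction:
    """Final counts C_hat (N,) and the pre-pooling count vectors x2 (N, K)."""

    count: np.ndarray
    count_set: np.ndarray

    def __post_init__(self):
        assert np.all(self.count >= 0)


class CountingHead(nn.Module):
    def __init__(self, in_dim: int, config: HeadConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.in_dim = in_dim
        self.fc1 = nn.Linear(in_dim, config.hidden, rng)
        self.dropout = nn.Dropout(config.dropout, rng)
        self.fc2 = nn.Linear(config.hidden, config.k, rng)
        # small weights + positive bias keep the initial count set near +1, so
        # the terminal ReLU never zeroes the gradient for every sample at init
        self.fc2.weight.data *= 0.05
        self.fc2.bias.data[:] = 1.0

    def forward(self, t_all: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Return (C_hat (N,), x2 (N, K)) as tensors on the tape."""
        n = t_all.shape[0]
        flat = t_all.reshape(n, int(np.prod(t_all.shape[1:])))
        if flat.shape[1] != self.in_dim:
            raise ValueError(f"token matrix flattens to {flat.shape[1]}, "
                             f"head expects {self.in_dim}")
        x1 = nn.relu(self.fc1(flat))
        x2 = self.fc2(self.dropout(x1))
        c_hat = nn.relu(x2.mean(axis=1))
        return c_hat, x2


def predict_count(t_all: nn.Tensor | np.ndarray, head: CountingHead,
                  train_mode: bool = False) -> CountPrediction:
    """Run the head on a merged token matrix (N, tokens, d)."""
    t = t_all if isinstance(t_all, nn.Tensor) else nn.Tensor(t_all)
    head.train(train_mode)
    c_hat, x2 = head(t)
    return CountPrediction(count=c_hat.data.copy(), count_set=x2.data.copy())
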