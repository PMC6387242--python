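"""Minimal dense-layer toolkit shared by the CNN and VAE stages.

Plain numpy with hand-derived backward passes; training everywhere is
vanilla mini-batch SGD (no momentum, no weight decay), matching the
gradient-descent update rule the classifier stages are defined with.
Gradients are averaged over the batch.  A module-level multiply counter can
be switched on to assert order-of-growth complexity without timing.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

#: operation instrumentation: when enabled, matmul multiply counts accumulate
OP_COUNTER = {"enabled": False, "mults": 0}


def count_mults(n: int) -> None:
    if OP_COUNTER["enabled"]:
        OP_COUNTER["mults"] += int(n)


def reset_op_counter(enabled: bool = True) -> None:
    OP_COUNTER["enabled"] = enabled
    OP_COUNTER["mults"] = 0


def softplus(a: np.ndarray | float) -> np.ndarray | float:
    """ln(1 + e^a), overflow-safe."""
    return np.logaddexp(0.0, a)


def softplus_grad(a: np.ndarray) -> np.ndarray:
    return expit(a)


def relu(a: np.ndarray | float) -> np.ndarray | float:
    return np.maximum(0.0, a)


def relu_grad(a: np.ndarray) -> np.ndarray:
    return (np.asarray(a) > 0).astype(np.asarray(a).dtype)


ACTIVATIONS = {
    "softplus": (softplus, softplus_grad),
    "relu": (relu, relu_grad),
    "identity": (lambda a: a, lambda a: np.ones_like(a)),
}


class Dense:
    """Affine map y = x W^T + b with batched forward/backward."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator | None = None,
        scale: float = 0.01,
        dtype: str = "float64",
    ) -> None:
        if rng is None:
            self.W = np.zeros((n_out, n_in), dtype=dtype)
        else:
            self.W = (rng.standard_normal((n_out, n_in)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    @property
    def n_in(self) -> int:
        return self.W.shape[1]

    @property
    def n_out(self) -> int:
        return self.W.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        count_mults(x.shape[0] * self.W.size)
        return x @ self.W.T + self.b

    def backward(self, x: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Given upstream dJ/dy (already carrying any 1/n factor), return
        (dJ/dW, dJ/db, dJ/dx)."""
        count_mults(2 * x.shape[0] * self.W.size)
        return g.T @ x, g.sum(axis=0), g @ self.W

    def sgd_step(self, dW: np.ndarray, db: np.ndarray, lr: float) -> None:
        self.W -= lr * dW
        self.b -= lr * db


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy; returns (loss, probs, dJ/dlogits)."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(logsumexp - z[np.arange(n), y]))
    probs = softmax(logits)
    g = probs.copy()
    g[np.arange(n), y] -= 1.0
    return loss, probs, g / n


def minibatches(
    n: int, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shuffled index batches covering 0..n-1 once."""
    perm = rng.permutation(n)
    return [perm[i : i + batch_size] for i in range(0, n, batch_size)]
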