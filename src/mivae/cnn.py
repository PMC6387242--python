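"""One-convolutional-layer CNN over time-frequency-channel images.

The kernels span the full image height (Nh) and slide along time only, so
each of the NF filters yields a single output row of length Nt - width + 1
(30 for the 32-frame images and the default width of 3).  The activated
feature maps are max-pooled by a factor of 10 (zero right-padding) and fed
to a two-way dense softmax head.  Training is mini-batch SGD on the
cross-entropy.

The printed output function of this architecture is f(a) = ln(1 + e^a)
(the softplus); it is the default here, with conventional max(0, a)
available via ``activation="relu"``.

The activated, pre-pooling feature maps flattened filter-major (NF x 30 ->
900 values at the defaults) are the feature vectors consumed by the VAE
classifier stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import ACTIVATIONS, Dense, count_mults, minibatches, softmax_xent, softmax
from .representation import ImageSet

__all__ = [
    "CnnConfig",
    "CnnModel",
    "TrainingHistory",
    "init_cnn",
    "conv_forward",
    "activation",
    "max_pool",
    "cnn_forward",
    "train_cnn",
    "extract_features",
    "unflatten_features",
]


@dataclass(frozen=True)
class CnnConfig:
    n_filters: int = 30
    kernel_width: int = 3
    pool_factor: int = 10
    learning_rate: float = 0.05
    epochs: int = 300
    batch_size: int = 50
    seed: int = 0
    activation: str = "softplus"
    init_scale: float = 0.01
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if self.kernel_width < 1:
            raise ValueError("kernel_width must be >= 1")
        if self.pool_factor < 1:
            raise ValueError("pool_factor must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    def conv_len(self, n_frames: int) -> int:
        return n_frames - self.kernel_width + 1

    def feature_dim(self, n_frames: int) -> int:
        """Length of the flattened pre-pooling feature vector."""
        return self.n_filters * self.conv_len(n_frames)

    def pooled_dim(self, n_frames: int) -> int:
        return self.n_filters * int(np.ceil(self.conv_len(n_frames) / self.pool_factor))


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


class CnnModel:
    """Kernels, biases and the dense head; see :func:`init_cnn`."""

    def __init__(self, cfg: CnnConfig, input_shape: tuple[int, int]) -> None:
        nh, nt = input_shape
        if cfg.kernel_width > nt:
            raise ValueError(
                f"kernel_width={cfg.kernel_width} exceeds frame count {nt}"
            )
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.input_shape = (int(nh), int(nt))
        # kernels stored flattened: row k is the Nh x width kernel of filter k
        self.W = (
            rng.standard_normal((cfg.n_filters, nh * cfg.kernel_width))
            * cfg.init_scale
        ).astype(cfg.dtype)
        self.b = np.zeros(cfg.n_filters, dtype=cfg.dtype)
        self.head = Dense(
            cfg.pooled_dim(nt), 2, rng=rng, scale=cfg.init_scale, dtype=cfg.dtype
        )

    @property
    def kernels(self) -> np.ndarray:
        """Kernels as an (NF, Nh, width) array."""
        nh = self.input_shape[0]
        return self.W.reshape(self.cfg.n_filters, nh, self.cfg.kernel_width)


def init_cnn(cfg: CnnConfig, input_shape: tuple[int, int]) -> CnnModel:
    """Zero-mean Gaussian kernels (sd = init_scale), deterministic per seed."""
    return CnnModel(cfg, input_shape)


def activation(a, kind: str = "softplus"):
    """The configured output function: softplus ln(1+e^a) or max(0, a)."""
    return ACTIVATIONS[kind][0](a)


def _im2col(imgs: np.ndarray, width: int) -> np.ndarray:
    """(n, Nh, Nt) -> (n, T_out, Nh*width) sliding time windows."""
    v = np.lib.stride_tricks.sliding_window_view(imgs, width, axis=2)
    n, nh, t_out, _ = v.shape
    return np.ascontiguousarray(v.transpose(0, 2, 1, 3)).reshape(n, t_out, nh * width)


def _as_batch(images) -> tuple[np.ndarray, bool]:
    """Normalize InputImage / ImageSet / array input to (n, Nh, Nt)."""
    if hasattr(images, "pixels"):
        return images.pixels[None], True
    if hasattr(images, "images"):
        return images.images, False
    arr = np.asarray(images)
    if arr.ndim == 2:
        return arr[None], True
    return arr, False


def conv_forward(m: CnnModel, images) -> np.ndarray:
    """Activated valid cross-correlation along time: (n, NF, Nt-width+1).

    A single image (InputImage or 2-D array) yields shape (NF, Nt-width+1).
    """
    arr, single = _as_batch(images)
    if arr.shape[1:] != tuple(m.input_shape):
        raise ValueError(
            f"image shape {arr.shape[1:]} does not match model input "
            f"{tuple(m.input_shape)}"
        )
    col = _im2col(arr.astype(m.cfg.dtype, copy=False), m.cfg.kernel_width)
    count_mults(col.shape[0] * col.shape[1] * m.W.size)
    pre = col @ m.W.T + m.b
    h = ACTIVATIONS[m.cfg.activation][0](pre)
    out = np.ascontiguousarray(h.transpose(0, 2, 1))
    return out[0] if single else out


def max_pool(fm: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping max over the last axis, zero right-padded."""
    if factor < 1:
        raise ValueError("pool factor must be >= 1")
    fm = np.asarray(fm)
    length = fm.shape[-1]
    blocks = int(np.ceil(length / factor))
    pad = blocks * factor - length
    if pad:
        pad_spec = [(0, 0)] * (fm.ndim - 1) + [(0, pad)]
        fm = np.pad(fm, pad_spec, constant_values=0.0)
    return fm.reshape(*fm.shape[:-1], blocks, factor).max(axis=-1)


def _forward_full(m: CnnModel, arr: np.ndarray, col: np.ndarray | None = None):
    """Cached forward pass for training: returns intermediates."""
    if col is None:
        col = _im2col(arr.astype(m.cfg.dtype, copy=False), m.cfg.kernel_width)
    count_mults(col.shape[0] * col.shape[1] * m.W.size)
    pre = col @ m.W.T + m.b  # (n, T_out, NF)
    f, _ = ACTIVATIONS[m.cfg.activation]
    h = f(pre)
    hmap = h.transpose(0, 2, 1)  # (n, NF, T_out)
    pooled = max_pool(hmap, m.cfg.pool_factor)
    flat = pooled.reshape(len(arr), -1)
    logits = m.head.forward(flat)
    return col, pre, hmap, pooled, flat, logits


def cnn_forward(m: CnnModel, images) -> np.ndarray:
    """Class probability pairs (left, right); rows sum to 1."""
    arr, single = _as_batch(images)
    if arr.shape[1:] != tuple(m.input_shape):
        raise ValueError(
            f"image shape {arr.shape[1:]} does not match model input "
            f"{tuple(m.input_shape)}"
        )
    *_, logits = _forward_full(m, arr)
    probs = softmax(logits)
    return probs[0] if single else probs


def cnn_predict(m: CnnModel, images) -> np.ndarray:
    """Argmax labels (ties resolve to class 0)."""
    probs = np.atleast_2d(cnn_forward(m, images))
    return np.argmax(probs, axis=1)


def _loss_and_grads(m: CnnModel, arr: np.ndarray, y: np.ndarray, col: np.ndarray | None = None):
    col, pre, hmap, pooled, flat, logits = _forward_full(m, arr, col)
    loss, _, dlogits = softmax_xent(logits, y)
    dWh, dbh, dflat = m.head.backward(flat, dlogits)
    n, nf, t_out = hmap.shape
    factor = m.cfg.pool_factor
    blocks = pooled.shape[-1]
    dpooled = dflat.reshape(n, nf, blocks)
    # route gradient to the argmax position of each pooling window
    pad = blocks * factor - t_out
    hpad = np.pad(hmap, ((0, 0), (0, 0), (0, pad)), constant_values=0.0) if pad else hmap
    win = hpad.reshape(n, nf, blocks, factor)
    arg = win.argmax(axis=-1)
    dh_pad = np.zeros_like(hpad)
    ii, jj, kk = np.meshgrid(
        np.arange(n), np.arange(nf), np.arange(blocks), indexing="ij"
    )
    dh_pad.reshape(n, nf, blocks, factor)[ii, jj, kk, arg] = dpooled
    dh = dh_pad[..., :t_out]
    _, fgrad = ACTIVATIONS[m.cfg.activation]
    dpre = dh.transpose(0, 2, 1) * fgrad(pre)  # (n, T_out, NF)
    count_mults(2 * col.shape[0] * col.shape[1] * m.W.size)
    dW = np.einsum("ntf,ntj->fj", dpre, col)
    db = dpre.sum(axis=(0, 1))
    acc = float(np.mean(np.argmax(logits, axis=1) == y))
    return loss, acc, {"W": dW, "b": db, "head.W": dWh, "head.b": dbh}


def train_cnn(
    m: CnnModel, images: ImageSet, cfg: CnnConfig | None = None
) -> tuple[CnnModel, TrainingHistory]:
    """Mini-batch SGD on the softmax cross-entropy; trains in place.

    The history records the full-training-set loss and accuracy at the end
    of each epoch.
    """
    cfg = cfg or m.cfg
    arr = images.images.astype(m.cfg.dtype, copy=False)
    y = np.asarray(images.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()
    # images are constant across epochs: lay out the conv windows once
    col_all = _im2col(arr, m.cfg.kernel_width)
    for _ in range(cfg.epochs):
        batch_loss, batch_acc = [], []
        for idx in minibatches(len(arr), cfg.batch_size, rng):
            loss, acc, grads = _loss_and_grads(m, arr[idx], y[idx], col=col_all[idx])
            m.W -= cfg.learning_rate * grads["W"].astype(m.W.dtype)
            m.b -= cfg.learning_rate * grads["b"].astype(m.b.dtype)
            m.head.sgd_step(grads["head.W"], grads["head.b"], cfg.learning_rate)
            batch_loss.append(loss)
            batch_acc.append(acc)
        history.loss.append(float(np.mean(batch_loss)))
        history.accuracy.append(float(np.mean(batch_acc)))
    return m, history


def extract_features(m: CnnModel, images) -> np.ndarray:
    """Flattened pre-pooling conv features, filter-major: (n, NF*(Nt-w+1)).

    With 30 filters and 32 frames at width 3 this is the 900-dimensional
    vector the VAE classifier consumes.
    """
    h = conv_forward(m, images)
    if h.ndim == 2:
        h = h[None]
    return h.reshape(h.shape[0], -1)


def unflatten_features(feat: np.ndarray, n_filters: int) -> np.ndarray:
    """Inverse of the feature flattening: (n, NF, T_out)."""
    feat = np.atleast_2d(feat)
    return feat.reshape(feat.shape[0], n_filters, -1)
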