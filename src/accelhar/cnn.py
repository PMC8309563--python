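"""Per-channel 1D convolutional pipeline, implemented directly in numpy.

Architecture, for window length T and m channels: each channel is
processed by its own convolution block — a 1D convolution with 3
filters of width 20 (stride 1, no padding), ReLU, and max-pooling of
size 3 — then flattened; the per-channel feature maps are concatenated
and fed to two fully connected ReLU layers of 1024 and 30 units,
followed by an l-unit softmax output layer.  For T = 64 this gives a
conv output length of 45, pooled length 15, 45 flattened features per
channel and a 180-wide concatenated representation.

Training minimises class-weighted categorical cross-entropy (the
per-sample weights are normalised by their batch sum, so weighting a
class by w is gradient-equivalent to duplicating its samples w times)
with mini-batch stochastic gradient descent plus momentum.  All
initialisation and shuffling flows from ``CnnConfig.seed``, and the
implementation is plain single-threaded numpy, so seeded runs are
bit-reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class CnnConfig:
    n_filters: int = 3
    kernel_size: int = 20
    pool_size: int = 3
    fc_sizes: tuple[int, int] = (1024, 30)
    n_classes: int = 10
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0


def conv_output_length(t_len: int, kernel: int) -> int:
    return t_len - kernel + 1


def pooled_length(conv_len: int, pool: int) -> int:
    return conv_len // pool


def flat_width(t_len: int, cfg: CnnConfig, m: int) -> int:
    """Concatenated feature width after per-channel conv/pool/flatten."""
    return m * cfg.n_filters * pooled_length(
        conv_output_length(t_len, cfg.kernel_size), cfg.pool_size
    )


@dataclass
class CnnModel:
    """Weights of the per-channel conv net; built by :func:`build_model`."""

    cfg: CnnConfig
    t_len: int
    m: int
    classes: list[str]
    conv_w: list[np.ndarray]  # per channel: (n_filters, kernel)
    conv_b: list[np.ndarray]  # per channel: (n_filters,)
    fc_w: list[np.ndarray]
    fc_b: list[np.ndarray]
    velocity: dict = field(default_factory=dict, repr=False)

    def parameters(self):
        params = {}
        for c in range(self.m):
            params[f"conv_w{c}"] = self.conv_w[c]
            params[f"conv_b{c}"] = self.conv_b[c]
        for i in range(len(self.fc_w)):
            params[f"fc_w{i}"] = self.fc_w[i]
            params[f"fc_b{i}"] = self.fc_b[i]
        return params


def build_model(cfg: CnnConfig, t_len: int, m: int, classes=None) -> CnnModel:
    """Initialise weights with a uniform fan-in scheme from cfg.seed."""
    if cfg.kernel_size > t_len:
        raise ValueError("convolution kernel wider than the window")
    if cfg.pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if classes is None:
        classes = [str(i) for i in range(cfg.n_classes)]
    classes = list(classes)
    rng = np.random.default_rng(cfg.seed)

    def init(shape, fan_in):
        bound = np.sqrt(1.0 / fan_in)
        return rng.uniform(-bound, bound, size=shape)

    conv_w = [init((cfg.n_filters, cfg.kernel_size), cfg.kernel_size) for _ in range(m)]
    conv_b = [np.zeros(cfg.n_filters) for _ in range(m)]
    widths = [flat_width(t_len, cfg, m), *cfg.fc_sizes, len(classes)]
    fc_w = [init((widths[i], widths[i + 1]), widths[i]) for i in range(len(widths) - 1)]
    fc_b = [np.zeros(widths[i + 1]) for i in range(len(widths) - 1)]
    return CnnModel(
        cfg=cfg, t_len=t_len, m=m, classes=classes,
        conv_w=conv_w, conv_b=conv_b, fc_w=fc_w, fc_b=fc_b,
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: CnnModel, x: np.ndarray, cache: bool = False):
    """x: B x T x m -> softmax probabilities (and caches for backprop)."""
    cfg = model.cfg
    pool = cfg.pool_size
    caches = {"windows": [], "relu_mask": [], "pool_arg": [], "flat": None}
    flats = []
    for c in range(model.m):
        win = sliding_window_view(np.ascontiguousarray(x[:, :, c]), cfg.kernel_size, axis=1)
        # win: B x L1 x kernel; conv: B x L1 x F
        conv = win @ model.conv_w[c].T + model.conv_b[c]
        mask = conv > 0
        act = conv * mask
        l1 = act.shape[1]
        l2 = l1 // pool
        trimmed = act[:, : l2 * pool, :].reshape(x.shape[0], l2, pool, cfg.n_filters)
        arg = trimmed.argmax(axis=2)
        pooled = trimmed.max(axis=2)  # B x L2 x F
        flats.append(pooled.reshape(x.shape[0], -1))
        if cache:
            caches["windows"].append(win)
            caches["relu_mask"].append(mask)
            caches["pool_arg"].append(arg)
    h = np.concatenate(flats, axis=1)
    caches["flat"] = h
    activations = [h]
    for i, (w, b) in enumerate(zip(model.fc_w, model.fc_b)):
        z = activations[-1] @ w + b
        if i < len(model.fc_w) - 1:
            z = np.maximum(z, 0.0)
        activations.append(z)
    probs = _softmax(activations[-1])
    if cache:
        caches["fc_acts"] = activations
        return probs, caches
    return probs


def _backward(model: CnnModel, x, probs, y_onehot, sample_w, caches):
    """Gradients of the weighted cross-entropy (normalised by the batch
    weight sum) with respect to every parameter."""
    cfg = model.cfg
    pool = cfg.pool_size
    b = x.shape[0]
    wsum = sample_w.sum()
    grads = {}
    delta = (probs - y_onehot) * (sample_w / wsum)[:, None]  # B x l
    acts = caches["fc_acts"]
    # fully connected stack
    d = delta
    for i in range(len(model.fc_w) - 1, -1, -1):
        grads[f"fc_w{i}"] = acts[i].T @ d
        grads[f"fc_b{i}"] = d.sum(axis=0)
        if i > 0:
            d = d @ model.fc_w[i].T
            d *= acts[i] > 0  # ReLU mask of the hidden activation
    d_flat = d @ model.fc_w[0].T  # gradient w.r.t. concatenated flat features
    per_chan = np.split(d_flat, model.m, axis=1)
    l1 = conv_output_length(model.t_len, cfg.kernel_size)
    l2 = l1 // pool
    for c in range(model.m):
        d_pool = per_chan[c].reshape(b, l2, cfg.n_filters)  # B x L2 x F
        # un-pool: route gradient to the argmax position
        d_act = np.zeros((b, l1, cfg.n_filters))
        arg = caches["pool_arg"][c]  # B x L2 x F
        pos = (np.arange(l2) * pool)[None, :, None] + arg
        bi = np.arange(b)[:, None, None]
        fi = np.arange(cfg.n_filters)[None, None, :]
        np.add.at(d_act, (bi, pos, fi), d_pool)
        d_act *= caches["relu_mask"][c]
        win = caches["windows"][c]  # B x L1 x K
        grads[f"conv_w{c}"] = np.einsum("blk,blf->fk", win, d_act)
        grads[f"conv_b{c}"] = d_act.sum(axis=(0, 1))
    return grads


def loss_and_gradients(model: CnnModel, x, y_idx, sample_w):
    """Weighted cross-entropy loss and parameter gradients on one batch."""
    probs, caches = _forward(model, x, cache=True)
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(y_idx)), y_idx] = 1.0
    wsum = sample_w.sum()
    eps = 1e-12
    loss = -(sample_w * np.log(probs[np.arange(len(y_idx)), y_idx] + eps)).sum() / wsum
    grads = _backward(model, x, probs, onehot, sample_w, caches)
    return loss, grads


def train_cnn(
    model: CnnModel,
    seg,
    class_weights: dict | None = None,
    cfg: CnnConfig | None = None,
) -> CnnModel:
    """Train with mini-batch SGD + momentum; returns a new model.

    ``seg`` is a SegmentTensor whose labels must all appear in
    ``model.classes``.  With ``epochs = 0`` the returned model equals
    the initialised one.
    """
    cfg = cfg or model.cfg
    x = seg.values
    labels = seg.labels.astype(str)
    classes = model.classes
    unknown = set(labels) - set(classes)
    if unknown:
        raise ValueError(f"labels not in model classes: {sorted(unknown)}")
    if len(np.unique(labels)) < 2:
        raise ValueError("CNN training needs at least 2 classes")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_to_idx[c] for c in labels])
    if class_weights is None:
        sample_w = np.ones(len(y_idx))
    else:
        sample_w = np.array([class_weights[c] for c in labels], dtype=float)

    model = copy.deepcopy(model)
    params = model.parameters()
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xC8)))
    n = len(y_idx)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            loss, grads = loss_and_gradients(
                model, x[batch], y_idx[batch], sample_w[batch]
            )
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss; aborting")
            for key, p in params.items():
                velocity[key] = cfg.momentum * velocity[key] - cfg.learning_rate * grads[key]
                p += velocity[key]
    model.velocity = velocity
    return model


def predict_proba(model: CnnModel, seg) -> np.ndarray:
    x = np.asarray(seg.values if hasattr(seg, "values") else seg, dtype=float)
    if x.ndim != 3 or x.shape[1] != model.t_len or x.shape[2] != model.m:
        raise ValueError(
            f"expected windows of shape (*, {model.t_len}, {model.m}), got {x.shape}"
        )
    return _forward(model, x)


def predict_cnn(model: CnnModel, seg) -> np.ndarray:
    """Argmax-of-softmax label for each window."""
    probs = predict_proba(model, seg)
    return np.array([model.classes[i] for i in probs.argmax(axis=1)], dtype=object)
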