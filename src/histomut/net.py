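"""A small residual convolutional network over tiles, in pure NumPy.

Architecture: a 3×3 stem convolution with ``n_filters`` kernels, followed by
``n_residual_blocks`` identity-shortcut residual blocks (conv-BN-ReLU-conv-BN
plus shortcut, then ReLU) each followed by 2×2 max-pooling, a global average
pool, and a dense head with 8 independent sigmoid outputs — one mutation
probability per biomarker.  Batch normalization smooths the loss landscape;
ReLU is the activation throughout.

Training is seeded SGD with momentum 0.9 and L2 regularization on conv/dense
weights, minimizing a multi-label binary cross-entropy (plain, class-weighted
or focal).  Biomarkers with a single class in the training data are masked
out of the loss.  Forward/backward passes are written directly against
im2col/col2im; inference runs in float64 so outputs are independent of batch
composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator

from .io import BIOMARKERS, N_BIOMARKERS

logger = logging.getLogger("histomut")

LOSSES = ("bce", "weighted_bce", "focal")


@dataclass
class NetConfig:
    """Hyperparameters of the tile classifier."""

    input_size: int = 64
    n_filters: int = 32
    kernel_size: int = 3
    n_residual_blocks: int = 2
    batch_size: int = 16
    loss_name: str = "bce"
    learning_rate: float = 0.05
    l2_coefficient: float = 1e-4
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_size", "n_filters", "kernel_size",
                     "n_residual_blocks", "batch_size", "epochs"):
            if getattr(self, name) < 1 and name != "epochs":
                raise ValueError(f"{name} must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss_name not in LOSSES:
            raise ValueError(f"loss_name must be one of {LOSSES}")


# --- layers -----------------------------------------------------------------


class Conv2D:
    """Same-padding stride-1 convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out

    def params(self):
        return [(self, "W", True), (self, "b", False)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * H * W, C * self.k * self.k)
        out = cols @ self.W.T.astype(x.dtype) + self.b.astype(x.dtype)
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._xshape
        k, p = self.k, self.k // 2
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            -1, self.c_out)
        self.dW = (dmat.T @ self._cols).astype(np.float32)
        self.db = dmat.sum(axis=0).astype(np.float32)
        dcols = (dmat @ self.W.astype(dmat.dtype)).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + H, p:p + W]


class BatchNorm2D:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [(self, "gamma", False), (self, "beta", False)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma.astype(x.dtype)[None, :, None, None] * xhat \
            + self.beta.astype(x.dtype)[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * self._xhat).sum(axis=axes).astype(np.float32)
        self.dbeta = dout.sum(axis=axes).astype(np.float32)
        g = self.gamma.astype(dout.dtype)[None, :, None, None]
        dxhat = dout * g
        mean_d = dxhat.mean(axis=axes)[None, :, None, None]
        mean_dx = (dxhat * self._xhat).mean(axis=axes)[None, :, None, None]
        dx = self._inv[None, :, None, None] * (
            dxhat - mean_d - self._xhat * mean_dx)
        self._xhat = None
        return dx


class ReLU:
    def params(self):
        return []

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    """2×2 stride-2 max pooling with exact argmax gradient routing."""

    def params(self):
        return []

    def forward(self, x, train):
        B, C, H, W = x.shape
        r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        if train:
            self._idx = r.argmax(axis=-1)
            self._xshape = x.shape
        return r.max(axis=-1)

    def backward(self, dout):
        B, C, H, W = self._xshape
        dr = np.zeros((B, C, H // 2, W // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None], axis=-1)
        return dr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(B, C, H, W)


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in),
                            size=(d_out, d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def params(self):
        return [(self, "W", True), (self, "b", False)]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W.T.astype(x.dtype) + self.b.astype(x.dtype)

    def backward(self, dout):
        self.dW = (dout.T @ self._x).astype(np.float32)
        self.db = dout.sum(axis=0).astype(np.float32)
        dx = dout @ self.W.astype(dout.dtype)
        self._x = None
        return dx


class ResidualBlock:
    """conv-BN-ReLU-conv-BN plus identity shortcut, then ReLU."""

    def __init__(self, c: int, k: int, rng: np.random.Generator):
        self.conv1 = Conv2D(c, c, k, rng)
        self.bn1 = BatchNorm2D(c)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(c, c, k, rng)
        self.bn2 = BatchNorm2D(c)
        self.relu_out = ReLU()

    def params(self):
        out = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2):
            out += layer.params()
        return out

    def forward(self, x, train):
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        return self.relu_out.forward(h + x, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dh = self.conv1.backward(dh)
        return dh + d  # shortcut gradient


class ResNetTiles:
    """The assembled network: stem → residual blocks with pooling → head."""

    def __init__(self, config: NetConfig):
        min_size = 2 ** config.n_residual_blocks
        if config.input_size % min_size or config.input_size < 2 * min_size:
            raise ValueError(
                f"input_size must be a multiple of {min_size} and at least "
                f"{2 * min_size} for {config.n_residual_blocks} pooled "
                f"residual blocks; got {config.input_size}"
            )
        rng = np.random.default_rng(config.seed)
        F, k = config.n_filters, config.kernel_size
        self.stem = Conv2D(3, F, k, rng)
        self.stem_bn = BatchNorm2D(F)
        self.stem_relu = ReLU()
        self.blocks = [ResidualBlock(F, k, rng)
                       for _ in range(config.n_residual_blocks)]
        self.pools = [MaxPool2() for _ in range(config.n_residual_blocks)]
        self.head = Dense(F, N_BIOMARKERS, rng)
        self.config = config

    def params(self):
        out = self.stem.params() + self.stem_bn.params()
        for blk in self.blocks:
            out += blk.params()
        out += self.head.params()
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (B, 3, H, W) batch."""
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem.forward(x, train), train), train)
        for blk, pool in zip(self.blocks, self.pools):
            h = pool.forward(blk.forward(h, train), train)
        if train:
            self._gap_shape = h.shape
        h = h.mean(axis=(2, 3))
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        B, C, H, W = self._gap_shape
        d = np.broadcast_to(d[:, :, None, None] / (H * W),
                            self._gap_shape).astype(dlogits.dtype)
        for blk, pool in zip(reversed(self.blocks), reversed(self.pools)):
            d = blk.backward(pool.backward(d))
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        self.stem.backward(d)


# --- losses -----------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def multilabel_loss(logits: np.ndarray, y: np.ndarray, mask: np.ndarray,
                    loss_name: str = "bce",
                    pos_weight: np.ndarray | None = None,
                    focal_gamma: float = 2.0
                    ) -> tuple[float, np.ndarray]:
    """Masked multi-label loss and its gradient w.r.t. the logits.

    ``mask`` is a per-biomarker 0/1 vector excluding single-class biomarkers.
    Returns (mean loss over active entries, dloss/dlogits).
    """
    p = _sigmoid(logits)
    eps = 1e-12
    y = y.astype(logits.dtype)
    m = mask.astype(logits.dtype)[None, :]
    denom = float(len(logits) * max(mask.sum(), 1))

    if loss_name == "bce":
        per = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        grad = (p - y)
    elif loss_name == "weighted_bce":
        w = np.ones_like(y) if pos_weight is None else np.where(
            y == 1, pos_weight[None, :].astype(logits.dtype), 1.0)
        per = -w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        grad = w * (p - y)
    elif loss_name == "focal":
        g = focal_gamma
        pt = np.where(y == 1, p, 1 - p)
        per = -((1 - pt) ** g) * np.log(pt + eps)
        logp = np.log(p + eps)
        log1p = np.log(1 - p + eps)
        grad_pos = g * p * (1 - p) ** g * logp - (1 - p) ** (g + 1)
        grad_neg = p ** (g + 1) - g * (1 - p) * p ** g * log1p
        grad = np.where(y == 1, grad_pos, grad_neg)
    else:
        raise ValueError(f"unknown loss {loss_name!r}")

    loss = float((per * m).sum() / denom)
    return loss, (grad * m / denom).astype(logits.dtype)


# --- estimator --------------------------------------------------------------


def _prepare_tiles(X, input_size: int, resize: bool) -> np.ndarray:
    """(n, H, W, 3) rasters → float32 NCHW in [0, 1], resized if allowed."""
    X = np.asarray(X)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError(f"expected (n, H, W, 3) tiles, got {X.shape}")
    if X.dtype == np.uint8:
        X = X.astype(np.float32) / 255.0
    else:
        X = X.astype(np.float32)
    if X.shape[1] != input_size or X.shape[2] != input_size:
        if not resize:
            raise ValueError(
                f"tiles are {X.shape[1]}x{X.shape[2]} but the network "
                f"expects {input_size}; enable resize or retile"
            )
        X = np.stack([
            _sk_resize(img, (input_size, input_size, 3), order=1,
                       preserve_range=True, anti_aliasing=True)
            for img in X
        ]).astype(np.float32)
    return np.ascontiguousarray(X.transpose(0, 3, 1, 2))


class TilePatchClassifier(BaseEstimator):
    """Residual-CNN multi-label classifier: tile → 8 biomarker probabilities.

    sklearn-style estimator.  ``fit(X, y)`` takes tiles as an (n, H, W, 3)
    array (uint8 or floats in [0, 1]) and an (n, 8) binary label matrix in
    canonical biomarker order; tiles inherit their slide's labels upstream.
    ``predict_proba`` returns an (n, 8) matrix of sigmoid probabilities.

    Fitted attributes: ``net_``, ``loss_trace_`` (per-epoch mean training
    loss), ``active_biomarkers_`` (loss mask), ``pos_weight_``.
    """

    def __init__(self, input_size: int = 64, n_filters: int = 32,
                 kernel_size: int = 3, n_residual_blocks: int = 2,
                 batch_size: int = 16, loss: str = "bce",
                 learning_rate: float = 0.05, l2: float = 1e-4,
                 epochs: int = 10, momentum: float = 0.9,
                 resize: bool = True, random_state: int = 0):
        self.input_size = input_size
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.n_residual_blocks = n_residual_blocks
        self.batch_size = batch_size
        self.loss = loss
        self.learning_rate = learning_rate
        self.l2 = l2
        self.epochs = epochs
        self.momentum = momentum
        self.resize = resize
        self.random_state = random_state

    def _config(self) -> NetConfig:
        return NetConfig(
            input_size=self.input_size, n_filters=self.n_filters,
            kernel_size=self.kernel_size,
            n_residual_blocks=self.n_residual_blocks,
            batch_size=self.batch_size, loss_name=self.loss,
            learning_rate=self.learning_rate, l2_coefficient=self.l2,
            epochs=self.epochs, seed=self.random_state,
        )

    def fit(self, X, y) -> "TilePatchClassifier":
        config = self._config()
        Xp = _prepare_tiles(X, self.input_size, self.resize)
        Y = np.asarray(y)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape != (len(Xp), N_BIOMARKERS):
            raise ValueError(
                f"labels must be ({len(Xp)}, {N_BIOMARKERS}), got {Y.shape}"
            )

        mask = np.array([len(np.unique(Y[:, j])) == 2
                         for j in range(N_BIOMARKERS)], dtype=np.float32)
        skipped = [BIOMARKERS[j] for j in range(N_BIOMARKERS) if not mask[j]]
        if skipped:
            logger.warning("single-class biomarkers excluded from loss: %s",
                           skipped)
        if mask.sum() == 0:
            raise ValueError("no biomarker has both classes in training data")

        n_pos = Y.sum(axis=0).astype(np.float64)
        n_neg = len(Y) - n_pos
        self.pos_weight_ = np.where(n_pos > 0, n_neg / np.maximum(n_pos, 1),
                                    1.0).astype(np.float32)

        net = ResNetTiles(config)
        params = net.params()
        velocity = {(id(obj), name): np.zeros_like(getattr(obj, name))
                    for obj, name, _ in params}
        rng = np.random.default_rng(
            np.random.SeedSequence([self.random_state, 0x5A1DE]))

        trace = []
        for _ in range(self.epochs):
            order = rng.permutation(len(Xp))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(Xp), self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = net.forward(Xp[idx], train=True)
                loss, dlogits = multilabel_loss(
                    logits, Y[idx], mask, self.loss, self.pos_weight_)
                net.backward(dlogits)
                for obj, name, decay in params:
                    g = getattr(obj, "d" + name)
                    if decay and self.l2 > 0:
                        g = g + self.l2 * getattr(obj, name)
                    key = (id(obj), name)
                    velocity[key] = (self.momentum * velocity[key]
                                     - self.learning_rate * g)
                    setattr(obj, name, getattr(obj, name) + velocity[key])
                epoch_loss += loss
                n_batches += 1
            trace.append(epoch_loss / max(n_batches, 1))

        self.net_ = net
        self.loss_trace_ = np.asarray(trace)
        self.active_biomarkers_ = mask.astype(bool)
        return self

    def decision_function(self, X) -> np.ndarray:
        Xp = _prepare_tiles(X, self.input_size, self.resize)
        out = np.empty((len(Xp), N_BIOMARKERS), dtype=np.float64)
        for start in range(0, len(Xp), 256):
            batch = Xp[start:start + 256].astype(np.float64)
            out[start:start + 256] = self.net_.forward(batch, train=False)
        return out

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.int8)


def build_network(config: NetConfig) -> ResNetTiles:
    """Construct the seeded network for a hyperparameter configuration."""
    return ResNetTiles(config)


def predict_tiles(model: TilePatchClassifier, tiles) -> np.ndarray:
    """Per-tile 8-vector of biomarker probabilities (thin wrapper)."""
    from .tiling import Tile
    if len(tiles) and isinstance(tiles[0], Tile):
        tiles = np.stack([t.pixels for t in tiles])
    return model.predict_proba(tiles)
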