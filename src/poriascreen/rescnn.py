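"""A small residual convolutional network for 2DCOS map images, in numpy.

The classifier mirrors the 12-weighted-layer residual design used for
spectral-image discrimination: a stem convolution, five residual blocks of
two 3x3 convolutions each with identity or 1x1-projection shortcuts
(F(x) = H(x) - x formulation), and a final fully connected layer on globally
average-pooled features — 12 weighted layers in all (batch-norm layers and
projection shortcuts are not counted, per the usual convention). Training is
plain SGD with momentum 0.9, the configured learning rate (default 0.01) and
L2 weight decay (default 1e-4) on convolution/linear weights, minimizing
softmax cross-entropy. Everything is seeded and deterministic under
single-threaded execution.

Implemented directly on numpy arrays: convolutions are evaluated as nine
shifted tensor contractions (one per 3x3 tap), which keeps memory flat and
lets BLAS do the work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from poriascreen._seeds import stream
from poriascreen.latent import ConfusionMatrix
from poriascreen.split import SplitResult


@dataclass
class NetConfig:
    weighted_layers: int = 12
    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 32
    image_size: int = 64
    seed: int = 0
    # conventional step schedule: lr is multiplied by lr_decay_factor once
    # two thirds of the epoch budget have run, which settles the late epochs
    lr_decay_factor: float = 0.1
    lr_decay_at: float = 2 / 3

    def validate(self) -> None:
        if self.weighted_layers != 12:
            raise ValueError("only the 12-weighted-layer architecture is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainRecord:
    epoch_loss: list[float]
    epoch_accuracy: list[float]
    test_accuracy: float
    epochs_run: int


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv:
    """k x k convolution, stride s, zero padding k//2, no bias."""

    decay = True

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng) -> None:
        std = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.standard_normal((c_out, c_in, k, k)) * std
        self.k, self.s, self.pad = k, stride, k // 2
        self.gW = np.zeros_like(self.W)
        self.v = np.zeros_like(self.W)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        k, s, p = self.k, self.s, self.pad
        Ho = (H + 2 * p - k) // s + 1
        Wo = (Wd + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp, self._out_hw = xp, (Ho, Wo)
        out = np.zeros((B, self.W.shape[0], Ho, Wo))
        for dy in range(k):
            for dx in range(k):
                xs = xp[:, :, dy : dy + s * Ho : s, dx : dx + s * Wo : s]
                out += np.tensordot(xs, self.W[:, :, dy, dx], axes=([1], [1])).transpose(
                    0, 3, 1, 2
                )
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        k, s, p = self.k, self.s, self.pad
        Ho, Wo = self._out_hw
        dxp = np.zeros_like(xp)
        for dy in range(k):
            for dx in range(k):
                xs = xp[:, :, dy : dy + s * Ho : s, dx : dx + s * Wo : s]
                self.gW[:, :, dy, dx] = np.tensordot(
                    dout, xs, axes=([0, 2, 3], [0, 2, 3])
                )
                dxp[:, :, dy : dy + s * Ho : s, dx : dx + s * Wo : s] += np.tensordot(
                    dout, self.W[:, :, dy, dx], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp

    def params(self):
        yield self


class BatchNorm:
    """Per-channel batch normalization with running statistics."""

    decay = False
    eps = 1e-5
    momentum = 0.1

    def __init__(self, c: int) -> None:
        self.W = np.ones(c)  # gamma
        self.beta = np.zeros(c)
        self.gW = np.zeros(c)
        self.gbeta = np.zeros(c)
        self.v = np.zeros(c)
        self.vbeta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu[None, :, None, None]) * self._invstd[None, :, None, None]
        return self.W[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gW = (dout * xhat).sum(axis=(0, 2, 3))
        self.gbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.W[None, :, None, None]
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * (m * dxhat - t1 - xhat * t2)

    def params(self):
        yield self


class Linear:
    decay = True

    def __init__(self, d_in: int, d_out: int, rng) -> None:
        self.W = rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in)
        self.beta = np.zeros(d_out)
        self.gW = np.zeros_like(self.W)
        self.gbeta = np.zeros(d_out)
        self.v = np.zeros_like(self.W)
        self.vbeta = np.zeros(d_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.gW = dout.T @ self._x
        self.gbeta = dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        yield self


class ResBlock:
    """Two 3x3 convolutions with batch norm and a (projected) shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng) -> None:
        self.conv1 = Conv(c_in, c_out, 3, stride, rng)
        self.bn1 = BatchNorm(c_out)
        self.conv2 = Conv(c_out, c_out, 3, 1, rng)
        self.bn2 = BatchNorm(c_out)
        self.projected = stride != 1 or c_in != c_out
        if self.projected:
            self.proj = Conv(c_in, c_out, 1, stride, rng)
            self.bn_proj = BatchNorm(c_out)

    def shortcut_forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.projected:
            return self.bn_proj.forward(self.proj.forward(x), train)
        return x

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.bn1.forward(self.conv1.forward(x), train)
        self._mask1 = h > 0
        h = h * self._mask1
        h = self.bn2.forward(self.conv2.forward(h), train)
        sc = self.shortcut_forward(x, train)
        out = h + sc
        self._mask_out = out > 0
        return out * self._mask_out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout * self._mask_out
        # residual branch
        dh = self.bn2.backward(dout)
        dh = self.conv2.backward(dh)
        dh = dh * self._mask1
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        # shortcut branch
        if self.projected:
            dsc = self.bn_proj.backward(dout)
            dx = dx + self.proj.backward(dsc)
        else:
            dx = dx + dout
        return dx

    def params(self):
        yield from self.conv1.params()
        yield from self.bn1.params()
        yield from self.conv2.params()
        yield from self.bn2.params()
        if self.projected:
            yield from self.proj.params()
            yield from self.bn_proj.params()


class ResNet12:
    """Stem conv + five residual blocks + linear head = 12 weighted layers."""

    widths = (16, 16, 32, 32, 64)
    strides = (1, 2, 2, 2, 2)

    def __init__(self, cfg: NetConfig) -> None:
        cfg.validate()
        self.cfg = cfg
        rng = stream(cfg.seed, "rescnn-init")
        self.stem = Conv(1, 16, 3, 2, rng)  # stride-2 stem halves the grid
        self.bn_stem = BatchNorm(16)
        self.blocks = []
        c_in = 16
        for c_out, s in zip(self.widths, self.strides):
            self.blocks.append(ResBlock(c_in, c_out, s, rng))
            c_in = c_out
        self.fc = Linear(c_in, 2, rng)

    # -- bookkeeping -------------------------------------------------------

    @property
    def weighted_layer_count(self) -> int:
        """Stem + 2 convs per block + fully connected; projections not counted."""
        return 1 + 2 * len(self.blocks) + 1

    @property
    def n_parameters(self) -> int:
        total = 0
        for layer in self._layers():
            total += layer.W.size
            if hasattr(layer, "beta"):
                total += layer.beta.size
        return total

    def _layers(self):
        yield from self.stem.params()
        yield from self.bn_stem.params()
        for b in self.blocks:
            yield from b.params()
        yield from self.fc.params()

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.bn_stem.forward(self.stem.forward(x), train)
        self._mask_stem = h > 0
        h = h * self._mask_stem
        for b in self.blocks:
            h = b.forward(h, train)
        self._pool_hw = h.shape[2] * h.shape[3]
        feats = h.mean(axis=(2, 3))  # global average pool
        self._feat_shape = h.shape
        return self.fc.forward(feats)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeats = self.fc.backward(dlogits)
        B, C, H, Wd = self._feat_shape
        dh = np.broadcast_to(
            dfeats[:, :, None, None] / self._pool_hw, self._feat_shape
        ).copy()
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        dh = dh * self._mask_stem
        dh = self.bn_stem.backward(dh)
        self.stem.backward(dh)

    def predict_logits(self, images: np.ndarray, batch: int = 64) -> np.ndarray:
        x = _prep(images, self.cfg.image_size)
        out = []
        for i in range(0, x.shape[0], batch):
            out.append(self.forward(x[i : i + batch], train=False))
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_logits(images).argmax(axis=1)


def build_network(cfg: NetConfig) -> ResNet12:
    """Construct the 12-weighted-layer residual classifier."""
    return ResNet12(cfg)


# ---------------------------------------------------------------------------
# data plumbing and training
# ---------------------------------------------------------------------------


def _prep(images: np.ndarray, size: int) -> np.ndarray:
    """(N, H, W[, C]) images -> standardized (N, 1, size, size) tensors."""
    x = np.asarray(images, dtype=float)
    if x.ndim == 4:
        x = x.mean(axis=3)  # collapse channels; maps are scalar fields
    if x.ndim != 3:
        raise ValueError("images must be (N, H, W) or (N, H, W, C)")
    if x.shape[1] != size or x.shape[2] != size:
        from poriascreen.twodcos import _resample

        x = np.stack([_resample(im, size) for im in x])
    mu = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return ((x - mu) / sd)[:, None, :, :]


def _softmax_ce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = y.size
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


def _sgd_step(model: ResNet12, cfg: NetConfig, lr: float) -> None:
    mu, wd = cfg.momentum, cfg.weight_decay
    for layer in model._layers():
        g = layer.gW + (wd * layer.W if layer.decay else 0.0)
        layer.v = mu * layer.v - lr * g
        layer.W = layer.W + layer.v
        if hasattr(layer, "beta"):
            layer.vbeta = mu * layer.vbeta - lr * layer.gbeta
            layer.beta = layer.beta + layer.vbeta


def train(
    images: np.ndarray,
    labels: np.ndarray,
    split: SplitResult,
    cfg: NetConfig,
    model: ResNet12 | None = None,
) -> tuple[ResNet12, TrainRecord]:
    """Train on ``split.train_ids``, report final accuracy on ``split.test_ids``.

    Per-epoch cross-entropy and training accuracy are recorded; data order is
    shuffled by the seeded stream each epoch, so runs repeat exactly.
    """
    cfg.validate()
    y = np.asarray(labels).astype(int).ravel()
    tr = np.asarray(split.train_ids, dtype=int)
    te = np.asarray(split.test_ids, dtype=int)
    if tr.size == 0:
        raise ValueError("empty training split")
    if np.unique(y[tr]).size < 2:
        raise ValueError("training split must contain both classes")
    x_all = _prep(images, cfg.image_size)
    model = model or build_network(cfg)
    rng = stream(cfg.seed, "rescnn-shuffle")

    losses, accs = [], []
    decay_epoch = int(np.floor(cfg.lr_decay_at * cfg.epochs))
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate * (
            cfg.lr_decay_factor if epoch >= decay_epoch else 1.0
        )
        order = tr[rng.permutation(tr.size)]
        total_loss = 0.0
        correct = 0
        for i in range(0, order.size, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(x_all[idx], train=True)
            loss, grad = _softmax_ce(logits, y[idx])
            model.backward(grad)
            _sgd_step(model, cfg, lr)
            total_loss += loss * idx.size
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        losses.append(total_loss / order.size)
        accs.append(correct / order.size)

    if te.size:
        test_acc = float((model_predict(model, x_all[te]) == y[te]).mean())
    else:
        test_acc = float("nan")
    record = TrainRecord(
        epoch_loss=losses,
        epoch_accuracy=accs,
        test_accuracy=test_acc,
        epochs_run=cfg.epochs,
    )
    return model, record


def model_predict(model: ResNet12, x_prepped: np.ndarray, batch: int = 64) -> np.ndarray:
    out = []
    for i in range(0, x_prepped.shape[0], batch):
        out.append(model.forward(x_prepped[i : i + batch], train=False))
    return np.concatenate(out, axis=0).argmax(axis=1)


def external_validate(
    model: ResNet12, images: np.ndarray, labels: np.ndarray
) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix and accuracy (trace / total) on an external set."""
    y = np.asarray(labels).astype(int).ravel()
    pred = model.predict(images)
    cm = ConfusionMatrix.from_predictions(y, pred)
    return cm, float((pred == y).mean())
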