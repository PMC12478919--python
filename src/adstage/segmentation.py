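"""U-Net segmentation: model builder, balanced cross-entropy / Dice losses,
training loop, and the binary segmentation metric battery.

Two encoder-decoder variants are provided through one builder. The *vanilla*
variant (depth 4) segments the whole brain from a slice; the *multi-layer*
variant (depth 3, skip connection at every level) segments the gray-matter
ribbon, the structure whose atrophy tracks Alzheimer's progression. Each
encoder level applies two same-padded 3x3 convolutions with ReLU and a 2x2
max-pool; the bottleneck is another double convolution; each decoder level
upsamples with a 2x2-stride-2 transposed convolution, concatenates the
mirror encoder feature, and applies a double convolution; a final 1x1
convolution with a sigmoid yields the per-pixel foreground probability.

Because foreground tissue occupies a small fraction of a slice, training
uses a class-balanced binary cross-entropy: the positive (tissue) term is
weighted by ``beta`` and the negative (background) term by ``1 - beta``.
With ``beta="auto"`` beta is set to the background-pixel fraction of the
training masks, so the rarer the tissue, the larger its weight. A Dice loss
is available as an alternative objective.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn


class SegConfigError(ValueError):
    """Raised for invalid model or training configuration."""


class SegInputError(ValueError):
    """Raised for invalid data passed to training or evaluation."""


@dataclass(frozen=True)
class UNetConfig:
    """Architecture of one encoder-decoder variant.

    ``filters[i]`` is the channel count of encoder level ``i`` (decoder
    levels mirror it); ``input_size`` must be divisible by ``2**depth`` so
    every pooling halves cleanly.
    """

    depth: int
    filters: tuple[int, ...]
    bottleneck_filters: int
    input_size: int
    kernel_size: int = 3

    def __post_init__(self):
        if len(self.filters) != self.depth:
            raise SegConfigError("len(filters) must equal depth")
        if any(f < 1 for f in self.filters) or self.bottleneck_filters < 1:
            raise SegConfigError("filter counts must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise SegConfigError(
                f"input_size {self.input_size} not divisible by 2^{self.depth}")


def vanilla_config(input_size: int = 224, base_filters: int = 32) -> UNetConfig:
    """Depth-4 whole-brain segmenter, filters doubling per level."""
    return UNetConfig(depth=4,
                      filters=tuple(base_filters * 2 ** i for i in range(4)),
                      bottleneck_filters=base_filters * 16,
                      input_size=input_size)


def multilayer_config(input_size: int = 224, base_filters: int = 32) -> UNetConfig:
    """Depth-3 gray-matter segmenter with a skip connection at every level."""
    return UNetConfig(depth=3,
                      filters=tuple(base_filters * 2 ** i for i in range(3)),
                      bottleneck_filters=base_filters * 8,
                      input_size=input_size)


class _ConvBlock(nn.Layer):
    """Two same-padded convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.seq = nn.Sequential(
            nn.Conv2d(cin, cout, k, rng), nn.ReLU(),
            nn.Conv2d(cout, cout, k, rng), nn.ReLU(),
        )

    def params(self):
        return self.seq.params()

    def forward(self, x, training=False):
        return self.seq.forward(x, training=training)

    def backward(self, dy):
        return self.seq.backward(dy)


class UNet:
    """Encoder-decoder segmenter mapping (N,1,H,W) to foreground
    probabilities (N,1,H,W) in (0,1)."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        self.config = config
        k = config.kernel_size
        self.enc_blocks: list[_ConvBlock] = []
        self.pools: list[nn.MaxPool2d] = []
        cin = 1
        for f in config.filters:
            self.enc_blocks.append(_ConvBlock(cin, f, k, rng))
            self.pools.append(nn.MaxPool2d())
            cin = f
        self.bottleneck = _ConvBlock(cin, config.bottleneck_filters, k, rng)
        self.ups: list[nn.ConvTranspose2d] = []
        self.dec_blocks: list[_ConvBlock] = []
        cin = config.bottleneck_filters
        for f in reversed(config.filters):
            self.ups.append(nn.ConvTranspose2d(cin, f, rng))
            self.dec_blocks.append(_ConvBlock(2 * f, f, k, rng))
            cin = f
        self.final = nn.Conv2d(cin, 1, 1, rng)  # 1x1 conv
        self.sigmoid = nn.Sigmoid()

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for b in self.enc_blocks:
            ps += b.params()
        ps += self.bottleneck.params()
        for u, b in zip(self.ups, self.dec_blocks):
            ps += u.params() + b.params()
        ps += self.final.params()
        return ps

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != 1:
            raise SegInputError("expected input of shape (N, H, W, 1)")
        if x.shape[1] != self.config.input_size or x.shape[2] != self.config.input_size:
            raise SegInputError(
                f"expected {self.config.input_size}px square input, got {x.shape[1:3]}")
        skips = []
        h = x.astype(np.float32)
        for block, pool in zip(self.enc_blocks, self.pools):
            c = block.forward(h, training)
            skips.append(c)
            h = pool.forward(c, training)
        h = self.bottleneck.forward(h, training)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            u = up.forward(h, training)
            h = np.concatenate([u, skip], axis=3)
            self._skip_channels.append(u.shape[3])
            h = block.forward(h, training)
        z = self.final.forward(h, training)
        return self.sigmoid.forward(z, training)

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        dy = self.sigmoid.backward(dprob)
        dy = self.final.backward(dy)
        dskips = []
        for up, block, cu in zip(reversed(self.ups), reversed(self.dec_blocks),
                                 reversed(self._skip_channels)):
            d = block.backward(dy)
            du, dskip = d[..., :cu], d[..., cu:]
            dskips.append(dskip)
            dy = up.backward(np.ascontiguousarray(du))
        dy = self.bottleneck.backward(dy)
        # dskips were collected walking the decoder backwards, i.e. in
        # shallow-to-deep encoder order; reverse to pair deepest-first.
        for block, pool, dskip in zip(reversed(self.enc_blocks),
                                      reversed(self.pools), reversed(dskips)):
            d = pool.backward(dy) + dskip
            dy = block.backward(d)
        return dy

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p.data[...] = w

    def save(self, path) -> None:
        np.savez_compressed(path, *[p.data for p in self.params()])

    def load(self, path) -> None:
        with np.load(path) as z:
            self.set_weights([z[k] for k in z.files])


def build_unet(config: UNetConfig, seed: int = 42) -> UNet:
    """Construct a randomly initialized U-Net for the given configuration."""
    return UNet(config, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# losses

_EPS = 1e-7


def balanced_cross_entropy(y_true: np.ndarray, y_pred: np.ndarray,
                           beta: float) -> float:
    """Mean over pixels of ``-beta*y*log(p) - (1-beta)*(1-y)*log(1-p)``.

    ``beta`` up-weights the (rarer) foreground class; predictions are clipped
    to [1e-7, 1 - 1e-7] before the logs.
    """
    if not 0.0 < beta < 1.0:
        raise SegConfigError("beta must be in (0, 1)")
    y = np.asarray(y_true, dtype=np.float64)
    p = np.clip(np.asarray(y_pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    if y.shape != p.shape:
        raise SegInputError("shape mismatch between mask and prediction")
    return float(np.mean(-beta * y * np.log(p) - (1.0 - beta) * (1.0 - y) * np.log1p(-p)))


def _balanced_cross_entropy_grad(y: np.ndarray, p: np.ndarray, beta: float) -> np.ndarray:
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    g = (-beta * y / pc + (1.0 - beta) * (1.0 - y) / (1.0 - pc)) / y.size
    return g.astype(np.float32)


def dice_loss(y_true: np.ndarray, y_pred: np.ndarray, smooth: float = 1.0) -> float:
    """``1 - (2*sum(p*y) + smooth) / (sum(p) + sum(y) + smooth)``."""
    y = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(y_pred, dtype=np.float64)
    if y.shape != p.shape:
        raise SegInputError("shape mismatch between mask and prediction")
    num = 2.0 * float((p * y).sum()) + smooth
    den = float(p.sum()) + float(y.sum()) + smooth
    return float(1.0 - num / den)


def _dice_loss_grad(y: np.ndarray, p: np.ndarray, smooth: float = 1.0) -> np.ndarray:
    num = 2.0 * float((p * y).sum()) + smooth
    den = float(p.sum()) + float(y.sum()) + smooth
    g = -(2.0 * y * den - num) / den ** 2
    return g.astype(np.float32)


# ---------------------------------------------------------------------------
# training

@dataclass
class SegTrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 100
    loss: str = "balanced_bce"          # or "dice"
    beta: float | str = "auto"
    seed: int = 42

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise SegConfigError("learning_rate must be positive")
        if self.loss not in ("balanced_bce", "dice"):
            raise SegConfigError("loss must be 'balanced_bce' or 'dice'")
        if isinstance(self.beta, str):
            if self.beta != "auto":
                raise SegConfigError("beta must be numeric or 'auto'")
        elif not 0.0 < self.beta < 1.0:
            raise SegConfigError("beta must be in (0, 1)")


def _as_batch(images: np.ndarray) -> np.ndarray:
    """(H,W) / (N,H,W) / (N,H,W,1) -> (N,H,W,1) float32."""
    a = np.asarray(images, dtype=np.float32)
    if a.ndim == 2:
        a = a[None]
    if a.ndim == 3:
        a = a[..., None]
    return a


def resolve_beta(beta: float | str, masks: np.ndarray) -> float:
    """``"auto"`` resolves to the background-pixel fraction of the training
    masks (clipped away from 0/1); a numeric beta passes through."""
    if beta != "auto":
        return float(beta)
    frac_bg = 1.0 - float(np.mean(masks))
    return float(np.clip(frac_bg, 0.01, 0.99))


def train_segmenter(model: UNet, train_data, val_data,
                    config: SegTrainConfig) -> dict:
    """Adam training with best-epoch selection by validation Dice.

    ``train_data``/``val_data`` are ``(images, masks)`` pairs of arrays with
    shape (N, H, W); masks must be binary. Returns a history dict with
    per-epoch ``loss`` and ``val_dice`` (both of length ``epochs``) plus
    ``best_epoch``; the model is left holding the best-validation weights.
    """
    x_tr, m_tr = _as_batch(train_data[0]), _as_batch(train_data[1])
    x_va, m_va = _as_batch(val_data[0]), _as_batch(val_data[1])
    if x_tr.shape[0] == 0:
        raise SegInputError("empty training data")
    for m in (m_tr, m_va):
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise SegInputError("masks must be binary {0, 1}")
    beta = resolve_beta(config.beta, m_tr)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    n = x_tr.shape[0]
    history = {"loss": [], "val_dice": [], "beta": beta}
    best_dice, best_weights, best_epoch = -1.0, model.get_weights(), 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, mb = x_tr[idx], m_tr[idx].astype(np.float32)
            opt.zero_grad()
            p = model.forward(xb, training=True)
            if config.loss == "balanced_bce":
                loss = balanced_cross_entropy(mb, p, beta)
                grad = _balanced_cross_entropy_grad(mb, p, beta)
            else:
                loss = dice_loss(mb, p)
                grad = _dice_loss_grad(mb, p)
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_dice = _mean_dice(model, x_va, m_va, config.batch_size)
        history["loss"].append(float(np.mean(losses)))
        history["val_dice"].append(val_dice)
        if val_dice > best_dice:
            best_dice, best_epoch = val_dice, epoch
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    return history


def _mean_dice(model: UNet, x: np.ndarray, masks: np.ndarray,
               batch_size: int) -> float:
    dices = []
    for start in range(0, x.shape[0], batch_size):
        p = model.forward(x[start:start + batch_size], training=False)
        pred = (p >= 0.5).astype(np.uint8)
        for pi, mi in zip(pred, masks[start:start + batch_size]):
            dices.append(evaluate_segmentation(pi[..., 0], mi[..., 0]).dice)
    return float(np.mean(dices)) if dices else 0.0


def predict_mask(model: UNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary foreground mask: 1 where predicted probability >= threshold."""
    single = np.asarray(image).ndim == 2
    x = _as_batch(image)
    p = model.forward(x, training=False)
    mask = (p >= threshold).astype(np.uint8)[..., 0]
    return mask[0] if single else mask


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class SegMetrics:
    dice: float
    iou: float
    accuracy: float
    precision: float
    recall: float
    f1: float


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Confusion-count metrics with foreground (1) as the positive class.

    Dice and F1 coincide algebraically (both are 2TP/(2TP+FP+FN)); ratios
    with empty denominators are defined as 1 when prediction and truth agree
    exactly (both empty) and 0 otherwise.
    """
    p = np.asarray(pred)
    g = np.asarray(truth)
    if p.shape != g.shape:
        raise SegInputError("shape mismatch between prediction and truth")
    for a in (p, g):
        if not np.all(np.isin(np.unique(a), (0, 1))):
            raise SegInputError("masks must be binary {0, 1}")
    p = p.astype(bool)
    g = g.astype(bool)
    tp = int(np.sum(p & g))
    tn = int(np.sum(~p & ~g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))

    def ratio(num: int, den: int) -> float:
        if den == 0:
            return 1.0 if fp == fn == 0 else 0.0
        return num / den

    dice = ratio(2 * tp, 2 * tp + fp + fn)
    iou = ratio(tp, tp + fp + fn)
    accuracy = (tp + tn) / p.size
    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    return SegMetrics(dice=dice, iou=iou, accuracy=accuracy,
                      precision=precision, recall=recall, f1=dice)
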