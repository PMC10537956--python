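"""Encoder-only segmentation network with an 8x-downsampled mask output.

The model is the descending half of a U-Net: stacked 3x3 convolution /
batch-norm / ReLU blocks with three 2x spatial reductions on the output path
and no decoder, so a ``H x W`` RGB input yields an ``H/8 x W/8`` grid of
per-class scores (output stride 8). A final 1x1 projection maps features to
the K schema classes.

No autodiff stack is assumed: convolutions (im2col), batch normalisation,
spatial dropout and momentum SGD are implemented directly on numpy arrays.
At desk scale (widths 16/32/64, tiles of a few hundred pixels) a training
run is a few minutes on one CPU.

Training follows the hyperparameter envelope of the full-scale experiment:
pixel-wise multinomial cross-entropy on annotated output-grid positions
(optionally class-weighted), momentum SGD with momentum 0.9 or 0.99, an
adaptive learning rate confined to [5e-7, 5e-4] by a reduce-on-plateau rule,
dropout in [0, 0.1], and random flips/rotations plus mild brightness and
saturation jitter. Ground truth is brought to the output grid by per-block
majority vote; blocks dominated by the UNANNOTATED sentinel are excluded
from the loss.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .schema import UNANNOTATED, ClassSchema, LabelMask, SectionImage

OUTPUT_STRIDE = 8


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``epochs`` counts optimizer steps ("one iteration per epoch"): each epoch
    draws one fresh batch of augmented patches and performs one update.
    """

    patch_size: tuple[int, int] = (512, 1024)  # (width, height)
    batch_size: int = 32
    lr_min: float = 5e-7
    lr_max: float = 5e-4
    momentum: float = 0.99
    dropout: float = 0.0
    epochs: int = 500
    augmentations: frozenset[str] = frozenset(
        {"hflip", "vflip", "rot90", "brightness", "saturation"}
    )
    class_balancing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_min > self.lr_max:
            raise ValueError("lr_min must be <= lr_max")
        if not 0.0 <= self.dropout <= 0.1:
            raise ValueError("dropout must lie in [0, 0.1]")
        if not 0.0 < self.momentum < 1.0:
            raise ValueError("momentum must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    val_pixel_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp = (x.shape[2] - k) // stride + 1
    wp = (x.shape[3] - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    win = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, hp, wp), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    cols = np.ascontiguousarray(win.transpose(0, 4, 5, 1, 2, 3)).reshape(
        n * hp * wp, c * k * k
    )
    return cols, x.shape, (hp, wp)


def _col2im(dcols, xpad_shape, k, stride, out_hw, pad):
    n, c, hpad, wpad = xpad_shape
    hp, wp = out_hw
    dx = np.zeros(xpad_shape, dtype=dcols.dtype)
    d = dcols.reshape(n, hp, wp, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * hp : stride, j : j + stride * wp : stride] += d[
                :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2D:
    def __init__(self, c_in, c_out, k, stride, rng, pad=None):
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x, train):
        cols, xshape, (hp, wp) = _im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.W.T + self.b
        self._cache = (cols, xshape, (hp, wp), x.shape[0])
        return out.reshape(x.shape[0], hp, wp, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape, out_hw, n = self._cache
        d2 = dout.transpose(0, 2, 3, 1).reshape(-1, dout.shape[1])
        self.dW = (d2.T @ cols).astype(np.float32)
        self.db = d2.sum(axis=0).astype(np.float32)
        dcols = d2 @ self.W
        return _col2im(dcols, xshape, self.k, self.stride, out_hw, self.pad)

    def params(self):
        return [("W", self.W, "vW", "dW"), ("b", self.b, "vb", "db")]

    @property
    def n_params(self):
        return self.W.size + self.b.size


class BatchNorm2D:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.vgamma = np.zeros_like(self.gamma)
        self.vbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.dbeta = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        dx = g * (
            dout
            - (self.dbeta / m)[None, :, None, None]
            - xhat * (self.dgamma / m)[None, :, None, None]
        )
        return dx.astype(np.float32)

    def params(self):
        return [
            ("gamma", self.gamma, "vgamma", "dgamma"),
            ("beta", self.beta, "vbeta", "dbeta"),
        ]

    @property
    def n_params(self):
        return self.gamma.size + self.beta.size


class ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []

    n_params = 0


class SpatialDropout:
    """Drops whole feature channels with probability p (train mode only)."""

    def __init__(self, p, rng):
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = (self.rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.p).astype(
            np.float32
        )
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []

    n_params = 0


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class EncoderNet:
    """Downsampling U-Net half: three stride-2 conv blocks + 1x1 classifier."""

    def __init__(self, n_classes: int, widths: Sequence[int], dropout: float, seed: int):
        rng = np.random.Generator(np.random.PCG64(seed))
        self.widths = tuple(int(w) for w in widths)
        self.n_classes = n_classes
        w1, w2, w3 = self.widths
        self.layers = [
            Conv2D(3, w1, 3, 2, rng),
            BatchNorm2D(w1),
            ReLU(),
            Conv2D(w1, w2, 3, 2, rng),
            BatchNorm2D(w2),
            ReLU(),
            Conv2D(w2, w3, 3, 2, rng),
            BatchNorm2D(w3),
            ReLU(),
            Conv2D(w3, w3, 3, 1, rng),
            BatchNorm2D(w3),
            ReLU(),
            SpatialDropout(dropout, rng),
            Conv2D(w3, n_classes, 1, 1, rng, pad=0),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def sgd_step(self, lr: float, momentum: float) -> None:
        for layer in self.layers:
            for _, p, vname, gname in layer.params():
                v = getattr(layer, vname)
                g = getattr(layer, gname)
                v *= momentum
                v -= lr * g
                p += v

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p, *_ in layer.params():
                state[f"layer{i}.{name}"] = p
            if isinstance(layer, BatchNorm2D):
                state[f"layer{i}.run_mean"] = layer.run_mean
                state[f"layer{i}.run_var"] = layer.run_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, p, *_ in layer.params():
                p[...] = state[f"layer{i}.{name}"]
            if isinstance(layer, BatchNorm2D):
                layer.run_mean[...] = state[f"layer{i}.run_mean"]
                layer.run_var[...] = state[f"layer{i}.run_var"]


@dataclass
class ModelHandle:
    """Trained-or-untrained model plus the metadata needed to apply it."""

    net: EncoderNet
    schema: ClassSchema
    output_stride: int = OUTPUT_STRIDE

    @property
    def class_count(self) -> int:
        return self.net.n_classes

    @property
    def depth(self) -> int:
        return 3  # 2x spatial reductions on the output path

    @property
    def n_params(self) -> int:
        return self.net.n_params


DEFAULT_WIDTHS = (16, 32, 64)


def build_model(
    schema: ClassSchema, width_multiplier: float = 1.0, dropout: float = 0.0, seed: int = 0
) -> ModelHandle:
    """Construct the encoder with channel widths scaled by ``width_multiplier``."""
    if schema.n_classes < 2:
        raise ValueError("need at least 2 classes")
    widths = tuple(max(4, int(round(w * width_multiplier))) for w in DEFAULT_WIDTHS)
    return ModelHandle(EncoderNet(schema.n_classes, widths, dropout, seed), schema)


# ---------------------------------------------------------------------------
# ground truth at output stride
# ---------------------------------------------------------------------------


def downsample_labels_majority(
    labels: np.ndarray, factor: int, n_classes: int
) -> np.ndarray:
    """Majority label per ``factor x factor`` block; ties to the lowest id.

    UNANNOTATED pixels never vote; blocks where UNANNOTATED outnumbers all
    annotated pixels together are emitted as UNANNOTATED (excluded from loss
    and evaluation).
    """
    h, w = labels.shape
    hb, wb = h // factor, w // factor
    blocks = labels[: hb * factor, : wb * factor].reshape(hb, factor, wb, factor)
    counts = np.stack(
        [(blocks == k).sum(axis=(1, 3)) for k in range(n_classes)], axis=0
    )
    out = counts.argmax(axis=0).astype(np.uint8)
    annotated = counts.sum(axis=0)
    unann = (blocks == UNANNOTATED).sum(axis=(1, 3))
    out[(annotated == 0) | (unann > annotated)] = UNANNOTATED
    return out


def downsample_mask(mask: LabelMask, schema: ClassSchema, factor: int = OUTPUT_STRIDE) -> LabelMask:
    """Block-majority downsample of a full-resolution mask."""
    if mask.downsample_factor != 1:
        raise ValueError("expected a full-resolution mask")
    out = downsample_labels_majority(mask.labels, factor, schema.n_classes)
    return LabelMask(out, downsample_factor=factor, origin=mask.origin)


def upsample_mask(mask: LabelMask, factor: int = OUTPUT_STRIDE) -> LabelMask:
    """Nearest-neighbour label replication back to a finer grid.

    Class pixel *proportions* are preserved exactly (each cell becomes a
    ``factor x factor`` block of the same id). The result does not invert a
    majority downsample in general.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if mask.downsample_factor % factor != 0:
        raise ValueError("factor must divide the mask's downsample_factor")
    up = np.repeat(np.repeat(mask.labels, factor, axis=0), factor, axis=1)
    return LabelMask(
        up, downsample_factor=mask.downsample_factor // factor, origin=mask.origin
    )


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def _softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _cross_entropy(logits, targets, class_weights):
    """Weighted pixel CE over annotated positions; returns (loss, dlogits, acc)."""
    n, k, h, w = logits.shape
    flat_logits = logits.transpose(0, 2, 3, 1).reshape(-1, k)
    flat_t = targets.ravel()
    valid = flat_t != UNANNOTATED
    if not valid.any():
        raise ValueError("batch contains no annotated output-grid positions")
    y = flat_t[valid].astype(np.int64)
    p = _softmax(flat_logits[valid], axis=1)
    wgt = class_weights[y]
    wsum = wgt.sum()
    loss = float(-(wgt * np.log(p[np.arange(y.size), y] + 1e-12)).sum() / wsum)
    acc = float((p.argmax(axis=1) == y).mean())
    dp = p.copy()
    dp[np.arange(y.size), y] -= 1.0
    dp *= (wgt / wsum)[:, None]
    dflat = np.zeros_like(flat_logits)
    dflat[valid] = dp
    return loss, dflat.reshape(n, h, w, k).transpose(0, 3, 1, 2).astype(np.float32), acc


# ---------------------------------------------------------------------------
# augmentation + batch sampling
# ---------------------------------------------------------------------------


def _augment(img, lab, aug, rng):
    if "hflip" in aug and rng.random() < 0.5:
        img, lab = img[:, ::-1], lab[:, ::-1]
    if "vflip" in aug and rng.random() < 0.5:
        img, lab = img[::-1], lab[::-1]
    if "rot90" in aug and img.shape[0] == img.shape[1]:
        r = int(rng.integers(0, 4))
        if r:
            img, lab = np.rot90(img, r), np.rot90(lab, r)
    img = img.astype(np.float32)
    if "brightness" in aug:
        img = img * rng.uniform(0.9, 1.1) + rng.uniform(-10, 10)
    if "saturation" in aug:
        s = rng.uniform(0.8, 1.2)
        gray = img.mean(axis=2, keepdims=True)
        img = gray + s * (img - gray)
    return np.clip(img, 0, 255), lab


def _sample_batch(tiles, cfg, rng, class_tiles):
    pw, ph = cfg.patch_size
    imgs, labs = [], []
    for _ in range(cfg.batch_size):
        if cfg.class_balancing and class_tiles:
            cid = list(class_tiles)[int(rng.integers(0, len(class_tiles)))]
            ti = class_tiles[cid][int(rng.integers(0, len(class_tiles[cid])))]
        else:
            ti = int(rng.integers(0, len(tiles)))
        img, lab = tiles[ti]
        h, w = lab.shape
        if w < pw or h < ph:
            raise ValueError("tile smaller than patch size")
        x0 = int(rng.integers(0, w - pw + 1))
        y0 = int(rng.integers(0, h - ph + 1))
        pi = img[y0 : y0 + ph, x0 : x0 + pw]
        pl = lab[y0 : y0 + ph, x0 : x0 + pw]
        pi, pl = _augment(pi, pl, cfg.augmentations, rng)
        imgs.append(pi)
        labs.append(np.ascontiguousarray(pl))
    x = np.stack(imgs).transpose(0, 3, 1, 2).astype(np.float32) / 255.0
    return x, np.stack(labs)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(
    model: ModelHandle,
    dataset: Sequence[tuple[SectionImage, LabelMask]],
    cfg: TrainConfig,
) -> tuple[ModelHandle, TrainHistory]:
    """Train in place with momentum SGD and a plateau-adaptive learning rate.

    ``dataset`` pairs full-resolution images with full-resolution (possibly
    sparsely annotated) masks. Each epoch draws one batch of augmented
    patches, brings the labels to the output grid by block majority, and
    performs one optimizer step. The learning rate starts at ``lr_max`` and
    halves when the smoothed loss stops improving, never leaving
    ``[lr_min, lr_max]``.
    """
    if not dataset:
        raise ValueError("empty dataset")
    schema = model.schema
    k = schema.n_classes
    rng = np.random.Generator(np.random.PCG64(cfg.seed))

    tiles = []
    for img, mask in dataset:
        if mask.downsample_factor != 1:
            raise ValueError("training masks must be full resolution")
        tiles.append((img.pixels, mask.labels))

    # validation split: roughly 1/6 of tiles, at least 1 when we have >= 4
    idx = rng.permutation(len(tiles))
    n_val = max(1, len(tiles) // 6) if len(tiles) >= 4 else 0
    val_tiles = [tiles[i] for i in idx[:n_val]]
    tr_tiles = [tiles[i] for i in idx[n_val:]] or tiles
    if not val_tiles:
        val_tiles = tr_tiles

    # class frequency over training labels at the output grid
    freq = np.zeros(k, dtype=np.float64)
    class_tiles: dict[int, list[int]] = {}
    for ti, (_, lab) in enumerate(tr_tiles):
        ds = downsample_labels_majority(lab, OUTPUT_STRIDE, k)
        c = np.bincount(ds[ds != UNANNOTATED].ravel(), minlength=k)[:k]
        freq += c
        for cid in np.nonzero(c)[0]:
            class_tiles.setdefault(int(cid), []).append(ti)
    if freq.sum() == 0:
        raise ValueError("dataset has no annotated pixels")
    if np.count_nonzero(freq) == 1:
        import warnings

        warnings.warn("dataset contains a single annotated class", stacklevel=2)
    if cfg.class_balancing:
        present = freq > 0
        weights = np.ones(k)
        weights[present] = np.median(freq[present]) / freq[present]
        weights = np.clip(weights, 0.2, 10.0)
    else:
        weights = np.ones(k)

    history = TrainHistory()
    lr = cfg.lr_max
    best = np.inf
    since_best = 0
    patience = max(20, cfg.epochs // 20)
    ema = None
    for _ in range(cfg.epochs):
        x, labs = _sample_batch(tr_tiles, cfg, rng, class_tiles)
        targets = np.stack(
            [downsample_labels_majority(l, OUTPUT_STRIDE, k) for l in labs]
        )
        logits = model.net.forward(x, train=True)
        loss, dlogits, _ = _cross_entropy(logits, targets, weights)
        model.net.backward(dlogits)
        model.net.sgd_step(lr, cfg.momentum)

        ema = loss if ema is None else 0.9 * ema + 0.1 * loss
        if ema < best - 1e-4:
            best, since_best = ema, 0
        else:
            since_best += 1
            if since_best >= patience:
                lr = max(cfg.lr_min, lr * 0.5)
                since_best = 0

        # monitor pixel accuracy on one random validation patch
        vi = int(rng.integers(0, len(val_tiles)))
        vimg, vlab = val_tiles[vi]
        pw, ph = cfg.patch_size
        vx0 = int(rng.integers(0, vlab.shape[1] - pw + 1))
        vy0 = int(rng.integers(0, vlab.shape[0] - ph + 1))
        vpatch = vimg[vy0 : vy0 + ph, vx0 : vx0 + pw]
        vtarget = downsample_labels_majority(
            vlab[vy0 : vy0 + ph, vx0 : vx0 + pw], OUTPUT_STRIDE, k
        )
        vx = vpatch.transpose(2, 0, 1)[None].astype(np.float32) / 255.0
        vlogits = model.net.forward(vx, train=False)
        vpred = vlogits.argmax(axis=1)[0]
        vvalid = vtarget != UNANNOTATED
        vacc = float((vpred[vvalid] == vtarget[vvalid]).mean()) if vvalid.any() else np.nan

        history.loss.append(loss)
        history.val_pixel_accuracy.append(vacc)
        history.learning_rate.append(lr)
    return model, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def predict_scores(model: ModelHandle, image: SectionImage) -> np.ndarray:
    """Per-position class probabilities at the 8x grid, shape (K, H/8, W/8)."""
    h, w = image.height, image.width
    s = model.output_stride
    ph, pw = (-h) % s, (-w) % s
    px = image.pixels
    if ph or pw:
        px = np.pad(px, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    x = px.transpose(2, 0, 1)[None].astype(np.float32) / 255.0
    logits = model.net.forward(x, train=False)
    return _softmax(logits, axis=1)[0]


def predict_mask(
    model: ModelHandle,
    image: SectionImage,
    tile_size: int = 512,
    overlap: int = 0,
) -> LabelMask:
    """Tile-wise segmentation of a section into an 8x-downsampled label mask.

    Tiles are processed independently (scores averaged where tiles overlap);
    per position the predicted class is the argmax of the averaged scores,
    ties broken by the lowest class id (numpy argmax convention).
    """
    if overlap < 0 or overlap >= tile_size:
        raise ValueError("overlap must lie in [0, tile_size)")
    s = model.output_stride
    if tile_size % s or overlap % s:
        raise ValueError(f"tile_size and overlap must be multiples of {s}")
    h, w = image.height, image.width
    gh, gw = -(-h // s), -(-w // s)
    scores = np.zeros((model.class_count, gh, gw), dtype=np.float32)
    hits = np.zeros((gh, gw), dtype=np.float32)
    step = tile_size - overlap
    for y0 in range(0, h, step):
        for x0 in range(0, w, step):
            y1, x1 = min(y0 + tile_size, h), min(x0 + tile_size, w)
            tile = SectionImage(
                image.pixels[y0:y1, x0:x1],
                microns_per_pixel=image.microns_per_pixel,
            )
            p = predict_scores(model, tile)
            gy, gx = y0 // s, x0 // s
            th, tw = -(-(y1 - y0) // s), -(-(x1 - x0) // s)
            scores[:, gy : gy + th, gx : gx + tw] += p[:, :th, :tw]
            hits[gy : gy + th, gx : gx + tw] += 1.0
            if x1 == w:
                break
        if y1 == h:
            break
    labels = (scores / hits).argmax(axis=0).astype(np.uint8)
    return LabelMask(labels, downsample_factor=s)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: ModelHandle, path: str | Path) -> None:
    """Save parameters as .npz with a JSON metadata sidecar."""
    path = Path(path)
    np.savez(path, **model.net.state_dict())
    schema_blob = json.dumps(
        [[c.id, c.name, c.role, list(c.color)] for c in model.schema.classes]
    )
    meta = {
        "class_count": model.class_count,
        "output_stride": model.output_stride,
        "widths": list(model.net.widths),
        "schema": json.loads(schema_blob),
        "schema_sha1": hashlib.sha1(schema_blob.encode()).hexdigest(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1) + "\n")


def load_model(path: str | Path, schema: ClassSchema) -> ModelHandle:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["class_count"] != schema.n_classes:
        raise ValueError("schema class count does not match checkpoint")
    net = EncoderNet(schema.n_classes, meta["widths"], dropout=0.0, seed=0)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as state:
        net.load_state_dict(dict(state))
    return ModelHandle(net, schema)
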