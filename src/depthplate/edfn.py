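"""Encoder-decoder food network (EDFN): architecture, training, inference.

The segmentation backbone is a spliced residual encoder feeding a pyramid
scene-parsing decoder:

* encoder — the stem and first residual block of a pre-activation
  ResNet-style classifier: a 7x7/stride-2 convolution with 64 kernels, a
  3x3/stride-2 max pool, then three bottleneck units (1x1x64, 3x3x64,
  1x1x256 with a skip connection around each set of three), the last 3x3
  carrying stride 2.  A 120x160 RGB input becomes 256 feature maps at
  15x20 — 1/8 scale.  The deeper residual blocks of the classifier are
  spliced off; encoder weights are frozen during training.
* decoder — the 256x15x20 features are max-pooled into four parallel bins
  (1x1, 2x2, 3x3, 6x6), each reduced to 64 channels by a 1x1 convolution
  (a conventional pyramid-pooling reduction), upscaled back to 15x20 and
  concatenated with the encoder maps; a final 1x1 convolution produces the
  two-class (food / not-food) score map, bilinearly upsampled to the input
  resolution before the softmax cross-entropy loss.

Everything here is plain NumPy: im2col convolutions forward, and manual
gradients for the decoder weights (the only trainable ones) under RMSProp.
The classifier's published pretrained weights are an optional initialisation
this package does not ship; the random-init network still honours every
architectural contract and trains end-to-end on synthetic scenes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage.transform import resize

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class EDFNConfig:
    input_shape: tuple[int, int, int] = (120, 160, 3)
    encoder_channels: int = 256
    pyramid_bins: tuple[int, ...] = (1, 2, 3, 6)
    branch_channels: int = 64
    classes: int = 2
    batch_size: int = 32
    learning_rate: float = 1e-4
    decay: float = 0.995
    # "decay" can be read as the RMSProp moving-average coefficient or as a
    # per-epoch learning-rate multiplier; both readings sit behind this key.
    decay_mode: str = "rmsprop"  # rmsprop | lr_schedule
    epochs: int = 200
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        h, w, c = self.input_shape
        if h % 8 or w % 8:
            raise ConfigError(f"input dims {h}x{w} must be divisible by 8")
        if self.classes != 2:
            raise ConfigError("the head is a two-class (food / not food) classifier")
        if self.decay_mode not in ("rmsprop", "lr_schedule"):
            raise ConfigError(f"unknown decay_mode {self.decay_mode!r}")

    @property
    def encoder_shape(self) -> tuple[int, int, int]:
        h, w, _ = self.input_shape
        return (self.encoder_channels, h // 8, w // 8)


# ---------------------------------------------------------------- primitives


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """im2col convolution; x: (C, H, W), w: (O, C, kh, kw) -> (O, H', W')."""
    c, h, wd = x.shape
    o, _, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[1] - kh) // stride + 1
    wo = (x.shape[2] - kw) // stride + 1
    s0, s1, s2 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x,
        shape=(c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s1 * stride, s2 * stride),
    )
    cols = patches.reshape(c * kh * kw, ho * wo)
    out = w.reshape(o, -1) @ cols + b[:, None]
    return out.reshape(o, ho, wo)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1) -> np.ndarray:
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    ho = (xp.shape[1] - k) // stride + 1
    wo = (xp.shape[2] - k) // stride + 1
    s0, s1, s2 = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp,
        shape=(c, ho, wo, k, k),
        strides=(s0, s1 * stride, s2 * stride, s1, s2),
    )
    return patches.max(axis=(3, 4))


def _adaptive_maxpool(x: np.ndarray, bins: int) -> np.ndarray:
    """Max-pool (C, H, W) into a bins x bins grid."""
    c, h, w = x.shape
    out = np.empty((c, bins, bins), dtype=x.dtype)
    for i in range(bins):
        r0, r1 = (i * h) // bins, max(((i + 1) * h) // bins, (i * h) // bins + 1)
        for j in range(bins):
            c0, c1 = (j * w) // bins, max(((j + 1) * w) // bins, (j * w) // bins + 1)
            out[:, i, j] = x[:, r0:r1, c0:c1].max(axis=(1, 2))
    return out


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (n_out x n_in), half-pixel centers."""
    m = np.zeros((n_out, n_in))
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    m[np.arange(n_out), lo] += 1 - frac
    m[np.arange(n_out), hi] += frac
    return m


def _bilinear_resize(x: np.ndarray, h_out: int, w_out: int) -> np.ndarray:
    """(C, H, W) -> (C, h_out, w_out) via separable linear interpolation."""
    a = _interp_matrix(h_out, x.shape[1])
    b = _interp_matrix(w_out, x.shape[2])
    return np.einsum("ij,cjk,lk->cil", a, x, b)


def _bilinear_resize_adjoint(g: np.ndarray, h_in: int, w_in: int) -> np.ndarray:
    a = _interp_matrix(g.shape[1], h_in)
    b = _interp_matrix(g.shape[2], w_in)
    return np.einsum("ij,cik,kl->cjl", a, g, b)


def _he(rng: np.random.Generator, o: int, c: int, kh: int, kw: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (c * kh * kw)), (o, c, kh, kw))


# --------------------------------------------------------------------- model


class EDFN:
    """Model handle: weights plus forward/backward passes.

    ``encoder_weights`` are frozen; ``decoder_weights`` (the pyramid branch
    reductions and the classification head) are the trainable parameters.
    """

    def __init__(self, config: EDFNConfig | None = None, seed: int = 0) -> None:
        self.config = config or EDFNConfig()
        rng = np.random.default_rng(seed)
        cc = self.config.encoder_channels
        bc = self.config.branch_channels
        # encoder: stem + three pre-activation bottleneck units
        self.encoder_weights = {
            "stem": (_he(rng, 64, 3, 7, 7), np.zeros(64)),
            # unit 1: projection skip 64 -> 256
            "u1_a": (_he(rng, 64, 64, 1, 1), np.zeros(64)),
            "u1_b": (_he(rng, 64, 64, 3, 3), np.zeros(64)),
            "u1_c": (_he(rng, cc, 64, 1, 1), np.zeros(cc)),
            "u1_skip": (_he(rng, cc, 64, 1, 1), np.zeros(cc)),
            "u2_a": (_he(rng, 64, cc, 1, 1), np.zeros(64)),
            "u2_b": (_he(rng, 64, 64, 3, 3), np.zeros(64)),
            "u2_c": (_he(rng, cc, 64, 1, 1), np.zeros(cc)),
            # unit 3 downsamples: 3x3 stride 2, strided projection skip
            "u3_a": (_he(rng, 64, cc, 1, 1), np.zeros(64)),
            "u3_b": (_he(rng, 64, 64, 3, 3), np.zeros(64)),
            "u3_c": (_he(rng, cc, 64, 1, 1), np.zeros(cc)),
            "u3_skip": (_he(rng, cc, cc, 1, 1), np.zeros(cc)),
        }
        self.decoder_weights = {}
        for b in self.config.pyramid_bins:
            self.decoder_weights[f"branch{b}"] = (_he(rng, bc, cc, 1, 1), np.zeros(bc))
        head_in = cc + bc * len(self.config.pyramid_bins)
        self.decoder_weights["head"] = (
            _he(rng, self.config.classes, head_in, 1, 1),
            np.zeros(self.config.classes),
        )

    # ------------------------------------------------------------- forward

    def encode(self, image: np.ndarray) -> np.ndarray:
        """RGB (H, W, 3) in [0, 1] -> frozen encoder features (256, H/8, W/8)."""
        h, w, _ = self.config.input_shape
        if image.shape != (h, w, 3):
            raise ConfigError(f"expected input {h}x{w}x3, got {image.shape}")
        x = np.ascontiguousarray(np.asarray(image, dtype=float).transpose(2, 0, 1))
        ew = self.encoder_weights
        x = _conv2d(x, *ew["stem"], stride=2, pad=3)
        x = _maxpool(x, 3, 2, 1)

        def unit(x, a, bconv, c, skip=None, stride=1):
            y = np.maximum(x, 0)  # pre-activation
            s = _conv2d(y, *ew[skip], stride=stride) if skip else x
            y = np.maximum(_conv2d(y, *ew[a]), 0)
            y = np.maximum(_conv2d(y, *ew[bconv], stride=stride, pad=1), 0)
            y = _conv2d(y, *ew[c])
            return y + s

        x = unit(x, "u1_a", "u1_b", "u1_c", skip="u1_skip")
        x = unit(x, "u2_a", "u2_b", "u2_c")
        x = unit(x, "u3_a", "u3_b", "u3_c", skip="u3_skip", stride=2)
        return x

    def decode(self, feats: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Encoder features -> class logits at input resolution."""
        cfg = self.config
        _, fh, fw = feats.shape
        parts = [feats]
        if cache is not None:
            cache["feats"] = feats
        for b in cfg.pyramid_bins:
            pooled = _adaptive_maxpool(feats, b)
            w, bias = self.decoder_weights[f"branch{b}"]
            pre = _conv2d(pooled, w, bias)
            act = np.maximum(pre, 0)
            up = _bilinear_resize(act, fh, fw)
            parts.append(up)
            if cache is not None:
                cache[f"pool{b}"] = pooled
                cache[f"pre{b}"] = pre
        concat = np.concatenate(parts, axis=0)
        if cache is not None:
            cache["concat"] = concat
        w, bias = self.decoder_weights["head"]
        logits = _conv2d(concat, w, bias)
        h, wdt, _ = cfg.input_shape
        return _bilinear_resize(logits, h, wdt)

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Full pass: (H, W, 3) RGB -> (2, H, W) class logits."""
        return self.decode(self.encode(image))

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        """Argmax food mask at input resolution (class 1 = food)."""
        logits = self.forward(image)
        return logits[1] > logits[0]

    def n_encoder_params(self) -> int:
        return sum(w.size + b.size for w, b in self.encoder_weights.values())

    # ------------------------------------------------------------ training

    def _loss_and_grads(self, feats: np.ndarray, target: np.ndarray):
        """Softmax cross-entropy at full resolution + decoder gradients."""
        cfg = self.config
        cache: dict = {}
        logits = self.decode(feats, cache)
        z = logits - logits.max(axis=0, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=0, keepdims=True)
        onehot = np.stack([~target, target]).astype(float)
        n = target.size
        loss = float(-(onehot * np.log(p + 1e-12)).sum() / n)

        g_up = (p - onehot) / n
        _, fh, fw = feats.shape
        g_logits = _bilinear_resize_adjoint(g_up, fh, fw)

        grads: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        w_head, _ = self.decoder_weights["head"]
        concat = cache["concat"]
        grads["head"] = (
            np.einsum("ohw,chw->oc", g_logits, concat)[:, :, None, None],
            g_logits.sum(axis=(1, 2)),
        )
        g_concat = np.einsum("oc,ohw->chw", w_head[:, :, 0, 0], g_logits)
        ofs = cfg.encoder_channels
        bc = cfg.branch_channels
        for b in cfg.pyramid_bins:
            g_up_b = g_concat[ofs : ofs + bc]
            ofs += bc
            g_act = _bilinear_resize_adjoint(g_up_b, b, b)
            g_pre = g_act * (cache[f"pre{b}"] > 0)
            pooled = cache[f"pool{b}"]
            grads[f"branch{b}"] = (
                np.einsum("ohw,chw->oc", g_pre, pooled)[:, :, None, None],
                g_pre.sum(axis=(1, 2)),
            )
        return loss, grads

    def evaluate_loss(self, feats_list, targets) -> float:
        total = 0.0
        for feats, target in zip(feats_list, targets):
            loss, _ = self._loss_and_grads(feats, target)
            total += loss
        return total / len(feats_list)


@dataclass
class TrainResult:
    model: EDFN
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    split: tuple[np.ndarray, np.ndarray]  # train / validation indices


def prepare_sample(image: np.ndarray, mask: np.ndarray, config: EDFNConfig):
    """Resize an (RGB, mask) pair to the network input resolution."""
    h, w, _ = config.input_shape
    img = resize(np.asarray(image, dtype=float) / 255.0, (h, w, 3), order=1, anti_aliasing=True)
    m = resize(np.asarray(mask, dtype=float), (h, w), order=0, anti_aliasing=False) > 0.5
    return img, m


def train_edfn(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    config: EDFNConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
) -> TrainResult:
    """Train the decoder (encoder frozen) with RMSProp + best-checkpoint keep.

    Images and masks may be at any resolution; they are resized to the
    network input size (masks nearest-neighbour).  The dataset is split
    80/20 into training and validation with a seeded shuffle, and the
    weights minimising validation loss across epochs are returned.
    """
    config = config or EDFNConfig()
    if len(images) != len(masks) or any(m is None for m in masks):
        raise DataError("every training image needs a mask")
    model = EDFN(config, seed=seed)
    rng = np.random.default_rng(seed + 1)

    pairs = [prepare_sample(im, mk, config) for im, mk in zip(images, masks)]
    feats = [model.encode(im) for im, _ in pairs]  # frozen: encode once
    targets = [mk for _, mk in pairs]

    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(config.val_fraction * len(pairs))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        raise DataError("dataset too small to split")

    rho = config.decay if config.decay_mode == "rmsprop" else 0.9
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    eps = 1e-8
    best = {k: (w.copy(), b.copy()) for k, (w, b) in model.decoder_weights.items()}
    best_val, best_epoch = np.inf, -1
    train_hist, val_hist = [], []

    n_epochs = config.epochs if epochs is None else epochs
    for epoch in range(n_epochs):
        lr = config.learning_rate
        if config.decay_mode == "lr_schedule":
            lr *= config.decay**epoch
        perm = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start : start + config.batch_size]
            acc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for i in batch:
                loss, grads = model._loss_and_grads(feats[i], targets[i])
                epoch_loss += loss
                for k, (gw, gb) in grads.items():
                    if k in acc:
                        acc[k] = (acc[k][0] + gw, acc[k][1] + gb)
                    else:
                        acc[k] = (gw, gb)
            for k, (gw, gb) in acc.items():
                gw, gb = gw / len(batch), gb / len(batch)
                if k not in cache:  # warm start avoids the cold-cache step spike
                    cache[k] = (gw**2, gb**2)
                cw, cb = cache[k]
                cw[:] = rho * cw + (1 - rho) * gw**2
                cb[:] = rho * cb + (1 - rho) * gb**2
                w, b = model.decoder_weights[k]
                model.decoder_weights[k] = (
                    w - lr * gw / (np.sqrt(cw) + eps),
                    b - lr * gb / (np.sqrt(cb) + eps),
                )
        train_hist.append(epoch_loss / len(perm))
        val = model.evaluate_loss([feats[i] for i in val_idx], [targets[i] for i in val_idx])
        val_hist.append(val)
        if val < best_val:
            best_val, best_epoch = val, epoch
            best = {k: (w.copy(), b.copy()) for k, (w, b) in model.decoder_weights.items()}

    model.decoder_weights = best
    return TrainResult(
        model=model,
        train_loss=train_hist,
        val_loss=val_hist,
        best_epoch=best_epoch,
        split=(train_idx, val_idx),
    )


# ---------------------------------------------------------- augmentation


def augment_background_hue(
    rgb: np.ndarray, food_mask: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Rotate the hue of background (non-food) pixels by a random angle.

    The rotation angle is uniform over the full hue circle; food pixels are
    copied through bitwise unchanged, and background value/saturation
    survive the HSV round-trip up to 8-bit quantisation.
    """
    rgb = np.asarray(rgb)
    food_mask = np.asarray(food_mask, dtype=bool)
    if food_mask.shape != rgb.shape[:2]:
        raise DataError("mask not aligned with image")
    angle = float(np.random.default_rng(seed).uniform(0.0, 1.0))
    hsv = skcolor.rgb2hsv(rgb)
    hsv[..., 0] = (hsv[..., 0] + angle) % 1.0
    out = (skcolor.hsv2rgb(hsv) * 255.0).round().astype(np.uint8)
    out[food_mask] = rgb[food_mask]
    return out
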