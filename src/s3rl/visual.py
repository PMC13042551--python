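"""Contrastive learning of per-spot visual features from histology patches.

Two augmented views of each patch (random crop, flips, color distortion)
form a positive pair; views of different patches are negatives.  A small
convolutional encoder with an MLP projection head is trained with the
normalized temperature-scaled cross-entropy (NT-Xent) objective, and the
trained encoder applied to the un-augmented patches yields a 256-dimensional
semantic embedding per spot.

The default backbone is ``tiny_cnn``, a compact randomly initialized
convolutional encoder trained from scratch — sufficient for the
color/texture statistics that distinguish tissue domains at patch scale and
requiring no external weights.  A ``pretrained_resnet50`` backbone slot
exists in the config for environments that provide local weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Parameter, Tensor, take_cols, take_rows

__all__ = [
    "ContrastiveConfig",
    "VisualFeatures",
    "augment_patch",
    "contrastive_loss",
    "TinyCNN",
    "train_visual_encoder",
]


@dataclass
class VisualFeatures:
    """Per-spot semantic embedding H (n_spots × 256) with the training trace."""

    H: np.ndarray
    loss_trace: list = field(default_factory=list)

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float64)
        if not np.all(np.isfinite(self.H)):
            raise ValueError("visual features must be finite")


@dataclass
class ContrastiveConfig:
    temperature: float = 0.5
    learning_rate: float = 0.005
    weight_decay: float = 1e-6
    epochs: int = 500
    batch_size: int = 256
    backbone: str = "tiny_cnn"
    projection_dim: int = 256
    denominator: str = "standard"  # or "paper_printed"
    # augmentation strengths (crop area fraction range, flip prob, jitter)
    crop_scale: tuple[float, float] = (0.6, 1.0)
    flip_prob: float = 0.5
    color_jitter: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be ≥ 2 (a batch needs negatives)")
        if self.denominator not in ("standard", "paper_printed"):
            raise ValueError("denominator must be 'standard' or 'paper_printed'")


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

def _crop_resize(img: np.ndarray, y0: float, x0: float, ch: float, cw: float,
                 out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resample of the crop box [y0, y0+ch) × [x0, x0+cw)."""
    h, w = img.shape[:2]
    ys = y0 + (np.arange(out_h) + 0.5) * ch / out_h - 0.5
    xs = x0 + (np.arange(out_w) + 0.5) * cw / out_w - 0.5
    ys = np.clip(ys, 0, h - 1)
    xs = np.clip(xs, 0, w - 1)
    y0i = np.floor(ys).astype(int)
    x0i = np.floor(xs).astype(int)
    y1i = np.minimum(y0i + 1, h - 1)
    x1i = np.minimum(x0i + 1, w - 1)
    fy = (ys - y0i)[:, None, None]
    fx = (xs - x0i)[None, :, None]
    top = img[y0i][:, x0i] * (1 - fx) + img[y0i][:, x1i] * fx
    bot = img[y1i][:, x0i] * (1 - fx) + img[y1i][:, x1i] * fx
    return top * (1 - fy) + bot * fy


def _augment_once(img: np.ndarray, cfg: ContrastiveConfig,
                  rng: np.random.Generator) -> np.ndarray:
    h, w = img.shape[:2]
    out = img
    lo, hi = cfg.crop_scale
    if hi < 1.0 or lo < 1.0:
        area = rng.uniform(lo, hi)
        side = np.sqrt(area)
        ch, cw = side * h, side * w
        y0 = rng.uniform(0, h - ch)
        x0 = rng.uniform(0, w - cw)
        out = _crop_resize(out, y0, x0, ch, cw, h, w)
    if cfg.flip_prob > 0:
        if rng.random() < cfg.flip_prob:
            out = out[:, ::-1]
        if rng.random() < cfg.flip_prob:
            out = out[::-1, :]
    s = cfg.color_jitter
    if s > 0:
        out = out * (1.0 + rng.uniform(-s, s))                      # brightness
        m = out.mean()
        out = (out - m) * (1.0 + rng.uniform(-s, s)) + m            # contrast
        gray = out.mean(axis=2, keepdims=True)
        f = 1.0 + rng.uniform(-s, s)                                 # saturation
        out = gray + (out - gray) * f
        out = np.clip(out, 0.0, 1.0)
    return np.ascontiguousarray(out)


def augment_patch(patch: np.ndarray, rng: np.random.Generator,
                  config: ContrastiveConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Two independently augmented views of one patch (floats in [0, 1]).

    With all augmentation strengths at zero both views equal the input.
    All randomness comes from the supplied generator.
    """
    config = config or ContrastiveConfig()
    img = np.asarray(patch, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    return _augment_once(img, config, rng), _augment_once(img, config, rng)


# ---------------------------------------------------------------------------
# NT-Xent loss
# ---------------------------------------------------------------------------

def contrastive_loss(features: np.ndarray, temperature: float = 0.5,
                     denominator: str = "standard") -> float:
    """Mean NT-Xent over all 2N anchors; rows paired as (i, i+N).

    ``standard``: the denominator for anchor a sums exp(sim/τ) over all
    other 2N−1 rows.  ``paper_printed``: the positive-pair term is also
    omitted from the denominator (2N−2 terms), changing only normalization.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    F = np.asarray(features, dtype=np.float64)
    n2 = F.shape[0]
    if n2 < 4 or n2 % 2:
        raise ValueError("features must hold 2N rows with N ≥ 2")
    N = n2 // 2
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    Fn = F / np.where(norms == 0, 1.0, norms)
    sim = (Fn @ Fn.T) / temperature
    pos = np.concatenate([np.arange(N, 2 * N), np.arange(N)])
    mask = ~np.eye(n2, dtype=bool)
    if denominator == "paper_printed":
        mask = mask.copy()
        mask[np.arange(n2), pos] = False
    elif denominator != "standard":
        raise ValueError("denominator must be 'standard' or 'paper_printed'")
    # stable log-sum-exp per anchor over the allowed columns
    logits = np.where(mask, sim, -np.inf)
    mx = logits.max(axis=1)
    lse = mx + np.log(np.exp(logits - mx[:, None]).sum(axis=1))
    return float(np.mean(lse - sim[np.arange(n2), pos]))


def _contrastive_loss_t(z: Tensor, temperature: float,
                        denominator: str) -> Tensor:
    """Autodiff NT-Xent on projection rows paired (i, i+N)."""
    n2 = z.shape[0]
    N = n2 // 2
    eps = 1e-12
    norms = ((z * z).sum(axis=1, keepdims=True) + eps).sqrt()
    zn = z / norms
    sim = (zn @ zn.T) / temperature
    pos = np.concatenate([np.arange(N, 2 * N), np.arange(N)])
    mask = np.zeros((n2, n2))
    np.fill_diagonal(mask, -1e9)
    if denominator == "paper_printed":
        mask[np.arange(n2), pos] = -1e9
    masked = sim + Tensor(mask)
    # shift by detached row max for stability
    shift = Tensor(masked.data.max(axis=1, keepdims=True))
    lse = (masked - shift).exp().sum(axis=1).log() + shift.reshape(n2)
    # positive similarities: rows of zn dotted with their partners
    pos_sim = (zn * take_rows(zn, pos)).sum(axis=1) / temperature
    return (lse - pos_sim).mean()


# ---------------------------------------------------------------------------
# tiny convolutional encoder
# ---------------------------------------------------------------------------

class _Conv2d:
    """Valid convolution (stride 2) via an index-gather + matmul."""

    def __init__(self, in_h: int, in_w: int, in_c: int, out_c: int,
                 ksize: int, stride: int, rng: np.random.Generator):
        self.out_h = (in_h - ksize) // stride + 1
        self.out_w = (in_w - ksize) // stride + 1
        self.out_c = out_c
        fan_in = ksize * ksize * in_c
        self.W = Parameter(rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, out_c)))
        self.b = Parameter(np.zeros(out_c))
        # flat channel-last gather indices, one block per output position
        idx = []
        for oy in range(self.out_h):
            for ox in range(self.out_w):
                for ky in range(ksize):
                    for kx in range(ksize):
                        for c in range(in_c):
                            idx.append(((oy * stride + ky) * in_w + (ox * stride + kx)) * in_c + c)
        self._idx = np.asarray(idx, dtype=np.intp)
        self._fan_in = fan_in

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, in_h*in_w*in_c) channel-last
        B = x.shape[0]
        cols = take_cols(x, self._idx)
        cols = cols.reshape(B * self.out_h * self.out_w, self._fan_in)
        out = cols @ self.W + self.b
        return out.elu().reshape(B, self.out_h * self.out_w * self.out_c)

    @property
    def params(self):
        return [self.W, self.b]


class TinyCNN:
    """Two strided conv layers + a two-layer MLP projection head → 256-d."""

    def __init__(self, patch_h: int, patch_w: int, projection_dim: int = 256,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv1 = _Conv2d(patch_h, patch_w, 3, 8, 3, 2, rng)
        self.conv2 = _Conv2d(self.conv1.out_h, self.conv1.out_w, 8, 16, 3, 2, rng)
        flat = self.conv2.out_h * self.conv2.out_w * 16
        self.W3 = Parameter(rng.normal(0, np.sqrt(2.0 / flat), (flat, 128)))
        self.b3 = Parameter(np.zeros(128))
        self.W4 = Parameter(rng.normal(0, np.sqrt(2.0 / 128), (128, projection_dim)))
        self.b4 = Parameter(np.zeros(projection_dim))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x))
        h = (h @ self.W3 + self.b3).elu()
        return h @ self.W4 + self.b4

    def embed(self, patches: np.ndarray) -> np.ndarray:
        """Apply the trained encoder to un-augmented patches (floats in [0,1])."""
        flat = patches.reshape(patches.shape[0], -1)
        return self(Tensor(flat)).data

    @property
    def params(self):
        return (self.conv1.params + self.conv2.params
                + [self.W3, self.b3, self.W4, self.b4])


def train_visual_encoder(patches: np.ndarray,
                         config: ContrastiveConfig | None = None) -> VisualFeatures:
    """Train the contrastive encoder and embed every spot's patch.

    Returns the 256-d features of the *un-augmented* patches together with
    the per-epoch mean training loss.  Runs are reproducible for a fixed
    config and seed.
    """
    config = config or ContrastiveConfig()
    if config.backbone == "pretrained_resnet50":
        raise NotImplementedError(
            "pretrained_resnet50 requires local backbone weights; use "
            "backbone='tiny_cnn'"
        )
    if config.backbone != "tiny_cnn":
        raise ValueError(f"unknown backbone: {config.backbone!r}")
    patches = np.asarray(patches, dtype=np.float64)
    if patches.max() > 1.0:
        patches = patches / 255.0
    n, h, w, _ = patches.shape
    rng = np.random.default_rng(config.seed)
    model = TinyCNN(h, w, config.projection_dim, seed=config.seed)
    opt = Adam(model.params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    trace: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            if batch.size < 2:
                continue  # a single sample has no negatives
            views = [augment_patch(patches[i], rng, config) for i in batch]
            v1 = np.stack([a for a, _ in views]).reshape(batch.size, -1)
            v2 = np.stack([b for _, b in views]).reshape(batch.size, -1)
            z = model(Tensor(np.concatenate([v1, v2], axis=0)))
            loss = _contrastive_loss_t(z, config.temperature, config.denominator)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)) if losses else np.nan)
    return VisualFeatures(H=model.embed(patches), loss_trace=trace)
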