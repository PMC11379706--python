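"""Prototypical-part classification network.

A model maps an image through a convolutional encoder to a latent volume of
shape [H x W x D], viewed as H*W patches of size 1x1xD.  Classification
scores each patch against a set of learned prototype vectors (squared-L2
distance, converted to a log similarity), max-pools the similarity per
prototype, and applies a linear layer followed by softmax.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _net
from .errors import ConfigurationError, NumericError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-4  # stabilizer in the distance -> similarity transform


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledImage:
    """A single image with a binary label.

    pixels are float in [0,1], shape (H, W, C) with C in {1, 3}.
    """
    pixels: np.ndarray
    label: int
    image_id: str
    biased: bool = False

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3:
            raise ValidationError(f"pixels must be (H, W, C), got shape {px.shape}")
        h, w, c = px.shape
        if h < 16 or w < 16:
            raise ValidationError(f"image {self.image_id}: size {h}x{w} below 16x16")
        if c not in (1, 3):
            raise ValidationError(f"image {self.image_id}: {c} channels, expected 1 or 3")
        if not np.all(np.isfinite(px)):
            raise ValidationError(f"image {self.image_id}: non-finite pixels")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError(f"image {self.image_id}: pixels outside [0, 1]")
        object.__setattr__(self, 'pixels', px)


# A client's private shard is simply a list of LabeledImage.
ClientDataset = list


@dataclass
class PrototypeSet:
    """m prototype vectors of length D plus their class assignment."""
    vectors: np.ndarray          # (m, D)
    class_of: np.ndarray         # (m,) int
    per_class: int

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.class_of = np.asarray(self.class_of, dtype=int)
        if self.vectors.ndim != 2:
            raise ValidationError("prototype vectors must be 2-D (m, D)")
        if self.class_of.shape != (self.vectors.shape[0],):
            raise ValidationError("class_of length must equal prototype count")
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("non-finite prototype entries")

    @property
    def m(self) -> int:
        return self.vectors.shape[0]

    @property
    def depth(self) -> int:
        return self.vectors.shape[1]

    def copy(self) -> 'PrototypeSet':
        return PrototypeSet(self.vectors.copy(), self.class_of.copy(), self.per_class)


@dataclass
class ModelParams:
    """All learnable parameters of one model."""
    conv_weights: dict           # backbone ('conv*') + add-on ('addon*') arrays
    prototypes: PrototypeSet
    final_weights: np.ndarray    # (m, K)
    backbone: str = 'small_cnn'
    image_shape: tuple = (64, 64, 1)
    eps: float = DEFAULT_EPSILON

    def __post_init__(self):
        self.final_weights = np.asarray(self.final_weights, dtype=float)
        if self.final_weights.shape[0] != self.prototypes.m:
            raise ValidationError("final_weights must have one row per prototype")

    @property
    def n_classes(self) -> int:
        return self.final_weights.shape[1]

    def copy(self) -> 'ModelParams':
        return ModelParams(
            conv_weights={k: v.copy() for k, v in self.conv_weights.items()},
            prototypes=self.prototypes.copy(),
            final_weights=self.final_weights.copy(),
            backbone=self.backbone,
            image_shape=self.image_shape,
            eps=self.eps,
        )

    def backbone_keys(self) -> list:
        return [k for k in self.conv_weights if k.startswith('conv')]

    def addon_keys(self) -> list:
        return [k for k in self.conv_weights if k.startswith('addon')]


@dataclass
class TrainConfig:
    epochs: int = 10
    lr_warm: float = 3e-3
    lr_joint: float = 1e-3
    lambda_cluster: float = 0.8
    lambda_separation: float = 0.08
    batch_size: int = 32
    seed: int = 0
    frozen_backbone: bool = False
    train_final_layer: Optional[bool] = None  # default: only when backbone unfrozen

    def __post_init__(self):
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.lambda_cluster < 0 or self.lambda_separation < 0:
            raise ValidationError("loss coefficients must be >= 0")

    def replace(self, **kw) -> 'TrainConfig':
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def init_final_layer(class_of: Sequence[int], n_classes: int) -> np.ndarray:
    """Final-layer init: +1 on a prototype's own class, -0.5 on every other."""
    class_of = np.asarray(class_of, dtype=int)
    if class_of.size and (class_of.min() < 0 or class_of.max() >= n_classes):
        raise ValidationError("prototype class index out of range")
    w = np.full((class_of.shape[0], n_classes), -0.5)
    w[np.arange(class_of.shape[0]), class_of] = 1.0
    return w


def build_model(image_shape=(64, 64, 1), depth=32, per_class=10, n_classes=2,
                backbone='small_cnn', seed=0) -> ModelParams:
    """Build a randomly initialized model.

    depth is the number of channels D of the add-on layers and hence the
    prototype length; per_class prototypes are allocated to each class and
    initialized uniformly on [0, 1] to match the Sigmoid-bounded latent space.
    """
    if depth < 1 or per_class < 1 or n_classes < 1:
        raise ConfigurationError("depth, per_class and n_classes must be >= 1")
    out_ch = _net.backbone_out_channels(backbone)
    rng = np.random.default_rng(seed)
    conv = _net.BACKBONES[backbone](rng, image_shape[2])
    conv.update(_net.init_addon(rng, out_ch, depth))
    class_of = np.repeat(np.arange(n_classes), per_class)
    protos = PrototypeSet(rng.uniform(0.0, 1.0, (per_class * n_classes, depth)),
                          class_of, per_class)
    final = init_final_layer(class_of, n_classes)
    return ModelParams(conv, protos, final, backbone=backbone,
                       image_shape=tuple(image_shape))


# ---------------------------------------------------------------------------
# forward-pass operations
# ---------------------------------------------------------------------------

def _as_batch(images) -> np.ndarray:
    if isinstance(images, LabeledImage):
        images = [images]
    return np.stack([im.pixels if isinstance(im, LabeledImage) else np.asarray(im)
                     for im in images])


def embed_batch(images, params: ModelParams) -> np.ndarray:
    """Encode a batch of images; returns latent volumes (B, H, W, D)."""
    x = _as_batch(images)
    if x.shape[1:] != tuple(params.image_shape):
        raise ValidationError(
            f"image shape {x.shape[1:]} does not match model input "
            f"{tuple(params.image_shape)}")
    z, _ = _net.encode(x, params.conv_weights)
    return z


def embed(image, params: ModelParams) -> np.ndarray:
    """Encode one image into its latent volume [H x W x D], values in [0,1]."""
    return embed_batch([image], params)[0]


def prototype_distances(z: np.ndarray, protos: PrototypeSet) -> np.ndarray:
    """Squared L2 distance between every prototype and every latent patch.

    z: (H, W, D); returns (m, H, W).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 3:
        raise ValidationError("latent volume must be 3-D (H, W, D)")
    if z.shape[-1] != protos.depth:
        raise ValidationError(
            f"latent depth {z.shape[-1]} != prototype depth {protos.depth}")
    h, w, _ = z.shape
    zf = z.reshape(1, h * w, -1)
    dist = _net.patch_distances(zf, protos.vectors)[0]  # (m, HW)
    return dist.reshape(protos.m, h, w)


def similarity_from_distance(dist, eps: float = DEFAULT_EPSILON):
    """log((d+1)/(d+eps)): strictly decreasing in d, range (0, log(1/eps)]."""
    dist = np.asarray(dist, dtype=float)
    if np.any(dist < 0):
        raise ValidationError("distances must be >= 0")
    if not (0.0 < eps < 1.0):
        raise ValidationError("eps must be in (0, 1)")
    return np.log((dist + 1.0) / (dist + eps))


def classify(z: np.ndarray, protos: PrototypeSet, final_weights: np.ndarray,
             eps: float = DEFAULT_EPSILON):
    """Classify one latent volume.

    Returns (probabilities of length K, max-pooled similarity per prototype).
    """
    dist = prototype_distances(z, protos)
    sim = similarity_from_distance(dist, eps)
    top = sim.reshape(protos.m, -1).max(axis=1)
    logits = top @ np.asarray(final_weights, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise NumericError("non-finite logits")
    logits = logits - logits.max()
    ex = np.exp(logits)
    return ex / ex.sum(), top


def predict_batch(images, params: ModelParams) -> np.ndarray:
    """Argmax class prediction for a batch of images."""
    z = embed_batch(images, params)
    B = z.shape[0]
    zf = z.reshape(B, -1, z.shape[-1])
    dist = _net.patch_distances(zf, params.prototypes.vectors)
    sim = np.log((dist + 1.0) / (dist + params.eps))
    top = sim.max(axis=2)
    logits = top @ params.final_weights
    return logits.argmax(axis=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_arrays(batch, params):
    x = _as_batch(batch)
    y = np.array([im.label for im in batch], dtype=int)
    if y.size and (y.min() < 0 or y.max() >= params.n_classes):
        raise ValidationError("label outside the model's classes")
    return x, y


def loss(batch, params: ModelParams, cfg: TrainConfig) -> float:
    """Training objective on one batch:

    cross-entropy + lambda_cluster * cluster_cost
                  - lambda_separation * separation_cost_magnitude

    where cluster_cost is the mean (over images) min distance to any
    same-class prototype and the separation term is the mean min distance to
    any wrong-class prototype (entering with a negative sign).
    """
    if len(batch) == 0:
        raise ValidationError("empty batch")
    x, y = _batch_arrays(batch, params)
    z, _ = _net.encode(x, params.conv_weights)
    value, _, _ = _net.head_forward(
        z, params.prototypes.vectors, params.final_weights,
        params.prototypes.class_of, y, params.eps,
        cfg.lambda_cluster, cfg.lambda_separation)
    if not np.isfinite(value):
        raise NumericError("non-finite loss")
    return float(value)


def _trainable_keys(params: ModelParams, cfg: TrainConfig):
    keys = params.addon_keys() + ['prototypes']
    if not cfg.frozen_backbone:
        keys += params.backbone_keys()
    train_final = cfg.train_final_layer
    if train_final is None:
        train_final = not cfg.frozen_backbone
    if train_final:
        keys.append('final_weights')
    return keys


def train_local(dataset, params: ModelParams, cfg: TrainConfig,
                epoch_offset: int = 0) -> ModelParams:
    """Train a copy of `params` on one client's shard for cfg.epochs epochs.

    With cfg.frozen_backbone only the add-on layers and prototypes are
    optimized (warm-up regime); otherwise all parameters are.  The per-epoch
    shuffle is seeded from (cfg.seed, epoch_offset + epoch) so that a
    schedule split into segments reproduces the monolithic run exactly.
    """
    if len(dataset) == 0:
        raise ValidationError("empty dataset")
    out = params.copy()
    flat = dict(out.conv_weights)
    flat['prototypes'] = out.prototypes.vectors
    flat['final_weights'] = out.final_weights

    keys = _trainable_keys(out, cfg)
    lr = cfg.lr_warm if cfg.frozen_backbone else cfg.lr_joint
    opt = _net.Adam(keys, lr)
    x_all = _as_batch(dataset)
    y_all = np.array([im.label for im in dataset], dtype=int)
    if y_all.min() < 0 or y_all.max() >= out.n_classes:
        raise ValidationError("label outside the model's classes")
    n = len(dataset)
    need_conv = not cfg.frozen_backbone
    last = float('nan')
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng([cfg.seed, epoch_offset + epoch])
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            value, _, grads = _net.forward_backward(
                x_all[idx], y_all[idx], flat, flat['prototypes'],
                flat['final_weights'], out.prototypes.class_of,
                out.eps, cfg.lambda_cluster, cfg.lambda_separation,
                need_conv_grads=need_conv)
            opt.step(flat, grads)
            losses.append(value)
        last = float(np.mean(losses))
    logger.info("train_local: %d epochs (offset %d), last-epoch loss %.4f",
                cfg.epochs, epoch_offset, last)

    out.prototypes.vectors = flat.pop('prototypes')
    out.final_weights = flat.pop('final_weights')
    out.conv_weights = flat
    return out


def train_final_layer_only(dataset, params: ModelParams, cfg: TrainConfig,
                           lr: float = 1e-3) -> ModelParams:
    """Optimize only the final linear layer (cross-entropy, full batch).

    Keeps the best-loss iterate, so the training cross-entropy never
    increases relative to the input parameters.
    """
    if len(dataset) == 0:
        raise ValidationError("empty dataset")
    out = params.copy()
    x, y = _batch_arrays(dataset, out)
    z, _ = _net.encode(x, out.conv_weights)
    flat = {'final_weights': out.final_weights}
    opt = _net.Adam(['final_weights'], lr)

    def ce_of(w):
        val, _, cache = _net.head_forward(
            z, out.prototypes.vectors, w, out.prototypes.class_of, y,
            out.eps, 0.0, 0.0)
        return val, cache

    best_w = out.final_weights.copy()
    best, cache = ce_of(best_w)
    for _ in range(cfg.epochs):
        _, _, dfinal = _net.head_backward(
            z.shape, out.prototypes.vectors, flat['final_weights'], y,
            out.eps, 0.0, 0.0, cache)
        opt.step(flat, {'final_weights': dfinal})
        val, cache = ce_of(flat['final_weights'])
        if val < best:
            best = val
            best_w = flat['final_weights'].copy()
    out.final_weights = best_w
    return out
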