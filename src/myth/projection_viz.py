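"""Prototype push (projection) and activation-map visualization.

Push replaces each learned prototype with the nearest same-class latent
training patch, making it exactly visualizable.  Visualization upsamples a
prototype's similarity map to image size and draws the tightest rectangle
around all pixels at or above the 95th-percentile activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from PIL import Image, ImageDraw
from skimage.transform import resize

from .errors import NumericError, ValidationError
from .model_core import (ModelParams, PrototypeSet, embed, embed_batch,
                         prototype_distances, similarity_from_distance)


@dataclass
class PrototypeBox:
    """Axis-aligned, 0-based, half-open rectangle [r0:r1, c0:c1] on an image."""
    prototype_id: int
    image_id: str
    box: tuple                    # (r0, c0, r1, c1)
    threshold: float
    peak: tuple                   # (row, col) of the activation argmax

    def __post_init__(self):
        r0, c0, r1, c1 = self.box
        if not (0 <= r0 < r1 and 0 <= c0 < c1):
            raise ValidationError(f"degenerate box {self.box}")
        pr, pc = self.peak
        if not (r0 <= pr < r1 and c0 <= pc < c1):
            raise ValidationError("peak outside box")

    @property
    def area(self) -> int:
        r0, c0, r1, c1 = self.box
        return (r1 - r0) * (c1 - c0)


@dataclass
class ActivationMap:
    raw: np.ndarray               # (H, W) latent-grid similarities
    upsampled: np.ndarray         # (H_img, W_img)


def push_prototypes(params: ModelParams, train_shard):
    """Project every prototype onto its nearest same-class latent patch.

    Returns (new ModelParams, provenance) where provenance is a list of dicts
    with keys prototype_id, image_id, h, w, distance.  Ties are broken by the
    shard order of images, then row-major patch position.
    """
    if len(train_shard) == 0:
        raise ValidationError("empty training shard")
    out = params.copy()
    protos = out.prototypes
    labels = np.array([im.label for im in train_shard])
    for cls in np.unique(protos.class_of):
        if not np.any(labels == cls):
            raise ValidationError(
                f"class {cls} owns prototypes but has no training images")

    best_dist = np.full(protos.m, np.inf)
    best_patch = np.zeros_like(protos.vectors)
    provenance = [None] * protos.m
    for im in train_shard:
        z = embed(im, params)
        dist = prototype_distances(z, protos)        # (m, H, W)
        h, w = z.shape[:2]
        flat = dist.reshape(protos.m, -1)
        for j in range(protos.m):
            if protos.class_of[j] != im.label:
                continue
            k = int(flat[j].argmin())
            if flat[j, k] < best_dist[j]:            # strict: earlier image wins ties
                best_dist[j] = flat[j, k]
                r, c = divmod(k, w)
                best_patch[j] = z[r, c]
                provenance[j] = {'prototype_id': j, 'image_id': im.image_id,
                                 'h': r, 'w': c, 'distance': float(flat[j, k])}
    out.prototypes.vectors = best_patch
    return out, provenance


def upsample_activation(raw: np.ndarray, target_shape,
                        method: str = 'bilinear') -> np.ndarray:
    """Upsample a latent-grid activation map to image size."""
    raw = np.asarray(raw, dtype=float)
    h_img, w_img = target_shape
    if h_img < raw.shape[0] or w_img < raw.shape[1]:
        raise ValidationError("target smaller than source map")
    order = {'bilinear': 1, 'nearest': 0}.get(method)
    if order is None:
        raise ValidationError(f"unknown upsampling method {method!r}")
    return resize(raw, (h_img, w_img), order=order, mode='edge',
                  anti_aliasing=False, preserve_range=True)


def prototype_bbox(upsampled: np.ndarray, percentile: float = 95.0,
                   prototype_id: int = -1, image_id: str = '') -> PrototypeBox:
    """Tightest rectangle over all pixels >= the given activation percentile."""
    amap = np.asarray(upsampled, dtype=float)
    if not np.all(np.isfinite(amap)):
        raise NumericError("non-finite activation map")
    threshold = float(np.percentile(amap, percentile))
    rows, cols = np.nonzero(amap >= threshold)
    peak_flat = int(amap.argmax())
    peak = (peak_flat // amap.shape[1], peak_flat % amap.shape[1])
    return PrototypeBox(
        prototype_id=prototype_id,
        image_id=image_id,
        box=(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1),
        threshold=threshold,
        peak=peak,
    )


def most_activated_patch(image, params: ModelParams, percentile: float = 95.0):
    """Find the prototype with the highest pooled similarity on this image.

    Returns (prototype_id, PrototypeBox, similarity); ties resolved by the
    lowest prototype id.
    """
    z = embed(image, params)
    dist = prototype_distances(z, params.prototypes)
    sim = similarity_from_distance(dist, params.eps)
    pooled = sim.reshape(params.prototypes.m, -1).max(axis=1)
    j = int(pooled.argmax())                          # first max -> lowest id
    image_id = getattr(image, 'image_id', '')
    upsampled = upsample_activation(sim[j], image.pixels.shape[:2])
    box = prototype_bbox(upsampled, percentile, prototype_id=j, image_id=image_id)
    return j, box, float(pooled[j])


_PALETTE = [(66, 135, 245), (245, 130, 48), (60, 180, 75), (230, 25, 75),
            (145, 30, 180), (255, 225, 25)]


def render_overlay(image, boxes, labels=None, out_path=None):
    """Draw box perimeters (and optional text labels) on an image; save PNG.

    Pixels outside the one-pixel-wide box strokes (and label text, when
    given) are left untouched.  Returns the PIL image.
    """
    pixels = image.pixels if hasattr(image, 'pixels') else np.asarray(image)
    h, w = pixels.shape[:2]
    arr = (np.clip(pixels, 0, 1) * 255).astype(np.uint8)
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    pil = Image.fromarray(arr)
    draw = ImageDraw.Draw(pil)
    for i, b in enumerate(boxes):
        r0, c0, r1, c1 = b.box
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValidationError(f"box {b.box} out of image bounds {h}x{w}")
        color = _PALETTE[i % len(_PALETTE)]
        # PIL rectangle corners are inclusive; half-open box -> subtract 1
        draw.rectangle([c0, r0, c1 - 1, r1 - 1], outline=color, width=1)
        if labels is not None and i < len(labels) and labels[i]:
            draw.text((c0 + 2, max(r0 - 10, 0)), str(labels[i]), fill=color)
    if out_path is not None:
        pil.save(out_path, format='PNG')
    return pil
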