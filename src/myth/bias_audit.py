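"""Bias injection and the local-vs-global prototype audit.

The audit follows a four-step scheme: each client trains a local model;
the federation trains a global (and optionally personalized) model; each
client visualizes the most activated patches of each model on its own
private test images; a large divergence between local and global views
flags a possibly biased client.

The visual comparison is quantified here with two companion statistics:
the IoU between local and global most-activated boxes per test image, and
the squared L2 distance between index-aligned local and global prototype
vectors.  Both are artifact-level plumbing around what is otherwise a
visual-inspection protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import ValidationError
from .model_core import LabeledImage, ModelParams

CORNERS = ('tl', 'tr', 'bl', 'br')


@dataclass(frozen=True)
class MarkerSpec:
    shape: str = 'square'            # square | disc | glyph
    size: int = 8
    position: object = 'tl'          # corner keyword or (row, col) anchor
    intensity: float = 1.0
    target_class: int = 1

    def __post_init__(self):
        if self.shape not in ('square', 'disc', 'glyph'):
            raise ValidationError(f"unknown marker shape {self.shape!r}")
        if self.size < 2:
            raise ValidationError("marker size must be >= 2")
        if not (0.0 <= self.intensity <= 1.0):
            raise ValidationError("intensity must be in [0, 1]")


@dataclass
class ImageComparison:
    image_id: str
    local_box: tuple
    global_box: tuple
    personalized_box: Optional[tuple]
    iou_local_global: float


@dataclass
class AuditReport:
    client_id: int
    comparisons: list
    prototype_divergence: np.ndarray   # per-prototype squared L2, local vs global
    mean_iou: float
    mean_divergence: float
    frac_disagree: Optional[float] = None  # share of images with IoU < 0.2
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            'client_id': self.client_id,
            'mean_iou': self.mean_iou,
            'mean_divergence': self.mean_divergence,
            'frac_disagree': self.frac_disagree,
            'flagged': self.flagged,
            'prototype_divergence': [float(v) for v in self.prototype_divergence],
            'comparisons': [
                {'image_id': c.image_id, 'local_box': list(c.local_box),
                 'global_box': list(c.global_box),
                 'personalized_box': (list(c.personalized_box)
                                      if c.personalized_box else None),
                 'iou_local_global': c.iou_local_global}
                for c in self.comparisons],
        }


# ---------------------------------------------------------------------------
# bias injection
# ---------------------------------------------------------------------------

def _marker_anchor(spec: MarkerSpec, h: int, w: int):
    if isinstance(spec.position, str):
        if spec.position not in CORNERS:
            raise ValidationError(f"unknown corner keyword {spec.position!r}")
        r = 0 if spec.position[0] == 't' else h - spec.size
        c = 0 if spec.position[1] == 'l' else w - spec.size
        return r, c
    return tuple(int(v) for v in spec.position)


def _marker_mask(spec: MarkerSpec, h: int, w: int) -> np.ndarray:
    r0, c0 = _marker_anchor(spec, h, w)
    s = spec.size
    if r0 < 0 or c0 < 0 or r0 + s > h or c0 + s > w:
        raise ValidationError("marker out of image bounds")
    mask = np.zeros((h, w), dtype=bool)
    if spec.shape == 'square':
        mask[r0:r0 + s, c0:c0 + s] = True
    elif spec.shape == 'disc':
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = r0 + (s - 1) / 2, c0 + (s - 1) / 2
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= (s / 2) ** 2] = True
    else:  # glyph: hollow square with center dot, emoji stand-in
        mask[r0:r0 + s, c0:c0 + s] = True
        inner = max(1, s // 4)
        mask[r0 + inner:r0 + s - inner, c0 + inner:c0 + s - inner] = False
        mid = s // 2
        mask[r0 + mid - 1:r0 + mid + 1, c0 + mid - 1:c0 + mid + 1] = True
    return mask


def inject_marker(shard, spec: MarkerSpec):
    """Stamp the marker onto every target-class image; others untouched.

    Marker pixels are overwritten with spec.intensity (all channels), so the
    operation is idempotent.  Returns a new shard; input images of the
    non-target class are passed through unchanged (same objects).
    """
    out = []
    for im in shard:
        if im.label != spec.target_class:
            out.append(im)
            continue
        h, w, _ = im.pixels.shape
        mask = _marker_mask(spec, h, w)
        px = im.pixels.copy()
        px[mask] = spec.intensity
        out.append(LabeledImage(px, im.label, im.image_id, biased=True))
    return out


@dataclass(frozen=True)
class DrainSpec:
    width: int = 2               # tube thickness, pixels
    contrast: float = 0.6
    amplitude: float = 0.08      # curvature, fraction of image height
    target_class: int = 1
    seed: int = 0


def emulate_drain_bias(shard, spec: DrainSpec):
    """Overlay a curved tube-like line in the upper half of positive images.

    Position is randomized per image (seeded); negatives are untouched.
    """
    out = []
    for i, im in enumerate(shard):
        if im.label != spec.target_class:
            out.append(im)
            continue
        h, w, _ = im.pixels.shape
        rng = np.random.default_rng([spec.seed, i])
        half = h // 2
        base = rng.uniform(0.15, 0.7) * (half - spec.width - spec.amplitude * h)
        phase = rng.uniform(0, 2 * np.pi)
        cols = np.arange(w)
        rows = base + spec.amplitude * h * (1 + np.sin(2 * np.pi * cols / w + phase)) / 2
        px = im.pixels.copy()
        for c in cols:
            r = int(rows[c])
            r1 = min(r + spec.width, half)
            px[r:r1, c, :] = np.clip(px[r:r1, c, :] + spec.contrast, 0.0, 1.0)
        out.append(LabeledImage(px, im.label, im.image_id, biased=True))
    return out


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------

def box_iou(a: tuple, b: tuple) -> float:
    """IoU of two half-open (r0, c0, r1, c1) rectangles."""
    ar0, ac0, ar1, ac1 = a
    br0, bc0, br1, bc1 = b
    ih = max(0, min(ar1, br1) - max(ar0, br0))
    iw = max(0, min(ac1, bc1) - max(ac0, bc0))
    inter = ih * iw
    union = (ar1 - ar0) * (ac1 - ac0) + (br1 - br0) * (bc1 - bc0) - inter
    return inter / union if union > 0 else 0.0


def most_activated_box(im, model: ModelParams, which, percentile: float):
    """Box of the patch most activated by a prototype *set* on one image.

    Max-pools the similarity maps of the prototypes in `which`, upsamples the
    pooled map to image size and takes the percentile bounding box.
    """
    from .model_core import embed, prototype_distances, similarity_from_distance
    from .projection_viz import prototype_bbox, upsample_activation
    z = embed(im, model)
    sim = similarity_from_distance(prototype_distances(z, model.prototypes),
                                   model.eps)
    pooled = sim[list(which)].max(axis=0)
    return prototype_bbox(upsample_activation(pooled, im.pixels.shape[:2]),
                          percentile, image_id=getattr(im, 'image_id', '')).box


def compare_prototypes(local_model: ModelParams, global_model: ModelParams,
                       personalized_model: Optional[ModelParams],
                       test_shard, client_id: int = 0,
                       percentile: float = 95.0,
                       prototype_class: Optional[int] = None) -> AuditReport:
    """Compare local vs global prototype views on a private test set.

    Per test image, each model contributes the bounding box of the patch most
    activated by its prototype set (max-pooled over the prototypes selected
    by `prototype_class`; None = all).  The per-image statistic is the IoU
    between the local and global boxes; the report also carries the
    per-prototype squared L2 distance between the two models' (index-aligned)
    prototype vectors.
    """
    for other in (global_model, personalized_model):
        if other is None:
            continue
        if (other.prototypes.vectors.shape != local_model.prototypes.vectors.shape
                or other.image_shape != local_model.image_shape):
            raise ValidationError("models have mismatched architectures")
    if len(test_shard) == 0:
        raise ValidationError("empty test shard")
    which = [j for j in range(local_model.prototypes.m)
             if prototype_class is None
             or local_model.prototypes.class_of[j] == prototype_class]
    if not which:
        raise ValidationError(f"no prototypes of class {prototype_class}")
    comparisons = []
    for im in test_shard:
        lbox = most_activated_box(im, local_model, which, percentile)
        gbox = most_activated_box(im, global_model, which, percentile)
        pbox = None
        if personalized_model is not None:
            pbox = most_activated_box(im, personalized_model, which, percentile)
        comparisons.append(ImageComparison(
            image_id=im.image_id, local_box=lbox, global_box=gbox,
            personalized_box=pbox, iou_local_global=box_iou(lbox, gbox)))
    divergence = ((local_model.prototypes.vectors
                   - global_model.prototypes.vectors) ** 2).sum(axis=1)
    ious = np.array([c.iou_local_global for c in comparisons])
    return AuditReport(
        client_id=client_id,
        comparisons=comparisons,
        prototype_divergence=divergence,
        mean_iou=float(ious.mean()),
        mean_divergence=float(divergence.mean()),
        frac_disagree=float((ious < DISAGREE_IOU).mean()),
    )


DISAGREE_IOU = 0.2  # an image "disagrees" when local/global boxes barely meet


def default_flag_rule(values: np.ndarray, k: float = 2.0, low: bool = True,
                      floor: float = 0.1) -> np.ndarray:
    """Leave-one-out outlier rule.

    A client is flagged when its statistic deviates from the mean of the
    *other* clients by more than k times their SD (with a minimum spread
    `floor` so near-identical reports are never flagged).  `low=True` flags
    unusually small values (IoU); `low=False` flags unusually large ones
    (prototype divergence).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        others = np.delete(values, i)
        mu = others.mean()
        sd = others.std(ddof=0)
        margin = k * max(sd, floor)
        flags[i] = values[i] < mu - margin if low else values[i] > mu + margin
    return flags


def flag_bias(reports, rule: Optional[Callable] = None) -> list:
    """Flag clients whose audit diverges from the rest of the federation.

    The default rule flags a client when it is a leave-one-out outlier
    (2 x SD with a minimum spread floor) on either of two statistics: mean
    local-vs-global IoU (low side) or the fraction of test images whose
    local/global boxes clearly disagree (IoU < 0.2; high side).  A custom
    `rule` receives the list of AuditReport and returns a boolean array.
    """
    reports = list(reports)
    if len(reports) < 2:
        raise ValidationError("flagging requires at least 2 clients")
    if rule is not None:
        flags = np.asarray(rule(reports), dtype=bool)
    else:
        ious = np.array([r.mean_iou for r in reports])
        flags = default_flag_rule(ious, low=True)
        if all(r.frac_disagree is not None for r in reports):
            fracs = np.array([r.frac_disagree for r in reports])
            flags = flags | default_flag_rule(fracs, low=False)
    for r, f in zip(reports, flags):
        r.flagged = bool(f)
    return [r.client_id for r, f in zip(reports, flags) if f]
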