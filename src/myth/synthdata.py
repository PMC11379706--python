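"""Seeded synthetic image generator.

Produces binary-labeled grayscale/RGB images with a tunable
class-discriminative feature, plus the partitioning/balancing helpers used
to build per-client shards: IID partitioning, undersampling balance and
stratified train/test splits.  All randomness is driven by explicit seeds so
every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model_core import LabeledImage

FEATURES = ('central_ellipse_size', 'basal_opacity')


@dataclass(frozen=True)
class WorldSpec:
    height: int = 64
    width: int = 64
    channels: int = 1
    disease_feature: str = 'central_ellipse_size'
    feature_contrast: float = 0.4
    noise_sd: float = 0.1
    n_per_class: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.feature_contrast < 0:
            raise ValidationError("feature_contrast must be >= 0")
        if self.n_per_class < 2:
            raise ValidationError("n_per_class must be >= 2")
        if self.disease_feature not in FEATURES:
            raise ValidationError(f"unknown disease_feature {self.disease_feature!r}")
        if self.channels not in (1, 3):
            raise ValidationError("channels must be 1 or 3")


def _ellipse_mask(h, w, cy, cx, ry, rx):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _render(spec: WorldSpec, label: int, rng) -> np.ndarray:
    h, w = spec.height, spec.width
    img = np.full((h, w), 0.15)
    # torso-like bright column common to both classes
    img[:, int(0.2 * w):int(0.8 * w)] += 0.1
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    ry = (0.16 + rng.uniform(-0.02, 0.02)) * h
    rx = (0.20 + rng.uniform(-0.02, 0.02)) * w
    img[_ellipse_mask(h, w, cy, cx, ry, rx)] += 0.25  # the "heart"
    if label == 1 and spec.feature_contrast > 0:
        if spec.disease_feature == 'central_ellipse_size':
            # enlargement rendered as a bright rim around the base ellipse
            rim = _ellipse_mask(h, w, cy, cx, 1.45 * ry, 1.45 * rx) & ~_ellipse_mask(
                h, w, cy, cx, ry, rx)
            img[rim] += spec.feature_contrast
        else:  # basal_opacity: brightened lower third
            img[int(2 * h / 3):, :] += spec.feature_contrast
    img = img + rng.normal(0.0, spec.noise_sd, (h, w))
    img = np.clip(img, 0.0, 1.0)
    if spec.channels == 3:
        img = np.repeat(img[..., None], 3, axis=2)
    else:
        img = img[..., None]
    return img


def generate_dataset(spec: WorldSpec) -> list:
    """Generate exactly spec.n_per_class images of each class, seeded.

    Positives carry the disease feature at spec.feature_contrast above
    background; with feature_contrast=0 the label is independent of pixels.
    """
    rng = np.random.default_rng(spec.seed)
    images = []
    for i in range(2 * spec.n_per_class):
        label = i % 2
        images.append(LabeledImage(
            pixels=_render(spec, label, rng),
            label=label,
            image_id=f"img_{spec.seed}_{i:06d}",
        ))
    return images


def balance_by_undersampling(dataset, seed: int) -> list:
    """Randomly drop majority-class images until class counts are equal."""
    labels = np.array([im.label for im in dataset])
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to balance")
    if n_pos == n_neg:
        return list(dataset)
    minority = 1 if n_pos < n_neg else 0
    keep_n = min(n_pos, n_neg)
    rng = np.random.default_rng(seed)
    major_idx = np.flatnonzero(labels != minority)
    kept = set(rng.choice(major_idx, size=keep_n, replace=False).tolist())
    return [im for i, im in enumerate(dataset)
            if im.label == minority or i in kept]


def partition_iid(dataset, n_clients: int, seed: int) -> list:
    """Stratified IID split into n_clients shards of near-equal size."""
    if n_clients < 1:
        raise ValidationError("n_clients must be >= 1")
    if n_clients > len(dataset):
        raise ValidationError("more clients than images")
    rng = np.random.default_rng(seed)
    shards = [[] for _ in range(n_clients)]
    order = []
    # shuffle within each class, then interleave classes for stratification
    for cls in sorted({im.label for im in dataset}):
        idx = [i for i, im in enumerate(dataset) if im.label == cls]
        rng.shuffle(idx)
        order.extend(idx)
    for pos, i in enumerate(order):
        shards[pos % n_clients].append(dataset[i])
    return shards


def train_test_split(shard, test_fraction: float, seed: int):
    """Stratified, seeded, disjoint train/test split of one shard."""
    if not (0.0 < test_fraction < 1.0):
        raise ValidationError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = sorted({im.label for im in shard})
    per_class = {c: [i for i, im in enumerate(shard) if im.label == c]
                 for c in classes}
    # largest-remainder allocation so the total test count is exact
    exact = {c: test_fraction * len(per_class[c]) for c in classes}
    n_test = {c: int(np.floor(exact[c])) for c in classes}
    want_total = int(round(test_fraction * len(shard)))
    leftovers = sorted(classes, key=lambda c: exact[c] - n_test[c], reverse=True)
    for c in leftovers:
        if sum(n_test.values()) >= want_total:
            break
        n_test[c] += 1
    train, test = [], []
    for c in classes:
        idx = per_class[c]
        rng.shuffle(idx)
        test.extend(idx[:n_test[c]])
        train.extend(idx[n_test[c]:])
    return ([shard[i] for i in sorted(train)], [shard[i] for i in sorted(test)])
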