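"""Evaluation metrics: sensitivity/specificity, balanced accuracy and
multi-seed mean +/- SD summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class EvalResult:
    sensitivity: float           # percent
    specificity: float           # percent
    balanced_accuracy: float     # percent
    n_pos: int
    n_neg: int
    seed: int = 0


def confusion_rates(predictions, labels):
    """Return (sensitivity, specificity) in percent for binary labels."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValidationError("predictions and labels must have equal length")
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValidationError("both classes must be present in labels")
    tp = int((predictions[pos] == 1).sum())
    tn = int((predictions[neg] == 0).sum())
    sensitivity = 100.0 * tp / pos.sum()
    specificity = 100.0 * tn / neg.sum()
    return sensitivity, specificity


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """(sensitivity + specificity) / 2, both in percent."""
    for v in (sensitivity, specificity):
        if not (0.0 <= v <= 100.0):
            raise ValidationError("rates must be in [0, 100]")
    return (sensitivity + specificity) / 2.0


def evaluate(predictions, labels, seed: int = 0) -> EvalResult:
    sens, spec = confusion_rates(predictions, labels)
    labels = np.asarray(labels, dtype=int)
    return EvalResult(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=balanced_accuracy(sens, spec),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
        seed=seed,
    )


def multi_seed_summary(records, ddof: int = 1) -> pd.DataFrame:
    """Aggregate per-(model, client, seed) balanced accuracies.

    `records` is an iterable of dicts with keys model, client, seed and
    balanced_accuracy.  For each model the per-seed values are first averaged
    over clients, then summarized as mean +/- SD across seeds (sample SD by
    default, ddof=1).  With a single seed the SD is reported as NaN rather
    than a silent zero.
    """
    df = pd.DataFrame(list(records))
    required = {'model', 'client', 'seed', 'balanced_accuracy'}
    if not required.issubset(df.columns):
        raise ValidationError(f"records need columns {sorted(required)}")
    per_seed = (df.groupby(['model', 'seed'])['balanced_accuracy']
                  .mean().reset_index())
    rows = []
    for model, grp in per_seed.groupby('model'):
        vals = grp['balanced_accuracy'].to_numpy()
        sd = float(np.std(vals, ddof=ddof)) if len(vals) > ddof else float('nan')
        rows.append({'model': model, 'mean': float(vals.mean()), 'sd': sd,
                     'n_seeds': len(vals)})
    return pd.DataFrame(rows).set_index('model')
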