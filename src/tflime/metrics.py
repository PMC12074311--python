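"""Segmentation and saliency evaluation.

Segmentation quality compares a predicted cell set against a ground-truth
cell set: Jaccard overlap (IoU), false-positive rate (fraction of predicted
cells outside the truth) and energy retention ratio (fraction of the truth's
energy captured).  Saliency quality sweeps a binarisation threshold tau over
a normalised attribution mask and integrates precision and recall over the
sweep (AUP, AUR) plus the area under the precision-recall pairing (AUPRC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["iou", "fpr", "err", "MetricCurves", "normalize_mask", "saliency_curves"]


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


def iou(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard overlap |P & G| / |P | G|; two empty sets agree perfectly (1)."""
    p, g = _as_bool(predicted), _as_bool(truth)
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, g).sum() / union)


def fpr(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of predicted cells not marked in the truth: |P \\ G| / |P|."""
    p, g = _as_bool(predicted), _as_bool(truth)
    n_pred = p.sum()
    if n_pred == 0:
        raise ValueError("false-positive rate is undefined for an empty prediction")
    return float(np.logical_and(p, ~g).sum() / n_pred)


def err(predicted: np.ndarray, truth: np.ndarray, energy: np.ndarray) -> float:
    """Energy retention ratio: energy in P & G over energy in G."""
    p, g = _as_bool(predicted), _as_bool(truth)
    energy = np.asarray(energy, dtype=float)
    total = energy[g].sum()
    if total <= 0:
        raise ValueError("ground truth carries no energy")
    return float(energy[np.logical_and(p, g)].sum() / total)


@dataclass(frozen=True)
class MetricCurves:
    """Threshold-swept precision/recall and their areas."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    aup: float
    aur: float
    auprc: float


def normalize_mask(values: np.ndarray) -> np.ndarray:
    """Map raw attributions to [0, 1]: clip negatives to 0, divide by the max."""
    values = np.clip(np.asarray(values, dtype=float), 0.0, None)
    peak = values.max()
    return values / peak if peak > 0 else values


def saliency_curves(
    mask: np.ndarray, truth: np.ndarray, grid_size: int = 99
) -> MetricCurves:
    """Precision/recall over an even threshold grid in (0, 1).

    At each tau cells with mask >= tau are selected; precision of an empty
    selection is 1 by convention.  AUP and AUR approximate the integrals of
    P(tau) and R(tau) over (0, 1) by the trapezoid rule on the grid,
    normalised by the grid span so a constant curve integrates to its value.
    AUPRC is the trapezoidal area under the (recall, precision) pairing,
    anchored at recall 0 with the precision of the strictest threshold.
    """
    mask = np.asarray(mask, dtype=float)
    truth = _as_bool(truth)
    if mask.shape != truth.shape:
        raise ValueError("mask and ground truth shapes differ")
    n_true = truth.sum()
    if n_true == 0:
        raise ValueError("ground truth is empty")

    thresholds = np.linspace(0, 1, grid_size + 2)[1:-1]
    selected = mask[None, :, :] >= thresholds[:, None, None]
    n_selected = selected.sum(axis=(1, 2))
    n_hit = (selected & truth[None, :, :]).sum(axis=(1, 2))
    precision = np.where(n_selected > 0, n_hit / np.maximum(n_selected, 1), 1.0)
    recall = n_hit / n_true

    span = thresholds[-1] - thresholds[0]
    aup = float(np.trapezoid(precision, thresholds) / span)
    aur = float(np.trapezoid(recall, thresholds) / span)
    pr_recall = np.concatenate([recall, [0.0]])
    pr_precision = np.concatenate([precision, [precision[-1]]])
    order = np.argsort(pr_recall, kind="stable")
    auprc = float(np.trapezoid(pr_precision[order], pr_recall[order]))
    return MetricCurves(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        aup=aup,
        aur=aur,
        auprc=auprc,
    )
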