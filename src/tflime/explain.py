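"""The time-frequency LIME engine.

An explanation of a single prediction proceeds through five stages: the
series is transformed to a complex spectrogram and segmented into homogeneous
blocks (the interpretable units); random binary perturbations switch subsets
of blocks off; each perturbed spectrogram is inverted back to a time series
and scored by the black box; dynamic-time-warping distances to the original
series, passed through an exponential kernel, weight the perturbations by
locality; and a weighted ridge regression of the target-class probability on
the binary block indicators yields one importance weight per block.  The
weights expand to an L x K heatmap over the spectrogram.

An element-wise mode replaces the segmentation by single-cell tiles, giving
the classic fixed-window LIME comparator within the same machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.linear_model import Ridge

from .config import DEFAULT_STFT, LimeParams, TfhsParams
from .dtw import dtw_distance
from .metrics import normalize_mask
from .models import BlackBoxModel
from .segmentation import Segmentation, fill_equidistant, segment
from .transform import StftParams, TFMatrix, TimeSeries, istft, magnitude, stft

__all__ = [
    "Explanation",
    "sample_perturbations",
    "apply_mask",
    "kernel_weights",
    "fit_surrogate",
    "heatmap",
    "explain",
]


@dataclass
class Explanation:
    """Per-block importances for one prediction of one series."""

    block_weights: np.ndarray
    intercept: float
    target_class: int
    local_fit_quality: float
    segmentation: Segmentation

    def heatmap(self) -> np.ndarray:
        return heatmap(self, self.segmentation)

    def saliency(self) -> np.ndarray:
        """Heatmap normalised to [0, 1] (negatives clipped) for evaluation."""
        return normalize_mask(self.heatmap())

    def top_blocks(self, n: int = 5) -> list[int]:
        """Indices of the ``n`` blocks with largest positive weight."""
        order = np.argsort(self.block_weights)[::-1]
        return [int(i) for i in order[:n]]

    def to_json(self) -> str:
        blocks = [
            {
                "frame_lo": b.frame_lo,
                "frame_hi": b.frame_hi,
                "bin_lo": b.bin_lo,
                "bin_hi": b.bin_hi,
                "origin": b.origin,
                "weight": float(w),
            }
            for b, w in zip(self.segmentation.blocks, self.block_weights)
        ]
        return json.dumps(
            {
                "target_class": self.target_class,
                "intercept": self.intercept,
                "local_fit_quality": self.local_fit_quality,
                "matrix_shape": list(self.segmentation.matrix_shape),
                "blocks": blocks,
            },
            indent=1,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def sample_perturbations(
    n_blocks: int, params: LimeParams, rng: np.random.Generator
) -> np.ndarray:
    """Binary perturbation matrix of shape (u, n_blocks).

    Row 0 is the all-ones vector (the unperturbed instance anchors the
    surrogate).  Every other row draws a retained-count uniformly from
    {1, ..., n_blocks} and keeps that many distinct blocks, so the number of
    retained units is uniform across samples rather than binomial.
    """
    if n_blocks < 1:
        raise ValueError("need at least one block to perturb")
    samples = np.zeros((params.n_samples, n_blocks), dtype=np.int8)
    samples[0] = 1
    for i in range(1, params.n_samples):
        c = int(rng.integers(1, n_blocks + 1))
        keep = rng.choice(n_blocks, size=c, replace=False)
        samples[i, keep] = 1
    return samples


def apply_mask(tf: TFMatrix, seg: Segmentation, bits: np.ndarray) -> TFMatrix:
    """Zero the complex coefficients of every switched-off block.

    On a one-sided spectrum each stored bin stands for its conjugate pair, so
    zeroing it removes the full real component; a two-sided spectrum has the
    mirrored bins zeroed explicitly to keep reconstructions real.
    """
    bits = np.asarray(bits)
    if bits.size != len(seg.blocks):
        raise ValueError(
            f"perturbation vector has {bits.size} bits for {len(seg.blocks)} blocks"
        )
    coeffs = tf.coeffs.copy()
    n_bins_full = tf.params.n_window
    for block, bit in zip(seg.blocks, bits):
        if bit:
            continue
        coeffs[
            block.frame_lo : block.frame_hi + 1, block.bin_lo : block.bin_hi + 1
        ] = 0
        if not tf.params.one_sided:
            for k in range(block.bin_lo, block.bin_hi + 1):
                coeffs[block.frame_lo : block.frame_hi + 1, (-k) % n_bins_full] = 0
    return TFMatrix(coeffs, tf.params, tf.sampling_rate)


def kernel_weights(distances: np.ndarray, kernel_width: float) -> np.ndarray:
    """Locality weights from raw distances.

    Distances are standardised to zero mean and unit variance across the
    batch (making the weights invariant to affine rescaling of the raw
    distances), the below-mean half is clamped to 0 so weights never increase
    with distance, and the result passes through the exponential kernel
    ``exp(-d^2 / rho^2)``.  Zero-variance batches get uniform weight 1.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 1 or distances.size < 2:
        raise ValueError("need at least two distances to standardise")
    std = distances.std()
    if std == 0:
        return np.ones_like(distances)
    z = (distances - distances.mean()) / std
    z = np.maximum(z, 0.0)
    return np.exp(-(z**2) / kernel_width**2)


def fit_surrogate(
    bits: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    params: LimeParams,
) -> tuple[np.ndarray, float, float]:
    """Weighted ridge regression of target probabilities on block indicators.

    Returns (block weight vector, intercept, weighted R^2 on the fit data).
    """
    bits = np.asarray(bits, dtype=float)
    if np.all(bits == bits[0]):
        raise np.linalg.LinAlgError(
            "degenerate perturbation design: all samples identical"
        )
    model = Ridge(alpha=params.ridge_penalty, fit_intercept=True)
    model.fit(bits, targets, sample_weight=weights)
    fitted = model.predict(bits)
    resid = np.average((targets - fitted) ** 2, weights=weights)
    total = np.average((targets - np.average(targets, weights=weights)) ** 2,
                       weights=weights)
    r2 = 1.0 - resid / total if total > 0 else 1.0
    return model.coef_.copy(), float(model.intercept_), float(r2)


def heatmap(explanation: Explanation, seg: Segmentation) -> np.ndarray:
    """Expand block weights to the matrix: every cell carries its block's w."""
    out = np.zeros(seg.matrix_shape)
    for block, w in zip(seg.blocks, explanation.block_weights):
        out[
            block.frame_lo : block.frame_hi + 1, block.bin_lo : block.bin_hi + 1
        ] = w
    return out


def _elementwise_segmentation(
    mag: np.ndarray, tile: int = 1
) -> Segmentation:
    """Fixed-window tiling with no peak-based blocks (classic LIME units)."""
    blocks = fill_equidistant(mag.shape, [], tile)
    return Segmentation(
        blocks=blocks,
        matrix_shape=mag.shape,
        global_mean=float(mag.mean()),
        global_std=float(mag.std()),
    )


def explain(
    series: TimeSeries,
    model: BlackBoxModel,
    stft_params: StftParams | None = None,
    tfhs_params: TfhsParams | None = None,
    lime_params: LimeParams | None = None,
    mode: str = "tfhs",
) -> Explanation:
    """Explain one prediction of ``model`` on ``series``.

    ``mode="tfhs"`` uses homogeneous segmentation blocks as interpretable
    units; ``mode="elementwise"`` uses single-cell tiles (the fixed-window
    LIME comparator).  Reproducible given ``lime_params.seed``.
    """
    stft_params = stft_params or DEFAULT_STFT
    tfhs_params = tfhs_params or TfhsParams()
    lime_params = lime_params or LimeParams()
    rng = np.random.default_rng(lime_params.seed)

    tf = stft(series, stft_params)
    mag = magnitude(tf)
    if mode == "tfhs":
        seg = segment(mag, tfhs_params)
    elif mode == "elementwise":
        seg = _elementwise_segmentation(mag)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    target_class = (
        lime_params.target_class
        if lime_params.target_class is not None
        else model.predicted_class(series.values)
    )

    bits = sample_perturbations(len(seg.blocks), lime_params, rng)
    reconstructed = _batch_reconstruct(tf, seg, bits, series)
    probs = model.predict(reconstructed)
    targets = probs[:, target_class]
    distances = np.array(
        [dtw_distance(series.values, z) for z in reconstructed]
    )
    weights = kernel_weights(distances, lime_params.kernel_width)
    coef, intercept, r2 = fit_surrogate(bits, targets, weights, lime_params)
    return Explanation(
        block_weights=coef,
        intercept=intercept,
        target_class=target_class,
        local_fit_quality=r2,
        segmentation=seg,
    )


def _batch_reconstruct(
    tf: TFMatrix, seg: Segmentation, bits: np.ndarray, original: TimeSeries
) -> np.ndarray:
    """Mask + inverse-transform all perturbations at once.

    Equivalent to looping ``apply_mask`` then ``istft`` per row, but the
    block zeroing and the overlap-add run batched across perturbations.
    """
    params = tf.params
    n = params.n_window
    hop = params.hop
    n_frames = tf.coeffs.shape[0]
    length = len(original)
    u = bits.shape[0]

    coeffs = np.broadcast_to(tf.coeffs, (u,) + tf.coeffs.shape).copy()
    for j, block in enumerate(seg.blocks):
        off = bits[:, j] == 0
        if off.any():
            coeffs[
                off,
                block.frame_lo : block.frame_hi + 1,
                block.bin_lo : block.bin_hi + 1,
            ] = 0

    window = params.window()
    if params.one_sided:
        frames = np.fft.irfft(coeffs, n=n, axis=2)
    else:
        frames = np.fft.ifft(coeffs, axis=2).real
    frames *= window

    acc = np.zeros((u, length))
    wsum = np.zeros(length)
    for l in range(n_frames):
        start = l * hop
        acc[:, start : start + n] += frames[:, l]
        wsum[start : start + n] += window**2
    covered = wsum > 1e-12
    divisor = np.maximum(wsum, 0.5 * wsum.max())  # same clamping as istft
    out = np.empty((u, length))
    out[:, covered] = acc[:, covered] / divisor[covered]
    out[:, ~covered] = original.values[~covered]
    return out
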