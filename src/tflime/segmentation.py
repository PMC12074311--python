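"""Time-frequency homogeneous segmentation (TFHS).

Partitions an STFT magnitude matrix into rectangular blocks of coherent
energy.  The pipeline: per-frame spectral peak detection with global noise
suppression; DBSCAN clustering of peaks on normalised (bin, magnitude)
features; splitting clusters at temporal gaps; bidirectional frequency
boundary expansion under energy-decay and global-energy constraints; overlap
resolution favouring the higher-energy block; pruning of low-energy blocks;
and equidistant tiling of whatever remains uncovered, so the blocks always
form an exact partition of the matrix.  The blocks are the perturbation units
of the explanation engine and double as a segmentation of the spectrogram in
their own right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import DBSCAN

from .config import TfhsParams

__all__ = [
    "Peak",
    "TFBlock",
    "Segmentation",
    "detect_peaks",
    "cluster_peaks",
    "split_temporal",
    "expand_boundaries",
    "resolve_overlaps",
    "prune_low_energy",
    "fill_equidistant",
    "segment",
]


@dataclass(frozen=True)
class Peak:
    """A spectral peak: frame/bin location plus normalised cluster features."""

    frame: int
    bin: int
    magnitude: float
    norm_bin: float
    norm_mag: float


@dataclass(frozen=True)
class TFBlock:
    """Inclusive rectangle ``[frame_lo, frame_hi] x [bin_lo, bin_hi]``."""

    frame_lo: int
    frame_hi: int
    bin_lo: int
    bin_hi: int
    origin: str = "peak"  # "peak" or "fill"

    def __post_init__(self) -> None:
        if self.frame_lo > self.frame_hi or self.bin_lo > self.bin_hi:
            raise ValueError("block bounds must be non-empty")

    @property
    def n_cells(self) -> int:
        return (self.frame_hi - self.frame_lo + 1) * (self.bin_hi - self.bin_lo + 1)

    def cell_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.frame_lo : self.frame_hi + 1, self.bin_lo : self.bin_hi + 1] = True
        return mask

    def mean_magnitude(self, mag: np.ndarray) -> float:
        return float(
            mag[self.frame_lo : self.frame_hi + 1, self.bin_lo : self.bin_hi + 1].mean()
        )


@dataclass
class Segmentation:
    """An ordered, disjoint, covering set of blocks over an ``L x K`` matrix."""

    blocks: list[TFBlock]
    matrix_shape: tuple[int, int]
    global_mean: float
    global_std: float

    def __len__(self) -> int:
        return len(self.blocks)

    def labels(self) -> np.ndarray:
        """Matrix of block indices (-1 where uncovered; never after fill)."""
        lab = np.full(self.matrix_shape, -1, dtype=int)
        for i, b in enumerate(self.blocks):
            lab[b.frame_lo : b.frame_hi + 1, b.bin_lo : b.bin_hi + 1] = i
        return lab

    def peak_region(self) -> np.ndarray:
        """Boolean mask of all cells covered by peak-based blocks."""
        mask = np.zeros(self.matrix_shape, dtype=bool)
        for b in self.blocks:
            if b.origin == "peak":
                mask |= b.cell_mask(self.matrix_shape)
        return mask

    def to_json(self, mag: np.ndarray | None = None) -> str:
        blocks = []
        for b in self.blocks:
            entry = {
                "frame_lo": b.frame_lo,
                "frame_hi": b.frame_hi,
                "bin_lo": b.bin_lo,
                "bin_hi": b.bin_hi,
                "origin": b.origin,
            }
            if mag is not None:
                entry["mean_magnitude"] = b.mean_magnitude(mag)
            blocks.append(entry)
        return json.dumps(
            {
                "matrix_shape": list(self.matrix_shape),
                "global_mean": self.global_mean,
                "global_std": self.global_std,
                "blocks": blocks,
            },
            indent=1,
        )

    def save(self, path: str | Path, mag: np.ndarray | None = None) -> None:
        Path(path).write_text(self.to_json(mag))


def detect_peaks(mag: np.ndarray, params: TfhsParams) -> list[Peak]:
    """Per-frame spectral peaks passing energy and noise-suppression gates.

    A bin qualifies when it reaches ``eta`` times its frame's maximum, exceeds
    the global ``mean + beta * std`` floor, and is a local maximum along
    frequency (boundary bins compare against their single neighbour).  Runs of
    equal values are represented by their leftmost bin only, and a run must be
    strictly above every adjacent bin it has — a constant frame yields no
    peaks.
    """
    mag = np.asarray(mag, dtype=float)
    if mag.ndim != 2 or mag.size == 0:
        raise ValueError("magnitude matrix must be non-empty and 2-D")
    n_frames, n_bins = mag.shape
    mu, sigma = float(mag.mean()), float(mag.std())
    noise_floor = mu + params.noise_suppression * sigma
    max_mag = float(mag.max())

    peaks: list[Peak] = []
    for l in range(n_frames):
        row = mag[l]
        threshold = max(params.energy_threshold_factor * row.max(), noise_floor)
        k = 0
        while k < n_bins:
            # maximal run of equal values starting at k
            k_end = k
            while k_end + 1 < n_bins and row[k_end + 1] == row[k]:
                k_end += 1
            value = row[k]
            is_peak = (
                value >= threshold
                and (k_end - k + 1) < n_bins
                and (k == 0 or row[k - 1] < value)
                and (k_end == n_bins - 1 or row[k_end + 1] < value)
            )
            if is_peak and value > 0:
                peaks.append(
                    Peak(
                        frame=l,
                        bin=k,
                        magnitude=float(value),
                        norm_bin=k / (n_bins - 1) if n_bins > 1 else 0.0,
                        norm_mag=float(value) / max_mag if max_mag > 0 else 0.0,
                    )
                )
            k = k_end + 1
    return peaks


def cluster_peaks(peaks: list[Peak], params: TfhsParams) -> list[list[Peak]]:
    """DBSCAN over (bin, magnitude) pairs; noise points are dropped.

    The neighbourhood test is
    ``(kp - kq)^2 + alpha * (Ap - Aq)^2 <= eps^2``, realised as Euclidean
    DBSCAN after scaling the magnitude axis by ``sqrt(alpha)``.  Frequency
    enters in bin units and magnitude normalised by the matrix maximum, so
    the default radius of 0.5 groups the per-frame peaks of one stationary
    tone (same bin across frames, similar magnitude) while keeping tones a
    bin or more apart in separate clusters.
    """
    if not peaks:
        return []
    features = np.array(
        [[float(p.bin), np.sqrt(params.magnitude_scale) * p.norm_mag] for p in peaks]
    )
    labels = DBSCAN(
        eps=params.cluster_radius, min_samples=params.min_cluster_points
    ).fit_predict(features)
    clusters: dict[int, list[Peak]] = {}
    for peak, label in zip(peaks, labels):
        if label >= 0:
            clusters.setdefault(int(label), []).append(peak)
    return [clusters[label] for label in sorted(clusters)]


def split_temporal(cluster: list[Peak], max_time_gap: int) -> list[list[Peak]]:
    """Split a cluster wherever consecutive peak frames are > gamma apart."""
    if not cluster:
        return []
    ordered = sorted(cluster, key=lambda p: (p.frame, p.bin))
    subsets: list[list[Peak]] = [[ordered[0]]]
    for peak in ordered[1:]:
        if peak.frame - subsets[-1][-1].frame > max_time_gap:
            subsets.append([peak])
        else:
            subsets[-1].append(peak)
    return subsets


def _weighted_median_bin(subset: list[Peak]) -> int:
    """Magnitude-weighted median bin: the seed of the boundary search."""
    ordered = sorted(subset, key=lambda p: p.bin)
    weights = np.array([p.magnitude for p in ordered])
    total = weights.sum()
    if total <= 0:
        return ordered[len(ordered) // 2].bin
    cum = np.cumsum(weights)
    idx = int(np.searchsorted(cum, total / 2))
    return ordered[min(idx, len(ordered) - 1)].bin


def expand_boundaries(
    mag: np.ndarray, subset: list[Peak], params: TfhsParams
) -> TFBlock:
    """Grow the frequency extent of a temporally contiguous peak subset.

    The time span is the subset's frame range ``[ll, lr]``.  Starting from the
    magnitude-weighted median bin, the search walks outward in each direction
    over the band profile (time-averaged magnitude over ``[ll, lr]``).  A
    candidate bin is kept while its profile value stays above ``tau_drop``
    times the running maximum of the explored band and above ``tau_global``
    times the global mean magnitude; the walk also stops after absorbing a
    bin that is a local minimum of the profile.
    """
    if not subset:
        raise ValueError("cannot expand an empty peak subset")
    mag = np.asarray(mag, dtype=float)
    n_bins = mag.shape[1]
    frame_lo = min(p.frame for p in subset)
    frame_hi = max(p.frame for p in subset)
    profile = mag[frame_lo : frame_hi + 1].mean(axis=0)
    global_floor = params.global_energy * float(mag.mean())
    seed = _weighted_median_bin(subset)

    def is_local_min(k: int) -> bool:
        # strict: a flat plateau is not a minimum, so constant bands expand
        left = profile[k - 1] if k > 0 else np.inf
        right = profile[k + 1] if k < n_bins - 1 else np.inf
        return profile[k] < min(left, right)

    lo = hi = seed
    band_max = profile[seed]
    for k in range(seed - 1, -1, -1):
        if profile[k] < params.energy_decay * band_max or profile[k] < global_floor:
            break
        lo = k
        band_max = max(band_max, profile[k])
        if is_local_min(k):
            break
    band_max = max(profile[lo : seed + 1])
    for k in range(seed + 1, n_bins):
        if profile[k] < params.energy_decay * band_max or profile[k] < global_floor:
            break
        hi = k
        band_max = max(band_max, profile[k])
        if is_local_min(k):
            break
    return TFBlock(frame_lo, frame_hi, lo, hi, origin="peak")


def _largest_clear_rectangle(
    free: np.ndarray,
) -> tuple[int, int, int, int] | None:
    """Largest all-True axis-aligned rectangle of a boolean grid.

    Histogram sweep, O(rows * cols).  Ties resolve to the first maximal
    rectangle encountered scanning rows then columns, keeping the trimming
    deterministic.  Returns inclusive (r0, r1, c0, c1) or None if empty.
    """
    n_rows, n_cols = free.shape
    heights = np.zeros(n_cols, dtype=int)
    best: tuple[int, tuple[int, int, int, int]] | None = None
    for r in range(n_rows):
        heights = np.where(free[r], heights + 1, 0)
        stack: list[tuple[int, int]] = []  # (start column, height)
        for c in range(n_cols + 1):
            h = int(heights[c]) if c < n_cols else 0
            start = c
            while stack and stack[-1][1] >= h:
                top_start, top_height = stack.pop()
                area = top_height * (c - top_start)
                if area > 0 and (best is None or area > best[0]):
                    best = (area, (r - top_height + 1, r, top_start, c - 1))
                start = top_start
            if h > 0:
                stack.append((start, h))
    return best[1] if best else None


def resolve_overlaps(
    blocks: list[TFBlock],
    mag: np.ndarray,
    overlap_threshold: float,
) -> list[TFBlock]:
    """Make the peak-based blocks pairwise disjoint.

    Blocks are ranked by descending mean magnitude (the dominant structure
    wins every contested cell).  Each lower-ranked block is trimmed to the
    largest rectangle that avoids everything already kept; a block reduced to
    nothing — e.g. a duplicate whose Jaccard overlap reaches the threshold —
    is dropped.  The result shares no cell between any pair of blocks, so
    every pairwise Jaccard overlap is below ``overlap_threshold``.
    """
    if not blocks:
        return []
    shape = mag.shape
    ranked = sorted(
        blocks,
        key=lambda b: (
            -b.mean_magnitude(mag),
            b.frame_lo,
            b.bin_lo,
            b.frame_hi,
            b.bin_hi,
        ),
    )
    covered = np.zeros(shape, dtype=bool)
    kept: list[TFBlock] = []
    for block in ranked:
        region = covered[
            block.frame_lo : block.frame_hi + 1, block.bin_lo : block.bin_hi + 1
        ]
        if not region.any():
            trimmed = block
        else:
            rect = _largest_clear_rectangle(~region)
            if rect is None:
                continue
            r0, r1, c0, c1 = rect
            trimmed = TFBlock(
                block.frame_lo + r0,
                block.frame_lo + r1,
                block.bin_lo + c0,
                block.bin_lo + c1,
                origin=block.origin,
            )
        kept.append(trimmed)
        covered[
            trimmed.frame_lo : trimmed.frame_hi + 1,
            trimmed.bin_lo : trimmed.bin_hi + 1,
        ] = True
    return kept


def prune_low_energy(
    blocks: list[TFBlock], mag: np.ndarray, params: TfhsParams
) -> list[TFBlock]:
    """Drop peak-based blocks whose mean magnitude is an insignificant
    fraction of the global mean (noise-induced structure)."""
    floor = params.prune_factor * float(np.asarray(mag).mean())
    return [b for b in blocks if b.mean_magnitude(mag) >= floor]


def fill_equidistant(
    matrix_shape: tuple[int, int], blocks: list[TFBlock], fill_window: int
) -> list[TFBlock]:
    """Tile every uncovered cell with rectangles of at most
    ``fill_window x fill_window`` cells, scanning row-major over frames then
    bins; tiles are clipped at matrix edges and around existing blocks."""
    covered = np.zeros(matrix_shape, dtype=bool)
    for b in blocks:
        covered[b.frame_lo : b.frame_hi + 1, b.bin_lo : b.bin_hi + 1] = True
    n_frames, n_bins = matrix_shape
    tiles: list[TFBlock] = []
    for l in range(n_frames):
        k = 0
        while k < n_bins:
            if covered[l, k]:
                k += 1
                continue
            k_hi = k
            while (
                k_hi + 1 < n_bins
                and k_hi - k + 1 < fill_window
                and not covered[l, k_hi + 1]
            ):
                k_hi += 1
            l_hi = l
            while (
                l_hi + 1 < n_frames
                and l_hi - l + 1 < fill_window
                and not covered[l_hi + 1, k : k_hi + 1].any()
            ):
                l_hi += 1
            tiles.append(TFBlock(l, l_hi, k, k_hi, origin="fill"))
            covered[l : l_hi + 1, k : k_hi + 1] = True
            k = k_hi + 1
    return tiles


def segment(mag: np.ndarray, params: TfhsParams | None = None) -> Segmentation:
    """Full TFHS pipeline over a magnitude matrix.

    Deterministic in its inputs.  When no peak survives detection, clustering
    and pruning, the result is pure equidistant tiling; with
    ``fill_window = 1`` that degenerates to one block per matrix cell.
    """
    params = params or TfhsParams()
    mag = np.asarray(mag, dtype=float)
    if mag.ndim != 2 or mag.size == 0:
        raise ValueError("magnitude matrix must be non-empty and 2-D")
    if np.any(mag < 0):
        raise ValueError("magnitude matrix must be non-negative")

    peaks = detect_peaks(mag, params)
    blocks: list[TFBlock] = []
    for cluster in cluster_peaks(peaks, params):
        for subset in split_temporal(cluster, params.max_time_gap):
            blocks.append(expand_boundaries(mag, subset, params))
    blocks = resolve_overlaps(blocks, mag, params.overlap_threshold)
    blocks = prune_low_energy(blocks, mag, params)
    blocks.sort(
        key=lambda b: (
            -b.mean_magnitude(mag),
            b.frame_lo,
            b.bin_lo,
            b.frame_hi,
            b.bin_hi,
        )
    )
    blocks = blocks + fill_equidistant(mag.shape, blocks, params.fill_window)
    return Segmentation(
        blocks=blocks,
        matrix_shape=mag.shape,
        global_mean=float(mag.mean()),
        global_std=float(mag.std()),
    )
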