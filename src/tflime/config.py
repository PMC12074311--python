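"""Default parameter sets and named presets.

The defaults reproduce the reference experimental configuration: Hann frames
of 128 samples with 50% overlap at fs = 200 Hz (1.5625 Hz per bin), peak
energy-threshold factor eta = 0.5, noise suppression beta = 1.5, DBSCAN radius
eps = 0.5 with magnitude scaling alpha = 1, maximum time gap gamma = 1 frame,
boundary decay constraint tau_drop = 0.6, global energy threshold
tau_global = 1.2, overlap threshold delta = 0.3, equidistant fill window 2,
and u = 500 perturbation samples for the surrogate fit.  The locality
kernel width (0.5 on standardised DTW distances) and the ridge penalty (0.1)
are the package's own calibrated defaults; neither is part of the reference
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .transform import StftParams

__all__ = ["TfhsParams", "LimeParams", "DEFAULT_STFT", "preset"]


@dataclass(frozen=True)
class TfhsParams:
    """Tuning knobs of the time-frequency homogeneous segmentation.

    energy_threshold_factor (eta)
        a peak must reach this fraction of its frame's spectral maximum.
    noise_suppression (beta)
        a peak must exceed the global mean magnitude by ``beta`` global
        standard deviations.
    cluster_radius (eps) / magnitude_scale (alpha) / min_cluster_points
        DBSCAN neighbourhood on (bin index, normalised magnitude) features;
        ``alpha`` scales the magnitude axis.
    max_time_gap (gamma)
        clusters are split where consecutive peak frames differ by more.
    energy_decay (tau_drop) / global_energy (tau_global)
        boundary expansion keeps a bin while its time-averaged magnitude stays
        above ``tau_drop`` times the running band maximum and above
        ``tau_global`` times the global mean magnitude.
    overlap_threshold (delta)
        Jaccard overlap at which two blocks are considered duplicates.
    fill_window
        side length (frames and bins) of the equidistant fill tiles.
    prune_factor
        peak-based blocks whose mean magnitude falls below this fraction of
        the global mean are discarded as noise-induced.
    """

    energy_threshold_factor: float = 0.5
    noise_suppression: float = 1.5
    cluster_radius: float = 0.5
    magnitude_scale: float = 1.0
    min_cluster_points: int = 2
    max_time_gap: int = 1
    energy_decay: float = 0.6
    global_energy: float = 1.2
    overlap_threshold: float = 0.3
    fill_window: int = 2
    prune_factor: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.energy_threshold_factor <= 1):
            raise ValueError("energy_threshold_factor must be in (0, 1]")
        if self.noise_suppression < 0:
            raise ValueError("noise_suppression must be >= 0")
        if self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be positive")
        if self.magnitude_scale < 0:
            raise ValueError("magnitude_scale must be >= 0")
        if self.max_time_gap < 1:
            raise ValueError("max_time_gap must be >= 1")
        if not (0 < self.energy_decay <= 1):
            raise ValueError("energy_decay must be in (0, 1]")
        if self.global_energy <= 0:
            raise ValueError("global_energy must be positive")
        if not (0 < self.overlap_threshold <= 1):
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.fill_window < 1:
            raise ValueError("fill_window must be >= 1")


@dataclass(frozen=True)
class LimeParams:
    """Perturbation-and-surrogate settings for one explanation."""

    n_samples: int = 500
    kernel_width: float = 0.5
    ridge_penalty: float = 0.1
    seed: int = 0
    target_class: int | None = None  # None: explain the model's predicted class

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be >= 0")


DEFAULT_STFT = StftParams(n_window=128, hop=64, window_fn="hann", one_sided=True)

_PRESETS = {
    # 64-class two-window detection task: wider DBSCAN radius
    "dataset2": {"cluster_radius": 0.6},
    # ECG-like data with weak time-frequency energy
    "ecg": {"cluster_radius": 0.32, "energy_threshold_factor": 0.25},
}


def preset(name: str, base: TfhsParams | None = None) -> TfhsParams:
    """Return a named TFHS parameter preset applied on top of ``base``."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return replace(base or TfhsParams(), **_PRESETS[name])
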