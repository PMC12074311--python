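"""Synthetic benchmarks with exact time-frequency ground truth.

Two generators are provided.  The segmentation benchmark draws signals that
are superpositions of 1-5 windowed sine components (amplitude U[1, 5],
frequency up to 50 Hz, uniform phase, uniform activation windows) plus
Gaussian white noise, sampled at 200 Hz for 1000 points.  The 64-class
detection benchmark places an independent subset of the frequency set
{5, 20, 40} Hz in each of two 2.5 s windows; the pair of subsets is the class
label.

Ground-truth saliency masks are recorded differentially during construction:
each component is added in turn to the noiseless partial signal and the cells
of the STFT magnitude matrix that change by more than half of the change's
maximum are marked as belonging to that component; the sample's mask is the
union over components.  The half-maximum cutoff records the component's main
energy (its FWHM footprint) rather than the arbitrarily wide leakage skirt,
at the same resolution the segmenter sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .transform import StftParams, TimeSeries, TFMatrix, stft
from .config import DEFAULT_STFT

__all__ = [
    "SignalComponent",
    "SignalSpec",
    "SyntheticSample",
    "synthesize",
    "ground_truth_mask",
    "generate_dataset1",
    "generate_dataset2",
    "samples_to_npz",
    "encode_label",
    "decode_label",
    "FREQUENCY_SET",
    "WINDOWS",
]

#: detection-task frequency alphabet (Hz) and the two activation windows (s)
FREQUENCY_SET = (5.0, 20.0, 40.0)
WINDOWS = ((0.0, 2.5), (2.5, 5.0))

#: differential magnitude cutoff marking a cell as part of a component: the
#: full-width-at-half-maximum footprint, i.e. the component's main energy
MASK_THRESHOLD = 0.5

#: resolvability floors at the default STFT resolution (1.5625 Hz, 0.32 s hop)
MIN_FREQ_SEPARATION = 3.0
MIN_DURATION = 0.5
MIN_FREQUENCY = 1.5625


@dataclass(frozen=True)
class SignalComponent:
    """One windowed sine: ``A * sin(2*pi*f*t + phi)`` active on [t_start, t_end)."""

    amplitude: float
    frequency: float
    phase: float
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("component window must have positive duration")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    def sample(self, t: np.ndarray) -> np.ndarray:
        active = (t >= self.t_start) & (t < self.t_end)
        return np.where(
            active,
            self.amplitude * np.sin(2 * np.pi * self.frequency * t + self.phase),
            0.0,
        )


@dataclass(frozen=True)
class SignalSpec:
    """Generative description of one sample: components plus noise level."""

    components: tuple[SignalComponent, ...]
    noise_sigma: float = 0.01
    sampling_rate: float = 200.0
    n_samples: int = 1000

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class SyntheticSample:
    """A generated series with its spec, ground-truth mask and optional label."""

    series: TimeSeries
    spec: SignalSpec
    mask: np.ndarray
    label: "Dataset2Label | None" = None


@dataclass(frozen=True)
class Dataset2Label:
    """Which of {5, 20, 40} Hz is present in each half of the signal."""

    window1: frozenset[float]
    window2: frozenset[float]

    @property
    def class_index(self) -> int:
        return encode_label(self.window1, self.window2)


def _subset_code(subset: frozenset[float]) -> int:
    """Bit per frequency, lowest frequency = least significant bit."""
    code = 0
    for i, f in enumerate(FREQUENCY_SET):
        if f in subset:
            code |= 1 << i
    return code


def encode_label(window1: frozenset[float], window2: frozenset[float]) -> int:
    """Class index in [0, 63]: ``8 * code(window1) + code(window2)``."""
    return 8 * _subset_code(frozenset(window1)) + _subset_code(frozenset(window2))


def decode_label(class_index: int) -> Dataset2Label:
    if not 0 <= class_index < 64:
        raise ValueError("class index must be in [0, 64)")
    code1, code2 = divmod(class_index, 8)
    to_set = lambda code: frozenset(
        f for i, f in enumerate(FREQUENCY_SET) if code & (1 << i)
    )
    return Dataset2Label(to_set(code1), to_set(code2))


def samples_to_npz(samples, path, manifest: dict | None = None) -> None:
    """Persist generated samples: series matrix, labels, masks, spec table.

    Writes a compressed .npz next to a ``<path>.manifest.json`` recording the
    generation parameters.  Labels are -1 for the segmentation benchmark.
    """
    import json
    from pathlib import Path

    series = np.stack([s.series.values for s in samples])
    masks = np.stack([s.mask for s in samples]).astype(np.uint8)
    labels = np.array(
        [s.label.class_index if s.label is not None else -1 for s in samples]
    )
    spec_rows = [
        [i, c.amplitude, c.frequency, c.phase, c.t_start, c.t_end]
        for i, s in enumerate(samples)
        for c in s.spec.components
    ]
    np.savez_compressed(
        path,
        series=series,
        labels=labels,
        masks=masks,
        components=np.array(spec_rows) if spec_rows else np.zeros((0, 6)),
        sampling_rate=np.array(samples[0].spec.sampling_rate),
    )
    if manifest is not None:
        Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1))


def synthesize(spec: SignalSpec, rng: np.random.Generator) -> TimeSeries:
    """Sample the spec: deterministic component sum plus ``sigma * N(0, 1)``."""
    t = spec.times()
    values = np.zeros_like(t)
    for comp in spec.components:
        values += comp.sample(t)
    if spec.noise_sigma > 0:
        values = values + spec.noise_sigma * rng.standard_normal(t.size)
    return TimeSeries(values, spec.sampling_rate)


def ground_truth_mask(
    spec: SignalSpec, stft_params: StftParams | None = None
) -> np.ndarray:
    """Differential footprint of each component in the noiseless spectrogram.

    Components are added one at a time; a cell belongs to a component when the
    added component changes the magnitude there by more than
    ``MASK_THRESHOLD`` of the change's maximum.  Returns the boolean union.
    """
    stft_params = stft_params or DEFAULT_STFT
    t = spec.times()
    partial = np.zeros_like(t)
    prev_mag = np.abs(
        stft(TimeSeries(partial, spec.sampling_rate), stft_params).coeffs
    )
    mask = np.zeros(prev_mag.shape, dtype=bool)
    for comp in spec.components:
        partial = partial + comp.sample(t)
        mag = np.abs(stft(TimeSeries(partial, spec.sampling_rate), stft_params).coeffs)
        diff = np.abs(mag - prev_mag)
        peak = diff.max()
        if peak > 0:
            mask |= diff > MASK_THRESHOLD * peak
        prev_mag = mag
    return mask


def _draw_window(
    rng: np.random.Generator, duration: float, lo: float = 0.0, hi: float | None = None
) -> tuple[float, float]:
    """Uniform activation window of at least MIN_DURATION inside [lo, hi]."""
    hi = duration if hi is None else hi
    while True:
        a, b = np.sort(rng.uniform(lo, hi, size=2))
        if b - a >= MIN_DURATION:
            return float(a), float(b)


def _draw_frequencies(rng: np.random.Generator, k: int) -> list[float]:
    """Frequencies in (0, 50] Hz, pairwise at least MIN_FREQ_SEPARATION apart."""
    freqs: list[float] = []
    while len(freqs) < k:
        f = float(rng.uniform(MIN_FREQUENCY, 50.0))
        if all(abs(f - g) >= MIN_FREQ_SEPARATION for g in freqs):
            freqs.append(f)
    return freqs


def _draw_spec(
    rng: np.random.Generator, n_components: int, noise_sigma: float
) -> SignalSpec:
    spec = SignalSpec(components=(), noise_sigma=noise_sigma)
    comps = []
    for f in _draw_frequencies(rng, n_components):
        t_start, t_end = _draw_window(rng, spec.duration)
        comps.append(
            SignalComponent(
                amplitude=float(rng.uniform(1.0, 5.0)),
                frequency=f,
                phase=float(rng.uniform(0.0, 2 * np.pi)),
                t_start=t_start,
                t_end=t_end,
            )
        )
    return SignalSpec(components=tuple(comps), noise_sigma=noise_sigma)


def generate_dataset1(
    n_single: int = 200,
    n_multi: int = 800,
    noise_sigma: float = 0.01,
    rng: np.random.Generator | int | None = None,
    stft_params: StftParams | None = None,
) -> list[SyntheticSample]:
    """Segmentation benchmark: single-component and 2-5 component cohorts."""
    rng = np.random.default_rng(rng)
    stft_params = stft_params or DEFAULT_STFT
    samples: list[SyntheticSample] = []
    counts = [1] * n_single + [int(rng.integers(2, 6)) for _ in range(n_multi)]
    for k in counts:
        spec = _draw_spec(rng, k, noise_sigma)
        samples.append(
            SyntheticSample(
                series=synthesize(spec, rng),
                spec=spec,
                mask=ground_truth_mask(spec, stft_params),
            )
        )
    return samples


def generate_dataset2(
    n: int,
    noise_sigma: float = 0.01,
    rng: np.random.Generator | int | None = None,
    stft_params: StftParams | None = None,
    stratified: bool = False,
) -> list[SyntheticSample]:
    """64-class detection benchmark.

    Each window of ``WINDOWS`` independently receives a uniform subset of
    ``FREQUENCY_SET`` (components span the whole window; amplitudes and phases
    as in the segmentation benchmark).  With ``stratified=True`` the class
    sequence cycles through all 64 labels before repeating.
    """
    rng = np.random.default_rng(rng)
    stft_params = stft_params or DEFAULT_STFT
    if stratified:
        order = np.arange(64)
        classes = np.concatenate(
            [rng.permutation(order) for _ in range(n // 64 + 1)]
        )[:n]
    else:
        classes = rng.integers(0, 64, size=n)
    samples: list[SyntheticSample] = []
    for class_index in classes:
        label = decode_label(int(class_index))
        comps = []
        for subset, (w_lo, w_hi) in zip((label.window1, label.window2), WINDOWS):
            for f in sorted(subset):
                comps.append(
                    SignalComponent(
                        amplitude=float(rng.uniform(1.0, 5.0)),
                        frequency=f,
                        phase=float(rng.uniform(0.0, 2 * np.pi)),
                        t_start=w_lo,
                        t_end=w_hi,
                    )
                )
        spec = SignalSpec(components=tuple(comps), noise_sigma=noise_sigma)
        samples.append(
            SyntheticSample(
                series=synthesize(spec, rng),
                spec=spec,
                mask=ground_truth_mask(spec, stft_params),
                label=label,
            )
        )
    return samples
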