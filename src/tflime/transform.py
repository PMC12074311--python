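"""Short-time Fourier analysis: the shared time-frequency coordinate system.

A signal is carved into overlapping frames of ``n_window`` samples spaced
``hop`` apart (frames are taken only where a full window fits, so
``L = (T - N) // H + 1``), each frame is tapered and transformed with the DFT,
and the resulting complex matrix ``coeffs`` of shape ``L x K`` is what every
other module segments, masks and inverts.  Reconstruction uses weighted
overlap-add with squared-window normalisation, which is exact on the interior
for any constant-overlap-add (COLA) window/hop pair such as Hann with
``hop = n_window / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

__all__ = ["TimeSeries", "StftParams", "TFMatrix", "stft", "istft", "magnitude"]

#: below this summed squared-window value a sample counts as uncovered
_COVERAGE_TOL = 1e-12


@dataclass(frozen=True)
class TimeSeries:
    """A univariate, uniformly sampled signal."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("time series must be a non-empty 1-D vector")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class StftParams:
    """Frame length ``n_window`` (N), hop ``H``, taper and spectrum sidedness."""

    n_window: int = 128
    hop: int = 64
    window_fn: str = "hann"
    one_sided: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.n_window):
            raise ValueError("require 0 < hop <= n_window")

    @property
    def n_bins(self) -> int:
        return self.n_window // 2 + 1 if self.one_sided else self.n_window

    def window(self) -> np.ndarray:
        # periodic (DFT-even) taper: the variant with the COLA property
        return get_window(self.window_fn, self.n_window, fftbins=True)

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.n_window:
            raise ValueError(
                f"series of length {n_samples} is shorter than one frame "
                f"({self.n_window} samples)"
            )
        return (n_samples - self.n_window) // self.hop + 1

    def frame_interval(self, frame: int) -> tuple[int, int]:
        """Half-open sample interval ``[l*H, l*H + N)`` covered by a frame."""
        start = frame * self.hop
        return start, start + self.n_window

    def bin_frequency(self, k: int, sampling_rate: float) -> float:
        return k * sampling_rate / self.n_window


@dataclass
class TFMatrix:
    """Complex STFT coefficients together with the parameters that made them."""

    coeffs: np.ndarray
    params: StftParams
    sampling_rate: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if self.coeffs.ndim != 2:
            raise ValueError("coeffs must be a 2-D complex matrix")
        if self.coeffs.shape[1] != self.params.n_bins:
            raise ValueError(
                f"coeffs have {self.coeffs.shape[1]} bins, parameters imply "
                f"{self.params.n_bins}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.coeffs.shape

    def copy(self) -> "TFMatrix":
        return TFMatrix(self.coeffs.copy(), self.params, self.sampling_rate)


def stft(series: TimeSeries, params: StftParams) -> TFMatrix:
    """Windowed DFT over sliding frames.

    Frame ``l`` covers samples ``[l*H, l*H + N)``; bin ``k`` maps to frequency
    ``k * fs / N``.  One-sided output keeps ``K = N//2 + 1`` bins (the
    conjugate-symmetric half of the spectrum of a real signal).
    """
    x = series.values
    n = params.n_window
    n_frames = params.n_frames(x.size)
    frames = np.lib.stride_tricks.sliding_window_view(x, n)[:: params.hop]
    frames = frames[:n_frames] * params.window()
    if params.one_sided:
        coeffs = np.fft.rfft(frames, axis=1)
    else:
        coeffs = np.fft.fft(frames, axis=1)
    return TFMatrix(coeffs, params, series.sampling_rate)


def istft(
    tf: TFMatrix,
    target_length: int,
    original: TimeSeries | None = None,
) -> TimeSeries:
    """Weighted overlap-add inverse of :func:`stft`.

    Each frame is inverse-transformed, tapered again by the analysis window and
    accumulated; the sum is normalised by the summed squared window.  The
    divisor is clamped from below at half its maximum — within the fully
    overlapped interior of a COLA window/hop pair the squared-window sum never
    falls below that, so reconstruction there is exact, while the thinly
    covered first and last half-window attenuate smoothly instead of dividing
    by a vanishing taper (which would amplify any modification of the
    coefficients without bound).  Samples never covered by a frame (the tail
    beyond the last full window) carry no information in ``tf``; they are
    copied from ``original`` when given and zero otherwise.
    """
    params = tf.params
    n = params.n_window
    hop = params.hop
    n_frames = tf.coeffs.shape[0]
    min_length = (n_frames - 1) * hop + n
    if target_length < min_length:
        raise ValueError(
            f"target_length {target_length} cannot hold {n_frames} frames "
            f"of {n} samples at hop {hop}"
        )
    if original is not None and len(original) != target_length:
        raise ValueError("original series length must equal target_length")

    if params.one_sided:
        frames = np.fft.irfft(tf.coeffs, n=n, axis=1)
    else:
        frames = np.fft.ifft(tf.coeffs, axis=1).real
    window = params.window()
    frames = frames * window

    acc = np.zeros(target_length)
    wsum = np.zeros(target_length)
    starts = np.arange(n_frames) * hop
    for start, frame in zip(starts, frames):
        acc[start : start + n] += frame
        wsum[start : start + n] += window**2

    covered = wsum > _COVERAGE_TOL
    divisor = np.maximum(wsum, 0.5 * wsum.max())
    out = np.zeros(target_length)
    out[covered] = acc[covered] / divisor[covered]
    if original is not None:
        out[~covered] = original.values[~covered]
    return TimeSeries(out, tf.sampling_rate)


def magnitude(tf: TFMatrix) -> np.ndarray:
    """Elementwise modulus ``|M[l, k]|`` — the local signal energy envelope."""
    return np.abs(tf.coeffs)
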