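"""Shared fixtures.

The detection-task fixtures (datasets plus trained reference models) are
session-scoped because training takes tens of seconds; they are built lazily
so unit-test-only runs never pay for them.
"""

from __future__ import annotations

import numpy as np
import pytest

import tflime as tl
from tflime.models import MlpSpec, samples_to_arrays, train_mlp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def _detection_task(sigma: float):
    from tflime.experiments import detection_task

    model, test, accuracy = detection_task(sigma, seed=100)
    return model, test, accuracy


@pytest.fixture(scope="session")
def detection_baseline():
    """Trained reference MLP and held-out samples, low-noise task."""
    return _detection_task(0.01)


@pytest.fixture(scope="session")
def detection_noise():
    """Trained reference MLP and held-out samples, high-noise task."""
    return _detection_task(0.7)


@pytest.fixture(scope="session")
def single_tone_sample():
    """One noiseless single-tone series with its spec and mask."""
    spec = tl.SignalSpec(
        components=(
            tl.SignalComponent(
                amplitude=3.0, frequency=20.9, phase=0.4, t_start=1.0, t_end=4.5
            ),
        ),
        noise_sigma=0.0,
    )
    series = tl.synthesize(spec, np.random.default_rng(0))
    mask = tl.ground_truth_mask(spec)
    return series, spec, mask
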