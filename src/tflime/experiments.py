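"""Benchmark experiment runners.

Reusable drivers for the three quantitative studies the synthetic benchmarks
support: segmentation quality of TFHS against recorded ground truth,
accuracy of the reference detection MLP, and saliency quality (AUPRC) of the
explanations against ground-truth masks.  Each driver is deterministic in its
seed arguments and returns plain dictionaries of means, so callers (tests,
scripts, the CLI) can report or assert on them directly.
"""

from __future__ import annotations

import numpy as np

from .config import DEFAULT_STFT, LimeParams, TfhsParams, preset
from .datasets import SignalSpec, generate_dataset1, generate_dataset2, synthesize
from .explain import explain
from .metrics import err, fpr, iou, saliency_curves
from .models import BlackBoxModel, MlpSpec, samples_to_arrays, train_mlp
from .segmentation import segment
from .transform import TimeSeries, magnitude, stft

__all__ = [
    "segmentation_benchmark",
    "detection_task",
    "explanation_benchmark",
]


def segmentation_benchmark(
    n_single: int,
    n_multi: int,
    noise_sigma: float,
    seed: int,
    tfhs_params: TfhsParams | None = None,
) -> dict:
    """Segment a generated cohort and score against ground-truth masks.

    The predicted region is the union of peak-based blocks.  The energy
    matrix for the retention ratio is the squared magnitude of the noiseless
    signal's spectrogram, so noise energy never inflates the score.
    """
    tfhs_params = tfhs_params or TfhsParams()
    samples = generate_dataset1(n_single, n_multi, noise_sigma, rng=seed)
    ious, fprs, errs = [], [], []
    for sample in samples:
        mag = magnitude(stft(sample.series, DEFAULT_STFT))
        seg = segment(mag, tfhs_params)
        predicted = seg.peak_region()
        truth = sample.mask
        ious.append(iou(predicted, truth))
        fprs.append(fpr(predicted, truth) if predicted.any() else 0.0)
        noiseless = synthesize(
            SignalSpec(sample.spec.components, 0.0), np.random.default_rng(0)
        )
        energy = magnitude(stft(noiseless, DEFAULT_STFT)) ** 2
        errs.append(err(predicted, truth, energy))
    return {
        "iou": float(np.mean(ious)),
        "fpr": float(np.mean(fprs)),
        "err": float(np.mean(errs)),
        "n": len(samples),
    }


def detection_task(
    noise_sigma: float,
    seed: int,
    n_train: int = 10_000,
    n_test: int = 1000,
    mlp_spec: MlpSpec | None = None,
) -> tuple[BlackBoxModel, list, float]:
    """Train the reference MLP and measure held-out accuracy.

    Returns (model, held-out samples, accuracy in [0, 1]).  Training data is
    stratified over the 64 classes; the test draw is independent.
    """
    train = generate_dataset2(n_train, noise_sigma, rng=seed, stratified=True)
    X, y = samples_to_arrays(train)
    model = train_mlp(X, y, mlp_spec or MlpSpec(seed=seed))
    test = generate_dataset2(n_test, noise_sigma, rng=seed + 1)
    X_test, y_test = samples_to_arrays(test)
    accuracy = float((model.predict(X_test).argmax(1) == y_test).mean())
    return model, test, accuracy


def explanation_benchmark(
    model: BlackBoxModel,
    samples: list,
    n_explain: int,
    seed: int,
    mode: str = "tfhs",
    tfhs_params: TfhsParams | None = None,
    lime_params: LimeParams | None = None,
) -> dict:
    """Explain correctly-classified samples and score saliency vs masks.

    Follows the evaluation protocol of the detection study: only samples the
    model classifies correctly are explained, and samples whose ground-truth
    mask is empty (the all-absent class) are skipped since precision/recall
    are undefined there.
    """
    tfhs_params = tfhs_params or preset("dataset2")
    lime_params = lime_params or LimeParams()
    X, y = samples_to_arrays(samples)
    predictions = model.predict(X).argmax(1)
    eligible = [
        i
        for i in range(len(samples))
        if predictions[i] == y[i] and samples[i].mask.any()
    ][:n_explain]
    auprc, aup, aur = [], [], []
    for i in eligible:
        result = explain(
            samples[i].series,
            model,
            tfhs_params=tfhs_params,
            lime_params=LimeParams(
                n_samples=lime_params.n_samples,
                kernel_width=lime_params.kernel_width,
                ridge_penalty=lime_params.ridge_penalty,
                seed=seed + i,
            ),
            mode=mode,
        )
        curves = saliency_curves(result.saliency(), samples[i].mask)
        auprc.append(curves.auprc)
        aup.append(curves.aup)
        aur.append(curves.aur)
    return {
        "auprc": float(np.mean(auprc)),
        "aup": float(np.mean(aup)),
        "aur": float(np.mean(aur)),
        "n": len(eligible),
    }
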