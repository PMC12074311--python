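# tflime — time–frequency explanations for black-box time-series classifiers

`tflime` explains the predictions of an arbitrary time-series classifier by
attributing them to *regions of the time–frequency plane* rather than to
individual time points. Classical local surrogate explanations (LIME-style)
perturb raw samples of the series; for oscillatory signals this produces
saliency maps that are hard to read, because the discriminative structure —
"a 20 Hz component in the first half of the window" — lives in frequency, not
in any single sample. `tflime` instead:

1. computes a short-time Fourier transform (STFT) of the series,
2. partitions the spectrogram into rectangular blocks with a
   **time–frequency hierarchical segmentation** (TFHS) that isolates
   spectral-peak regions and tiles the remainder,
3. perturbs the prediction by zeroing random subsets of blocks and
   reconstructing the series through the inverse STFT,
4. fits a weighted ridge surrogate on the on/off block indicators, with
   sample weights derived from dynamic-time-warping distance to the original
   series,
5. returns one importance weight per block, which expands to a
   time–frequency heatmap.

The package also ships the synthetic benchmarks used to validate the method:
a *segmentation* benchmark (random multi-tone signals with recorded
ground-truth masks) and a 64-class *detection* benchmark (which of the
frequencies {5, 20, 40} Hz are active in each half of a 5 s window), plus a
reference MLP classifier for the latter, the evaluation metrics (IoU, false
positive ratio, energy retention ratio, saliency precision/recall areas and
AUPRC), and a command-line interface.

## Worked example

Segment and explain a two-tone signal (5 s at 200 Hz): a strong 8 Hz tone
during seconds 0.5–3 and a weaker 33 Hz tone during seconds 2–4.5, plus a
little noise. The black box here is a toy model that scores the 6–10 Hz band
energy, so the explanation should single out the 8 Hz block.

```python
import numpy as np
import tflime as tl
from tflime.config import LimeParams
from tflime.models import wrap_model

spec = tl.SignalSpec(
    components=(
        tl.SignalComponent(amplitude=3.0, frequency=8.0, phase=0.0,
                           t_start=0.5, t_end=3.0),
        tl.SignalComponent(amplitude=2.0, frequency=33.0, phase=1.2,
                           t_start=2.0, t_end=4.5),
    ),
    noise_sigma=0.05,
)
series = tl.synthesize(spec, np.random.default_rng(0))

mag = tl.magnitude(tl.stft(series, tl.DEFAULT_STFT))   # (14, 65) spectrogram
seg = tl.segment(mag)                                   # TFHS partition
for b in (b for b in seg.blocks if b.origin == "peak"):
    print(b.frame_lo, b.frame_hi, b.bin_lo, b.bin_hi)

truth = tl.ground_truth_mask(spec)
print(f"IoU vs ground truth: {tl.iou(seg.peak_region(), truth):.3f}")

def band_energy_model(batch):            # toy black box: 6-10 Hz band energy
    spectra = np.abs(np.fft.rfft(batch, axis=1))
    freqs = np.fft.rfftfreq(batch.shape[1], d=1 / 200.0)
    score = spectra[:, (freqs >= 6) & (freqs <= 10)].sum(axis=1)
    p = score / (score.max() + 1e-12)
    return np.stack([1 - p, p], axis=1)

result = tl.explain(series, wrap_model(band_energy_model, 2),
                    lime_params=LimeParams(seed=0, target_class=1))
print(f"surrogate weighted R^2: {result.local_fit_quality:.3f}")
i = int(np.argmax(result.block_weights))
b = result.segmentation.blocks[i]
print(f"{result.block_weights[i]:+.4f}", b.frame_lo, b.frame_hi, b.bin_lo, b.bin_hi)
```

Running this prints (exact values, seed-deterministic):

```
1 8 5 6
6 13 21 22
IoU vs ground truth: 0.912
surrogate weighted R^2: 0.999
+0.8129 1 8 5 6
```

TFHS finds exactly two peak blocks — frames 1–8 × bins 5–6 (7.8–9.4 Hz) and
frames 6–13 × bins 21–22 (32.8–34.4 Hz) — matching the two tones' true
activations with IoU 0.912, and the explanation assigns by far its largest
weight (+0.81; the runners-up are fill tiles at +0.04) to the 8 Hz block the
toy model actually reads. `result.heatmap()` expands the block weights to
the full 14 × 65 time–frequency plane.

## Command line

```sh
tflime simulate --dataset detection --n 10000 --sigma 0.01 --stratified \
                --seed 0 --out train.npz
tflime train    --data train.npz --seed 0 --out model.pkl
tflime simulate --dataset detection --n 1000 --sigma 0.01 --seed 1 --out test.npz
tflime evaluate --data test.npz --model model.pkl --n 100 --seed 0 --out summary.json
tflime segment  --data test.npz --out metrics.csv
tflime explain  --input series.csv --model model.pkl --preset dataset2 \
                --seed 0 --out explanation.json
```

All commands are deterministic in `--seed` and log progress to stderr.

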