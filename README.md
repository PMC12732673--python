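# deepblastoid

Automated morphological classification of human blastoids — stem-cell-derived
models of the preimplantation blastocyst — from brightfield microwell images,
with confidence-based triage of uncertain predictions to human review and
experiment-level analytics.

## The problem

Blastoids are formed in AggreWell plates where each well contains ~1,200
pyramidal microwells, one aggregate per microwell. Scoring an experiment means
classifying every microwell tile into one of five morphology classes:

| class | morphology |
|-------|------------|
| A | well-formed cavity + inner cell mass (ICM) inside a complete trophectoderm (TE) ring |
| B | cavity but no ICM |
| C | ICM but an irregular/broken TE ring |
| D | no cavity — cellular debris |
| W | empty microwell |

Manual scoring of tens of thousands of tiles per plate is the bottleneck.
This package provides the full desk-scale pipeline: a seeded synthetic
microwell-image simulator (with pixel-level truth masks), a CNN training and
inference harness, the Confidence Rate statistic for selective prediction,
classification and inter-rater metrics, and dose-response analytics.

## The Confidence Rate (CR)

For a 5-class score vector *P*, normalize *pᵢ = Pᵢ / ΣPᵢ*, take the mean
μ = ⅕Σpᵢ and population standard deviation σ = √(⅕Σ(pᵢ−μ)²), standardize the
winning score, *Z = (p_max − μ)/σ*, and squash: **CR = 1/(1+e^(−Z))**.
For five classes Z ∈ [0, 2], so CR ∈ [0.5, 1/(1+e^(−2)) ≈ 0.8808]; a uniform
vector (σ = 0) is defined as CR = 0.5. Predictions with CR below a threshold
(default 0.8) are flagged for expert review; sweeping the threshold trades
retained data volume against accuracy on the retained subset.

## Worked example

```python
import numpy as np
from deepblastoid import (
    SyntheticDatasetSpec, TrainConfig, train, topk_accuracy,
    confidence_rates, tradeoff_curve, summarize, decode_labels,
)
from deepblastoid.synthgen import generate_tiles

spec = SyntheticDatasetSpec(n_images=700, image_size_px=64, seed=11,
                            exact_counts=True)  # 140 tiles per class
images, masks, codes, manifest = generate_tiles(spec)

cfg = TrainConfig(epochs=10, input_size=64, seed=3)
model, log = train(images[:500], codes[:500], cfg)

proba = model.predict_proba(images[500:700])
y = codes[500:700]
print("top-1:", topk_accuracy(y, proba, 1))          # 0.98
print("top-2:", topk_accuracy(y, proba, 2))          # 1.0
pts = tradeoff_curve(proba, y, [0.0, 0.8])
print("retained @ CR>=0.8:", pts[1].retained_fraction,
      pts[1].retained_accuracy)                      # 0.99 0.9797...
print(summarize(decode_labels(np.argmax(proba, axis=1))).frequencies)
# (0.185, 0.21, 0.195, 0.18, 0.23) — generating mixture was 0.2 each
```

Training the small CNN on 500 clean 64-px tiles for 10 epochs reaches
~98% held-out top-1 here, and the class-frequency summary recovers the
generating mixture to within a few percentage points. On clean synthetic
data the classifier is already near its ceiling, so the CR sweep has little
headroom at this seed; its value shows on harder inputs, where raising the
threshold monotonically sheds low-confidence tiles and raises accuracy on
the retained subset (see `tradeoff_curve` and the acceptance run).

The same flow is available from the shell:

```bash
deepblastoid generate --n 600 --size 64 --seed 1 --out ds/
deepblastoid run --config config.yaml --seed 1 --out artifacts/
```

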