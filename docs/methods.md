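# Methods

## Scope and shape

The package re-implements a microwell brightfield classification pipeline at
desk scale. No real microscope data or pretrained weights are shipped or
required: a seeded simulator generates the study data, and every downstream
component — training harness, Confidence-Rate triage, metrics, analytics —
operates identically on real tiles should a user supply them. The classifier
is exposed as a scikit-learn-style estimator (`BlastoidClassifier` with
`fit`/`predict`/`predict_proba`, `get_params`/`set_params` and fitted
attributes ending in `_`) so it composes with sklearn pipelines and model
selection; the other stages are plain functions because they are not
fit/predict shaped.

## Synthetic microwell simulator

Each tile is drawn as antialiased intensity primitives on a darker well
background (base intensity 0.32 of full scale, Gaussian texture noise
sd 0.012): a bright TE ring (annulus, intensity 0.78), a cavity interior
(0.52), an ICM disk (0.88) placed against the inner ring wall, and debris
speckles (≈0.70) for class D. Geometry scales with tile size: ring radius
0.26–0.33 of the side, ICM radius 0.09–0.12, ring thickness 18% of its
radius. Class C rings carry a sinusoidal radius wobble and an angular gap
so that ring completeness falls in 0.45–0.70; classes A/B have completeness
0.97–1.0. Output is 16-bit grayscale PNG (intensities scaled to [0, 65535]),
default tile size 300×300 px; tests and the acceptance run use 64×64 to keep
a CPU-only budget.

Every render also emits a truth mask labelling ring, cavity, ICM and debris
pixels. A rule-based oracle inverts the class definitions from the mask
alone (foreground presence, cavity presence, angular ring completeness with
a 0.8 threshold); on interference-free renders it recovers the generating
label for 100% of tiles, which is what makes the classes separable *by
construction*. Determinism is bit-exact: every operation is a pure function
of (inputs, seed) through `numpy.random.default_rng`.

Three interference modes emulate what defeats classical thresholding on
such plates: out-of-plane clutter (soft Gaussian bodies, the 2-D projection
of 3-D structure), defocus (normalized Gaussian blur, intensity-conserving
to <0.1%), and uneven illumination (multiplicative plane ramp `1 + a·t`,
`t ∈ [−1, 1]` along a direction, amplitude `a ≤ 1`). The zero spec is the
identity, and interference never alters the truth label in a manifest.
Multi-batch datasets add a per-batch global intensity offset (±4% of full
scale per batch step) — enough structure for round-robin split experiments
without claiming biological fidelity.

What the simulator does **not** model: real texture statistics, partial
morphologies between classes, debris overlapping intact blastoids,
inter-well optical crosstalk, or annotation noise. Passing tests therefore
demonstrate that the pipeline's machinery is correct and recovers known
ground truth under controlled difficulty — not that the shipped defaults
reach any particular accuracy on real microscope data.

## Cropping and splits

Cropping is declared-layout slicing: a `PlateLayout` (rows, cols, origin,
pitch, tile size; half-open 0-based pixel boxes, row-major order) maps a
plate image to byte-exact sub-rectangles with no resampling or intensity
adjustment, so crop ∘ assemble is lossless. Grid *detection* is out of
scope — a declared layout is reproducible and testable. Splits: seeded
random partition into requested sizes (optionally stratified by class, off
by default), k-fold, and round-robin by batch (train on all batches but
one). All schemes are permutation-stable under a fixed seed.

## Classifier and training recipe

The recipe: cross-entropy loss; AdamW (decoupled weight decay) with
learning rate 3×10⁻⁴ and weight decay 10⁻³; 36 epochs by default; global
gradient-norm clipping (max-norm 1.0 — the clip threshold is a free choice,
exposed in config); a 10× learning-rate multiplier on the final fully
connected layer; batch size 62, which makes ⌈1796/62⌉ = 29 updates per
epoch on a 1796-image training set. Augmentations: horizontal and vertical
flips at p = 0.5 each, color jitter at p = 0.4 (brightness/contrast factors
uniform in [0.8, 1.2] — the magnitudes are free choices, only the
probability is fixed), random scaling with factor uniform in [0.8, 1.0]
(the shrunk image is center-padded back with the image median), and random
erasing at p = 0.2 (a rectangle covering 2–20% of the area, filled with the
median). 16-bit inputs map to [0, 1] by a fixed /65535 scale, never
per-image min-max, so intensity semantics are stable across tiles.

The network stack is implemented directly in NumPy (im2col convolution,
batch normalization with running statistics, ReLU, 2×2 max pooling, dense
layers, manual backpropagation). The registered `tiny_cnn` backbone is
three conv(3×3)–batchnorm–ReLU–pool stages (8/16/32 channels), a 64-unit
hidden dense layer and a 5-way head, designed for 64×64 inputs (any
multiple of 8 works). Batch normalization is what lets the recipe's default
learning rate converge within a 10-epoch desk-scale budget; evaluation
mode uses running statistics, so inference is deterministic and repeated
calls are bit-identical. Larger residual backbones can be registered but
are not shipped. ImageNet-style pretraining is out of scope; the small
backbone trains from scratch.

Desk-scale study conditions (also used by `scripts/acceptance.py`): 700
interference-free 64-px tiles with exactly 140 per class, 500 for training
and 200 held out, 10 epochs, fixed seeds. Under these conditions held-out
top-1 ranges over roughly 0.93–0.995 across training seeds (0.98 at the
fixture seed), and CR triage at threshold 0.8 retains ~99% of these easy
tiles; the accuracy-vs-volume trade becomes visible on harder inputs.

## Confidence Rate

Implemented exactly as the closed formulas in the README: normalization,
mean and *population* standard deviation over all five normalized values,
`Z = (p_max − μ)/σ`, sigmoid. The degenerate uniform vector (σ = 0) is
defined as CR = 0.5, the Z → 0 limit. CR is scale- and
permutation-invariant, and for five classes is bounded in
[0.5, 1/(1+e⁻²) ≈ 0.8808], the upper bound attained iff the four losing
probabilities are equal (σ = (p_max − 0.2)/2 algebraically in that case).
An alternative reading — standardizing against the mean of the *other four*
probabilities only — is not implemented; the closed formulas win.

## Metrics

Confusion matrix (rows = truth), top-k accuracy with probability ties
ranked to the lowest class index (matching argmax), one-vs-rest precision /
recall (= sensitivity) / specificity / F1 per class. Undefined 0/0 ratios
surface as NaN and are excluded from macro averages — small synthetic sets
routinely have empty classes, and silent zeros would bias macro F1. Macro
F1 is the ablation-table statistic; micro F1 (= accuracy for single-label
multiclass) is also reported. Fleiss' κ (complete tables) and
Krippendorff's α (nominal metric, coincidence matrix, tolerates missing
ratings) are implemented from their standard formulations; both are
undefined (NaN) when chance agreement is 1 or expected disagreement is 0,
i.e. when every rating in the table is a single category.

## Analytics

Cavitation efficiency = freq(A)+freq(B)+freq(C); empty ratio = freq(W).
Both are computed over all predictions by default (optionally only over
auto-accepted ones — pass the triaged subset). The seeding-density
calibration fits `ln(empty_ratio) = a + b·density` by least squares and
rejects fits with `b ≥ 0`; the log-linear form is the natural Poisson
zero-count model for "no aggregate landed in this microwell" and inverts in
closed form. Group comparison is one-way ANOVA from the sum-of-squares
decomposition with Tukey HSD adjusted pairwise p-values (studentized-range
distribution); two groups additionally get an unpaired two-tailed t-test.
Distribution functions come from scipy; the decompositions themselves are
closed-form so they remain oracle-testable.

## Numerical choices and edge cases

- Cross-entropy clamps a zero true-class probability at 10⁻¹² rather than
  returning infinity.
- Argmax and top-k ties break to the lowest class index (A before B …).
- ANOVA with zero within-group variance: F undefined (NaN) when means are
  equal, +∞ (p = 0) when they differ.
- Tradeoff curves report an empty retained set as accuracy `None`
  (undefined), never 0.
- All per-image seeds derive from a single `Generator`; dataset generation,
  training and inference are reproducible bit-exactly for a fixed spec.

## Known limitations

The simulator's five classes are far more separable than real brightfield
morphology, so absolute accuracies here overstate real-data performance;
the 64-px desk scale understates the resolution (300×300 native, 512×512
model input) a production run would use; and the NumPy backbone is CPU-only
and deliberately small. The pluggable-backbone registry contains only
`tiny_cnn`; deeper residual networks would need a DL framework backend.
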