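# hyotrack

Automatic hyoid-bone tracking in ultrasound swallowing videos, built as a
fully tested, reproducible pipeline:

- **`hyotrack.synthetic`** — seeded generator of synthetic B-mode swallowing
  sequences (720×540 px, 0.325 mm/px, 32 fps by default) with exact
  per-frame ground-truth hyoid points, three-phase trajectories (elevation →
  anterior movement → return, 13–17 mm range of motion), bright-echo +
  acoustic-shadow rendering on Rayleigh speckle, swallow event timestamps,
  and an optional double-shadow fast-motion artifact.
- **`hyotrack.siamfc`** — a from-scratch fully-convolutional Siamese tracker:
  padding-free AlexNet-style backbone (total stride 8, 127×127 exemplar /
  255×255 search, 17×17 score map upsampled ×16 bicubically), offline pair
  training with center jitter/stretch augmentation, class-balanced weighted
  binary cross-entropy, SGD with exponentially annealed learning rate, and
  an online tracking loop with a fixed first-frame template, scale pyramid,
  cosine window and scale penalty. Implemented entirely in NumPy (im2col
  convolutions with hand-written backprop); no deep-learning framework
  required.
- **`hyotrack.dcf`** — a MOSSE-style discriminative correlation-filter
  baseline trained online in the Fourier domain (element-wise spectral
  products, circulant augmentation at init, exponential moving-average
  updates, sub-pixel peak refinement).
- **`hyotrack.metrics`** — the kinematic evaluation suite: per-frame center
  error, one-pass-evaluation precision curves (named thresholds 5 px =
  1.63 mm and 10 px = 3.25 mm), RMSE, average error, per-axis Pearson
  correlation, range of motion from hyoid onset to offset, relative ROM
  error, and equal-weight aggregation across sequences (mean ± sample SD).
- **`hyotrack.io` / `hyotrack.cli`** — PNG-sequence/CSV/JSON dataset formats,
  manifests, YAML run configs, plots, and a CLI chaining the stages.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for the
metric invariants, numerical gradient checks, and `tests/test_acceptance.py`
with one test per acceptance criterion. The scaled-benchmark criterion
trains and evaluates the Siamese tracker end-to-end for three seeds
(~3 minutes per seed on one core).

## CLI

```bash
hyotrack simulate --out data/synth --seed 0            # 30/10/10 dataset
hyotrack train --manifest data/synth/manifest.json --out runs/train --seed 0
hyotrack track --frames data/synth/seq_040/frames \
    --annotations data/synth/seq_040/annotations.csv \
    --events data/synth/seq_040/events.json \
    --tracker siamfc --weights runs/train/weights.npz --out trace.csv
hyotrack evaluate --trace trace.csv \
    --annotations data/synth/seq_040/annotations.csv \
    --events data/synth/seq_040/events.json --out report.json
hyotrack run-experiment --manifest data/synth/manifest.json \
    --tracker dcf --out runs/exp
```

Trackers are initialized from a 30×30 px box centered on the frame-0
ground-truth point only; annotations beyond frame 0 are used exclusively
for evaluation.

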