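# colorform

Representational-similarity analysis (RSA) of joint **color/form coding**
across the layers of vision models.

The package measures, for a layered model, whether the representational
geometry of color (the similarity profile among 12 calibrated hues of a
stimulus — its "color space") is invariant across object forms
(orthogonal/independent coding) or varies with form (interactive coding),
and how that changes across the processing hierarchy. It provides:

- **`colorform.color_math`** — sRGB ↔ CIELUV conversion (white point derived
  exactly from the sRGB matrix, out-of-gamut pixels counted), chroma, hue
  rotation, desaturation, mean-equating with overflow shrinkage, and a
  network-oriented "synthetic HSV" parameterization of RGB (luminance = mean
  of R,G,B; saturation = Euclidean distance to the equal-luminance gray;
  hue = angle on the iso-circle with 0° at maximal R).
- **`colorform.stimuli`** — calibrated stimulus grids: textured recolorings
  at 12 evenly spaced hues, uniform silhouettes, grayscale versions, and
  analytically drawn oriented bars (12 orientations × 12 hues), all equated
  in masked mean luminance and saturation; plus greedy/exhaustive
  maximally-dissimilar subset selection.
- **`colorform.activations`** — a `ModelAdapter` contract for extracting
  flattened activations from named layers (toy NumPy network always
  available; torchvision models supported when torch is installed),
  `layer_fraction` bookkeeping, and an HDF5 activation cache.
- **`colorform.metrics`** — per-object 12×12 color RSMs (Pearson or
  Euclidean), length-66 color-space vectors, between-object /
  cross-layer / cross-space second-order correlations, the normalized
  within-object color distance (bounded in [0,1] via the
  `d = sqrt((1−r)/2)` identity), and metric MDS embedding.
- **`colorform.stats`** — per-pair OLS slopes over `layer_fraction`,
  one-sample and matched-pairs t-tests, Fisher z, and the color-label
  shuffle null (expectation exactly 0 under label exchange).
- **`colorform.synth`** — seeded synthetic unit populations mixing an
  additive (orthogonal) cosine color-tuning component with an interactive
  component at controllable strength λ ∈ [0,1], layered trajectories with a
  λ schedule, and the toy convolutional network — ground truth for every
  metric with no downloads.
- **`colorform.pipeline` / `colorform.cli`** — deterministic stage
  orchestration (stimuli → extract → analyze → report) with byte-identical
  reruns.

## CLI

```bash
# 144 calibrated oriented-bar stimuli (12 orientations x 12 hues) + manifest
colorform make-stimuli --out out/stimuli

# push them through a seeded random-weight toy network, cache activations
colorform extract --network toy --network-seed 0 --out out/cache.h5

# full metric/stat battery (between-object means, pair slopes + t-test,
# within-object distances, cross-layer profiles, shuffle null, ...)
colorform analyze --cache out/cache.h5 --n-shuffles 100 --seed 0 --out out/analysis

# validation on synthetic populations with known ground-truth lambda
colorform simulate --seed 0 --out out/sim

# human-readable bundle with figures (hollow markers = fully-connected layers)
colorform report --analysis out/analysis --out out/bundle
```

Object-image sources are supported via `--source image_dir:<path>` (a
directory of near-white-background PNG/JPEG images); the bar pipeline needs
no external files. A YAML config (`--config`) mirrors all flags.

## Notes

- All randomness is governed by explicit seeds; equal configs produce
  byte-identical tables.
- Pretrained-network analyses require torch/torchvision and locally
  available weights; no test or acceptance quantity depends on them.
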