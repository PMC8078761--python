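# coilpose

2D centerline pose estimation for *C. elegans*, including the coiled,
self-occluded postures where classical skeletonization fails.

## The problem

Worm trackers reduce each video frame to a centerline — the "pose" — as a
vector of tangent angles θ = (θ₁ … θ₁₀₀) ordered head to tail. Standard
morphological skeletonization handles non-overlapping shapes well but
breaks on coils, Ω-turns and self-crossings, which is exactly where much
of the interesting behavior lives (escape responses, deep turns, many
mutants). Manual labeling of enough points along a worm body is slow,
ambiguous, and specific to one imaging setup.

`coilpose` sidesteps labeling entirely:

1. **A generative shape model.** A Gaussian mixture with full covariances
   over tangent-angle vectors, fitted by EM to a library of resolved
   postures and selected by AIC, samples unlimited realistic poses —
   including coils deeper than anything in the library.
2. **Reverse skeletonization.** A renderer warps small rectangular texture
   patches from a real, tracker-labeled frame onto any target centerline,
   alpha-blends the overlaps, masks protrusions with the expected body
   outline, and composites over the real background — producing a
   realistic image of *that* worm in a posture it never assumed. These
   images, with their exactly-known centerlines, are the training data.
3. **A residual convolutional regressor** maps a standardized image to the
   100 angles. Because head and tail are often visually indistinguishable,
   training minimizes a symmetric loss,
   `min(d(θ̂, θ), d(θ̂, flip(θ)+π))` with `d` the RMS wrapped angle
   distance — the network learns *unoriented* poses.
4. **Post-processing** renders each prediction back into an image and
   scores it against the input by normalized cross-correlation (the
   *image error*, 1 − |c|ₘₐₓ; frames above 0.3 are discarded), resolves
   head-tail orientation by temporal continuity (30° adjacent-frame
   threshold, 0.2 s look-ahead) anchored to the sparse labels of classical
   tracking, then optionally spline-fills small gaps and Savitzky-Golay
   smooths the angle series.
5. **Behavior analysis** at posture scale: a two-state Gaussian HMM on
   10 s windowed centroid speed/angular speed separates roaming from
   dwelling; the eigenworm phase φ = atan2(a₂, a₁) and its velocity ω sign
   forward vs backward body waves; complete waves are counted from
   recurrences of cos φ; and the turning mode a₃ classifies Ω-turns
   (10 ≤ |a₃| < 20) and δ-turns (|a₃| ≥ 20).

Everything is testable offline: a procedural fixture module generates worm
videos with exact ground truth, so the entire pipeline — including network
training — runs and is validated without any recording. See
`docs/methods.md` for models, parameters and limitations.

The convolutional regressor and its training loop (im2col convolutions,
batch normalization, residual blocks, Adam, the symmetric loss gradient)
are implemented directly on NumPy with hand-derived backpropagation and
are fully deterministic given a seed.

## A worked example

```bash
python examples/02_shape_model.py
```

prints (abridged):

```
posture library: 3000 shapes x 100 angles
    5 components: AIC = -3,297,318  <- selected
   20 components: AIC = -3,148,054
   40 components: AIC = -2,942,878
sampled 2000 shapes; fraction coiled (|a3| > 15): 0.33
```

The AIC (2k − 2 log L) selects few components here because the procedural
library is a smooth five-mode family; real posture libraries are far more
ragged and warrant hundreds. Either way the fitted mixture generates
shapes of which a third are deep coils (turning mode |a₃| > 15) — postures
a classical tracker never labels, now available as training data.

```bash
python examples/01_render_synthetic_worms.py
```

```
self-reconstruction image error: 0.088
rendered coiled worm: image (48, 48), 185 worm pixels
```

An image error of 0.088 means the synthetic rendering of the worm's own
pose correlates with the real frame at |c| = 0.912 — renderings are nearly
indistinguishable from real frames, which is what makes them usable both
as training data and as a prediction quality score.

The other examples train a small regressor and measure eigenworm mode
errors (`03`), run the full cached pipeline on a fixture recording (`04`),
and segment roaming/dwelling states with body-wave counting (`05`).

A thin CLI wraps the pipeline for shell use:

```bash
coilpose calibrate config.yaml    # image size + error-threshold table
coilpose train config.yaml       # preprocess -> render -> train
coilpose predict config.yaml     # predict + postprocess, cached
coilpose export-wcon config.yaml out.wcon
```

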