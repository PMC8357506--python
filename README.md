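# echotrack

Speckle tracking for echocardiographic image sequences: SIFT feature
extraction, ratio-test matching with a KD-tree / Best-Bin-First search, and a
weighted iterative Lucas–Kanade refinement run coarse-to-fine over an image
pyramid, chained into a tolerance-gated point tracker.

## Why

Cardiac ultrasound cine loops are dominated by speckle — granular
interference texture that is both a nuisance (noise) and a signal (a tissue
signature that moves with the myocardium). Tracking selected points through a
loop yields wall-motion trajectories and contraction curves, but plain
window-based optical flow struggles when inter-frame motion is large and
speckle decorrelates. `echotrack` addresses this with a feature-based
pipeline:

1. **Despeckle** each frame with an m × n weighted neighbourhood-mean filter.
2. **Detect** scale-space keypoints: Gaussian scale space L(x, y, σ) =
   G(x, y, σ) ∗ I, difference-of-Gaussians D = L(kσ) − L(σ) with k = 2^(1/s),
   3-D extrema refined by the quadratic fit x̂ = −(∂²D/∂x²)⁻¹ ∂D/∂x, an
   inclusive |D(x̂)| ≥ 0.03 contrast gate, a curvature-ratio edge gate, and a
   36-bin gradient-orientation histogram per keypoint.
3. **Describe** each oriented keypoint with the rotation-normalised 4 × 4 × 8
   = 128-bin gradient histogram over a circular window of radius
   R = ⌈(3σ√2(d+1) + 1)/2⌉.
4. **Match** descriptor sets by Euclidean distance with the ratio test
   r = d_min/d̃_min < η (η = 0.44), searched either brute-force or with an
   in-package KD tree traversed Best-Bin-First.
5. **Refine** each matched displacement with weighted iterative Lucas–Kanade
   (per-pixel weights w = 1/max(|G − F|, ε)) run coarse-to-fine over a
   binomial ¼–⅛–1/16 image pyramid, so motions far beyond the linearisation
   radius of a single window remain recoverable.
6. **Gate** every per-frame displacement against a 1–20 px tolerance; a point
   whose candidate moves farther is recorded as lost with the (0, 0)
   sentinel, mirroring the standard trajectory-table convention.

Because clinical recordings are rarely shareable, the package ships a
first-class synthetic phantom generator: speckle textures with known analytic
motion (translation, rotation, periodic radial "cardiac" contraction) and
calibrated noise, so every stage can be validated against exact ground truth.

## Worked example

```python
import numpy as np
import echotrack as et

spec = et.PhantomSpec(height=128, width=128, speckle_density=0.12,
                      blur_sigma=1.5, seed=42)
seq = et.make_sequence(spec, et.Translation(velocity=(0.0, 1.0)), n_frames=20)

rng = np.random.default_rng(1)
seeds = rng.uniform(30, 90, size=(10, 2))
trajs = et.track_sequence(seq.frames, seeds, et.TrackConfig(tolerance=10.0))

survivors = [tr for tr in trajs if not tr.lost.any()]
errors = [
    np.hypot(*(tr.position(t) - seq.true_positions([seeds[tr.point_id]], t)[0]))
    for tr in survivors for t in range(len(seq))
]
print(f"tracked {len(survivors)}/10 seeds through all 20 frames")
print(f"mean |error| vs ground truth: {np.mean(errors):.4f} px")
```

prints

```
tracked 10/10 seeds through all 20 frames
mean |error| vs ground truth: 0.0008 px
```

i.e. on a noise-free phantom translating 1 px/frame, every seed point
survives the full loop and the recovered trajectories agree with the analytic
motion to well under a hundredth of a pixel.

The same pipeline is available from the shell:

```bash
echotrack simulate --out loop/ --frames 20 --motion translation --shift 0 1
echotrack detect loop/frame_0000.png --out keypoints.csv
echotrack track loop/ seeds.csv --out trajectories.csv --summary summary.json
```

`track` writes a per-point per-frame table (point_id, frame, abscissa,
ordinate, lost) in which lost frames carry the 0, 0 sentinel.

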