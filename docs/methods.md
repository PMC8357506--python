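# Methods

This note documents the models implemented in `echotrack`, the parameter
defaults and why they were chosen, what the synthetic phantoms do and do not
emulate, and the numerical decisions that were genuinely open.

## Synthetic speckle phantoms

A phantom frame is a Bernoulli field of point scatterers (per-pixel
probability `speckle_density`, amplitudes uniform in [0.5, 1]) convolved with
an isotropic Gaussian point-spread function of width `blur_sigma` pixels.
Intensity is standardised by the 99.9th percentile and clipped to [0, 1]; a
peak-based normalisation was rejected because a single bright scatterer
cluster then compresses the contrast of the entire frame and makes the
keypoint yield unstable across seeds. Defaults (128 × 128, density 0.08,
blur 1.5) give speckle grains a few pixels across, comparable to the scale
the detector's base smoothing (σ₀ = 1.6) expects.

Motion models are analytic and therefore carry exact ground truth:

* **Translation** — constant (d_row, d_col) per frame.
* **Rotation** — rigid rotation about a centre; angles measured from the
  +col axis toward +row, the same convention as gradient orientations.
* **PeriodicRadial** — a pure radial scaling toward the centre with inward
  displacement s(t) = A·sin²(πt/T) at the reference radius: zero at
  end-diastole (t = 0, T), peak systolic contraction at T/2, period exactly
  T. The scaling form keeps the deformation invertible and linear in radius.

Dense fields are stored as cumulative (2, H, W) pull-back offsets:
`warp_frame` computes output(x) = input(x − d(x)), so warping frame 0 by the
stored field reproduces frame t exactly (asserted to 1e-12 in the noise-free
tests). Forward point motion is exposed separately (`transform_points`) for
trajectory ground truth. Warping is bilinear by default (matching the
subpixel resolution the tracker is evaluated at, with edge replication
outside the frame); a bicubic option exists because bilinear resampling
low-pass filters a rotated copy and that attenuation — an artefact of the
resampling, not of the detector — measurably deletes near-threshold
keypoints in repeatability experiments.

Noise models: additive Gaussian (std = level), salt-and-pepper (corrupted
fraction = level, half salt half pepper), multiplicative speckle
(frame·(1 + level·N(0,1))); all clipped to [0, 1] and driven by
`numpy.random.SeedSequence` children of the phantom seed, so sequences are
bit-reproducible.

What the phantoms do **not** emulate: anisotropic ultrasound point-spread,
log compression, attenuation/shadowing, out-of-plane decorrelation, and
tissue-dependent texture. Passing tests therefore demonstrate algorithmic
correctness under controlled conditions, not clinical performance.

## Despeckling

The mean filter is plain weighted neighbourhood averaging with the mask
normalised to unit sum; default 3 × 3 uniform. Borders are edge-replicated
so output size equals input size. Non-uniform masks are accepted through
`MeanFilterSpec.weights`. The filter is deliberately linear — median and
adaptive Wiener filtering are out of scope.

## Scale-space detector

Canonical settings: σ₀ = 1.6, s = 3 scales per octave (k = 2^(1/3)), s + 3
Gaussian layers per octave so that s DoG layers are searchable, octaves
seeded by 2× decimation of the layer at 2σ₀, octave count automatic from
image size (down to 16 px). The input is assumed to carry a 0.5 px blur and
is not pre-doubled (no −1 octave).

Smoothing uses Lindeberg's discrete Gaussian kernel T(n; σ²) = e^(−σ²)Iₙ(σ²)
with half-sample mirrored borders rather than a sampled continuous Gaussian.
Two reasons: the discrete Gaussian satisfies the semigroup property exactly
under discrete convolution, and mirror extension is preserved by symmetric
convolution — together these make incremental octave construction agree with
direct smoothing at the quadrature scale to ~1e-8 RMS everywhere including
borders, where sampled kernels leave ~3e-3 discrepancies on
high-bandwidth input. The closed-form bivariate Gaussian is still exposed as
`gaussian_kernel_2d`.

Extrema are strict 26-neighbourhood max/min of the DoG stack, excluding the
first/last DoG layer and 1-px borders, pre-filtered at half the contrast
threshold (any weaker response cannot pass the refined gate). Refinement
solves x̂ = −H⁻¹g with central finite differences, re-centring onto the
neighbouring grid point when any |x̂| component exceeds 0.5, at most 5 times;
singular Hessians and non-convergent points are rejected with a reason. The
contrast gate is the inclusive |D(x̂)| ≥ 0.03; the absolute value is the
default because DoG minima (dark blobs) are equally valid speckle features,
and a `signed_contrast` switch restores the one-sided reading. Edge-like
points are rejected with the curvature-ratio test on the 2 × 2 spatial
Hessian, keep iff tr² / det < (r+1)²/r with r = 10 (strict inequality; the
boundary case is discarded). Orientation is the peak of a 36-bin
magnitude-weighted gradient-direction histogram over a Gaussian-weighted
circular window of radius 3·1.5σ, with parabolic three-bin peak refinement
and one extra keypoint per secondary peak ≥ 80 % of the maximum. The
orientation angle convention puts the row difference in the atan2 numerator
(configurable), which with (row, col) indexing equals the angle of the
gradient vector from +col toward +row.

## Descriptor

4 × 4 spatial subregions × 8 orientation bins = 128 values. Gradients are
sampled in the keypoint's own Gaussian layer inside a circular window of
radius R = ⌈(3σ√2(d+1)+1)/2⌉, offsets rotated by −θ, accumulated with
trilinear interpolation, weighted by a spatial Gaussian of σ = half the
window width (subregion width 3σ). Entries are clamped at 0.2 and the vector
renormalised — a standard illumination-robustness step that is switchable
off (`clamp_value=None`) for the literal unclamped pipeline.
Normalisation is Euclidean by default because Euclidean matching presumes
unit-norm comparability; unit-sum normalisation is available as `sum`.
Keypoints whose window exits the image are skipped rather than padded, to
avoid fabricated gradients.

## Matching

Each descriptor in A is matched against its two nearest neighbours in B and
accepted iff r = d_min/d̃_min < η with η = 0.44; the d_min = d̃_min = 0
duplicate case is reported as a failure. Many-to-one collisions on B are
resolved in favour of the smaller d_min (ties: lower index), switchable off
for strictly one-directional matching. Ties in distance break toward the
lower keypoint id, for determinism.

The KD tree splits on the highest-variance dimension at the median, giving
depth ≤ ⌈log₂ n⌉ + 1; leaves hold buckets of up to 8 descriptors, the
standard operating point for high-dimensional descriptor search (distance
evaluation vectorises over a bucket, and tiny leaves waste backtracking
budget). Best-Bin-First traversal pops cells from a priority queue keyed by
a tight lower-bound distance maintained per dimension, counts one "check"
per leaf bucket examined, and stops at `bbf_max_checks` (default 200) or
when the best remaining bound exceeds the current second-best distance — at
which point the result is provably exact, which is why exhaustive BBF
reproduces brute force identically. In the genuinely approximate regime
(~1000 stored descriptors, 50 checks) nearest-neighbour agreement with brute
force measures ≈ 96 % on phantom descriptor sets.

## Weighted pyramid Lucas–Kanade

The displacement b of a point from template frame F to moving frame G
minimises the weighted SSD of G(x + b) − F(x) over a (2S+1)² window
(S = 7 by default). Each iteration solves the weighted normal equations
(Σ w g gᵀ)Δ = Σ w (F − G(x+b)) g with g = ∇G sampled bilinearly at the
warped positions, and per-pixel weights w = 1/max(|G(x+b) − F(x)|, ε),
ε = 1e-3 — the residual-reciprocal weighting that de-emphasises decorrelated
speckle, recomputed each iteration from the current residual. The system is
solved by least squares (`lstsq`) so one-dimensional texture (e.g. a ramp)
yields the minimal-norm solution instead of a singular failure; an
all-zero-gradient window returns immediately flagged non-converged.
Iteration stops when |Δ| < 0.01 px or after 20 iterations.

The 1-D update formula this generalises divides by F′; the least-squares
formulation is the standard dimensional lift and sidesteps the undefined
F′ ≈ 0 case. The sign convention is that b maps F coordinates to G
coordinates (a feature at p in F appears at p + b in G), which is what makes
a +0.3 px content shift come back as b = +0.3.

The pyramid uses the 3 × 3 binomial stencil — ¼ centre, ⅛ edge neighbours,
1/16 diagonals (the unique normalisation of those weights) — followed by 2×
decimation. Estimation starts at the coarsest level (3 by default) from
b₀/2^(L−1) and doubles the estimate between levels. An even-coordinate
impulse maps to a single ¼ tap at the next level (the ⅛ and 1/16 taps are
reached only from odd coordinates, by parity). On default phantoms an 8 px
translation is recovered to < 0.01 px with 3 levels while a single level
with the same window fails by > 5 px — the pyramid's purpose in one number.

## Tracking pipeline

Per consecutive frame pair: denoise (3 × 3 mean filter), detect + describe,
match with the ratio test; each tracked point takes the accepted match
nearest its current position (ties: smaller ratio), and the implied
displacement initialises a pyramid-LK polish when `refine_with_lk` is on.
The tolerance gate accepts a per-frame Euclidean displacement ≤ `tolerance`
(inclusive; valid range 1–20 px, default 10); a rejected or out-of-frame
candidate records the (0, 0) sentinel with the lost flag. Lost points retain
their last known position internally and, with `reacquire` (default on), may
resume when a plausible match reappears nearby; with it off a lost point
stays lost. Features are recomputed per frame pair — no descriptor caching
across the sequence.

`contraction_curve` summarises a tracked loop as the per-frame mean distance
of surviving points from a reference (explicit point, or the per-frame
centroid of survivors), normalised to frame 0; frames with no survivors are
NaN, and a zero frame-0 distance leaves the series unnormalised. On a
periodic radial phantom the curve's minimum lands at the mid-cycle
contraction peak.

## Study conditions and problem sizes

The test suite and acceptance script measure at these fixed conditions:
detector repeatability on a 256 × 256 noise-free phantom (density 0.08, blur
1.5) under a 30° bicubic-resampled rotation, interior margin 20 px, success
radius 2 px; matching precision on 192 × 192 phantoms (density 0.12, blur
1.2) under a 10° rotation; order/reverse symmetry over 20 seeded 192 × 192
pairs with 0.02 additive Gaussian noise and (0.7, 0.4) px/frame translation;
BBF agreement with 200 stored / 100 query descriptors from a warped noisy
pair at 50 checks; tracking on a 128 × 128 phantom translating 1 px/frame
for 20 frames with 10 random seeds, plus a 25 px jump sequence for the lost
sentinel. These sizes keep the full suite under half a minute while leaving
hundreds of keypoints per experiment.

## Known limitations

* The detector is tuned for blob-like speckle; elongated anatomical edges
  are (by design) rejected by the curvature-ratio gate.
* The residual-reciprocal LK weighting is bounded by ε but still up-weights
  already-converged pixels ~1000 : 1; on pathological windows this can slow
  convergence relative to uniform weighting.
* Tracking associates each point with the single nearest accepted match;
  in regions with repetitive texture and sparse features, a mismatch within
  the tolerance radius is not detected.
* No geometric verification (e.g. RANSAC) is applied after the ratio test.
* Phantom realism limits are listed above; no claims are made about clinical
  recordings.
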