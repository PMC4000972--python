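# Methods

`gaborgist` classifies short bedside video clips of epileptic patients as
**normal** (awake, comfortable movement) or **abnormal** (seizure-related
movement: abrupt direction changes interleaved with periods of no movement).
The pipeline is deliberately simple and fully deterministic given its seeds:

1. grayscale intensity volume `V(y, x, t)` at 128 x 160 px, 25 fps, clips
   no longer than one minute;
2. a bank of four 3D Gabor filters (one scale, four orientations);
3. a 256-dimensional *gist* descriptor: signed average pooling of each
   filter response over a 4 x 4 x 4 spatiotemporal grid;
4. a soft-margin SVM trained on z-scored descriptors, with the
   regularization constant C chosen by stratified cross-validation;
5. evaluation by a repeated per-patient half-split protocol.

Because the clinical recordings behind this design are private, the package
ships a synthetic surrogate-video generator whose motion statistics realize
the clinical description above, so every stage is testable end to end.

## 3D Gabor filtering

A filter is a Gaussian envelope times two cosine carriers,

    G(x, y, t) = exp(-(X²/2σx² + Y²/2σy² + T²/2σt²)) · cos(2πX/λx) · cos(2πY/λy),

where `(X, Y, T)` rotate `(x, y, t)` by the spatial orientation θ (y–t
plane) followed by the temporal orientation ω (x–t plane).  The four default
orientation pairs are (θ, ω) ∈ {(0,0), (π/2,0), (0,π/2), (π/2,π/2)}: the
pure spatial pair and its two temporally tilted variants.  An alternative
envelope convention in which the printed denominators `2σ` are taken
literally (σ carrying units of squared length) is available via
`sigma_as_variance=True`; the default treats σ as a standard deviation.

Sampled kernels are mean-subtracted and L2-normalized.  Zero mean makes
every filter exactly DC-free, which is the operational form of robustness
to illumination changes: a constant intensity offset (ward lights on/off)
changes no response and hence no descriptor entry.  Volumes are extended
**symmetrically** at their borders before correlation.  This choice is
load-bearing: with zero padding, the background level leaks into border
responses through the implicit step to zero, which both violates offset
invariance at the edges and injects a large patient-specific nuisance
component into the descriptor.  With symmetric extension, a constant volume
maps to an identically zero response everywhere, to machine precision.

Filtering is same-size cross-correlation computed by FFT (exact to ~1e-12;
verified against a triple-loop direct sum at 1e-10), with the padded
volume's forward transform shared across the bank.  Long clips can be
filtered in temporal chunks with a `2·ht`-frame overlap; the stitched
output equals the unchunked one exactly.

### Choosing the single scale

The descriptor pools **signed means**, not energies.  This has a sharp
consequence: over a pooling block of extent `B`, a carrier of wavelength
λ ≪ B averages to nearly zero, so a fine-scale bank produces a descriptor
that is almost blind to where and when motion occurred.  At the working
resolution the spatial blocks are 32 x 40 px, so the bank's one scale is
set to match: **λx = λy = 32 px**, bandwidth σx = σy = λ/4 = 8 px, σt = 3
frames, support half-extents (16, 16, 6) ≈ 2σ (envelope tail mass < 2%).
Matching the carrier to the block also gives the descriptor its shift
tolerance — a 1-px translation changes the descriptor by ~4% of its norm
(the carrier phase advances by 2π/λ per pixel) — whereas a λ = 8 px bank
changes by ~40% under the same shift and scores at chance end to end.
Practitioners working at other resolutions should scale λ with the pooling
block, keeping σ = λ/4.

## Gist descriptor

Each response volume is partitioned into 4 x 4 x 4 blocks with bin edges at
`floor(i·d/4)` (exhaustive, non-overlapping, deterministic for dimensions
not divisible by four); each block contributes its arithmetic mean.  The
feature layout is kernel-major, blocks in (row, column, time) lexicographic
order: 4 kernels x 64 cells = 256 values.  Pooling is linear, and no
per-feature standardization happens at extraction time — z-scoring lives in
the evaluation stage so that test clips never influence the scaling.

## Soft-margin SVM

The classifier solves the Wolfe dual of the soft-margin problem

    max_α  Σᵢ αᵢ − ½ Σᵢⱼ αᵢαⱼ yᵢyⱼ K(xᵢ, xⱼ)   s.t.  0 ≤ αᵢ ≤ C,  Σᵢ αᵢyᵢ = 0,

with linear, polynomial `(x·x' + c)^d`, or Gaussian RBF
`exp(−‖x−x'‖²/2σ²)` kernels.  The solver is sequential minimal
optimization with maximal-violating-pair working-set selection and
stopping tolerance 1e-6 — deterministic for fixed input.  The bias is the
mean over unbounded support vectors (0 < α < C) of `yᵢ − Σⱼ αⱼyⱼK(xⱼ,xᵢ)`,
falling back to the KKT-interval midpoint when none are free.  Predictions
are `sgn(f(x))` with the tie `f = 0` mapped to +1 so that behaviour is
defined everywhere.  C defaults to a grid {0.01, 0.1, 1, 10, 100} searched
by stratified 5-fold cross-validation on the training half, ties broken
toward the smaller (more regularized) value.

Test coverage treats the solver with suspicion: on random small instances
the dual objective is compared at 1e-6 against an independent SLSQP
solution of the same QP, predictions must agree exactly, and KKT residuals
are checked at 1e-4 for all three kernel families.

## Evaluation protocol

For each repeat `r` (5 by default) with seed `base_seed + r`: independently
for every patient, a seeded permutation sends ceil(n/2) of that patient's
clips to training and the rest to testing; scaling statistics and C come
from the training half only; clip-level accuracy is recorded on the test
half.  The report carries per-repeat accuracies, their arithmetic mean,
the seeds and a config hash, and serializes to canonical JSON so identical
inputs give bitwise-identical reports.  An optional strict mode
(`group_by_recording`) keeps sibling clips segmented from one recording on
one side of the split; the default mirrors clip-level splitting.

## Synthetic surrogate videos

The generator renders a bright Gaussian-profile blob (σ = radius/2, default
radius 8 px — the moving body part) over a darker background, with optional
slow sinusoidal illumination drift, per-pixel Gaussian noise (default sd
0.01), independently moving distractor blobs (other people in the ward),
and per-patient appearance variation (background level ±30%, blob
brightness and size ±15% — clothing and lighting differences).

Motion is anchored at a resting position near the frame centre (the camera
is mounted above the bed), scattered by 4% of the frame per clip:

* **normal** — the blob circulates on an ellipse spanning roughly half the
  frame at constant speed (default 2.5 px/frame) with small capped
  heading-rate jitter.  Per-frame heading changes stay below the 0.35 rad
  cap; the trajectory sweeps a broad, stable annulus.
* **abnormal** — the same path model, but with probability `jerk_rate/100`
  per moving frame the direction of travel reverses instantaneously (a
  heading jump of ≈180° ≥ 90°), and each reversal dissipates the excursion
  amplitude by a factor 0.75 down to a 5-px floor; with probability
  `freeze_prob` per frame the blob freezes for `freeze_len_frames`.
  Defaults: 12 reversals per 100 frames, freeze probability 0.05, freeze
  length 25 frames.  The movement collapses onto small oscillations about
  the resting position, punctuated by stillness.

With `jerk_rate = 0` and `freeze_prob = 0` the abnormal model degenerates
to the normal one bitwise (same seed), which pins the classes' difference
entirely on the two abnormality mechanisms.  Every clip ships a per-frame
trajectory log (position, heading, jerk/freeze/clamp flags) used by the
tests as ground truth for the motion statistics.

### Why this motion contrast, and what it does not show

The filter-plus-mean-pool descriptor is *linear* in the video, so a linear
SVM on it can only separate classes whose class-conditional mean videos
differ.  Free random-walk motion from uniformly random start positions
gives both classes identical mean occupancy and is provably inseparable by
this pipeline, no matter how violently the walk jerks.  The surrogate
classes therefore differ in their *mean occupancy geometry* — a broad
annulus for smooth motion versus a central spot plus stillness for
convulsive motion — which is the face-valid video-level signature of
"moves comfortably around the bed" versus "convulses in place".  Passing
tests show that the pipeline detects this geometry reliably under noise,
illumination drift and per-patient appearance changes.  They do **not**
show that real seizure semiology is captured: real recordings contain
articulated bodies, occlusions, carers entering the frame, camera gain
changes and far richer motion; clinical accuracy on such data cannot be
inferred from the surrogate results and should be expected to be much
lower than the surrogate numbers.

## Problem sizes and numerical choices

The study-scale experiment uses 9 patients x 6 clips x 250 frames at
128 x 160 — a 54-clip cohort balanced within patients — and 5 half-split
repeats; feature extraction dominates the cost (~3 s per clip via shared
FFT).  Examples use 4-patient cohorts.  Tolerances: kernel zero-mean
1e-10 x tap count, unit norm 1e-10; FFT-vs-direct correlation 1e-10;
illumination invariance 1e-8; SMO tolerance 1e-6; dual-vs-oracle 1e-6;
KKT residuals 1e-4.  Degenerate cases are defined, not silently handled:
single-class training sets, single-clip patients, undecodable inputs,
boxes outside the frame and volumes smaller than a kernel's support all
raise errors naming the offending quantity.

## Known limitations

* Blob-world surrogates only; no articulated or multi-part motion.
* The descriptor's signed pooling discards motion energy; classes that
  differ only in energy (e.g. fast vs slow shaking at the same location)
  are invisible to it by design.
* One scale and four orientations, as in the original scheme; no
  multi-scale pyramid, no quadrature (sine-phase) pairs.
* Compressed video containers require an imageio decoder backend at
  runtime; the frame-directory path (PNG/TIFF) is the fully supported one.
* The binary protocol assumes each clip is wholly normal or wholly
  abnormal; no within-clip onset localization.
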