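# Methods

`patchreg` corrects motion and slow non-uniform distortion in two-photon
calcium imaging movies in two steps — per-frame rigid translation, then
patchwise affine warping — and aligns whole sessions onto each other with a
third, fully automated procedure. This note describes the models, the
numerical choices, and what the synthetic test bed does and does not show.

## Model of the data

A movie is a stack of H × W fluorescence frames (typically 512 × 512 at
~29 Hz). Two disturbance regimes are assumed:

- **Fast motion** (~100 ms): body movements of the head-fixed animal shift
  the whole frame rigidly. At frame rates above ~10 Hz these are, to a good
  approximation, pure translations.
- **Slow distortion** (minutes to hours): tissue relaxation, thermal drift
  and optical changes deform the field of view non-uniformly, but smoothly
  in both space and time. No single affine transform describes the
  deformation, but an affine per local patch does.

A third regime — fast *non-rigid* deformation, e.g. midline-sinus dilation
during vigorous movement — is explicitly outside the model: the warp
correction estimates one transform per ~17 s of data and cannot track it.
Single-channel data is assumed; negative-valued (signed-integer) pixels from
PMT offset subtraction are preserved, since every matching step below is
invariant to intensity shifts.

## Rigid step

Each frame is aligned to a template by the integer translation maximizing
Pearson correlation, searched greedily over the 8-neighborhood on a 4-level
image pyramid (scales 1/8, 1/4, 1/2, 1; 2×2 block averaging), coarse to
fine, with the coarser level's doubled shift as initialization. A final
per-axis parabola through the correlation at the optimum and its ±1
neighbors gives subpixel precision (offset clamped to (−1, 1); a
non-concave triple falls back to 0). Frames and templates are rank
transformed first (ties → average rank), so the estimate is invariant to
any monotone intensity remapping — calcium transients, bleaching, gain
drift. Candidate shifts whose overlap with the template falls below 25% of
the frame are rejected; ties are broken toward the smaller shift
(then smaller dy, then dx) for determinism.

Because the FOV distorts slowly, one template cannot serve a whole session.
The session is split into 5 equal temporal blocks (remainder to the last)
and templates are re-estimated bidirectionally from the middle: the mean of
the middle 2500 frames bootstraps a first template, which is refined by
registering those frames and re-averaging; block 3 is corrected with it;
the first/last 2500 corrected frames of block 3 give the templates for
blocks 2 and 4; the outer 2500-frame edges of blocks 2 and 4 give the
templates for blocks 1 and 5. Every template is therefore built from
already-corrected, temporally adjacent frames.

The estimated shift sequence is defined only *relative to the template*:
the template itself sits at the mean position of its source frames, so
recovered shifts carry one global offset. All ground-truth comparisons in
the tests remove this gauge before computing errors.

## Local intensity normalization

Before any affine estimation, images are normalized by their local
background: the image is convolved (zero-padded) with a binary disk of
radius 32 px, divided by the same convolution of an all-ones image (exact
edge compensation — the compensated blur of a constant image is that
constant everywhere), and the original image is divided by this local mean
and rescaled by the global mean. The transform flattens smooth intensity
structure (vignetting, widespread activity, slow drift) while preserving
local contrast, and is homogeneous of degree 1, so global gain passes
through to the gain-invariant matching objective. Pixels whose local mean
is below 1e-12 × global mean (all-dark borders of GRIN-lens fields) are set
to 0 and counted in a warning rather than dividing by ~0.

What it does *not* suppress is the transient of a single small cell: a
soma's footprint is a small fraction of the radius-32 disk, so its local
mean barely moves. Suppression of transient-driven mismatch comes jointly
from this normalization (for area-wide changes), from temporal averaging
(500-frame blocks), and from the ECC objective's gain/bias invariance.

## ECC maximization

The matching objective is the enhanced correlation coefficient: the
normalized inner product of the zero-centered template and warped-image
pixel vectors, restricted to the in-bounds support. It equals
1 − L/2 for the squared distance L between the unit-normalized vectors, and
is exactly invariant to gain and bias of either image.

Maximization is a forward-additive Gauss–Newton iteration: warp the moving
image and its spatial gradients with the current parameters (6 affine or 3
Euclidean — the Euclidean model is parametrized directly by (θ, e1, e2) so
its structure is exact), build the Jacobian of pixel values w.r.t.
parameters on the support, solve the ECC normal equations, and re-evaluate.
Numerical choices:

- gradients are central differences of the σ = 1 px Gaussian-smoothed
  image, stabilizing the step on shot-noise-limited data;
- a full step that lowers the score is halved up to 4 times
  (backtracking); if no improving step exists the best iterate is kept —
  this is what makes the iteration stable near the optimum, where the full
  Gauss–Newton step otherwise oscillates;
- stopping: Δρ < 1e-6, update norm < 1e-8, or 50 iterations;
- **failure criterion** (the method itself only prescribes the fallback,
  keeping the patch as is): a fit is rejected unless the final score
  reaches 0.3, the linear-part determinant lies in [0.2, 5], and the
  support covers at least 25% of the template. The support fraction guard
  matters: without it, a transform that pushes all but a sliver of the
  image out of bounds can score arbitrarily well on the sliver.

For large displacements (across-session alignment), the fit runs coarse to
fine over a 4-level pyramid (Gaussian-filtered before each halving),
doubling translations between levels; at the coarsest level a small
multi-start sweep over translation (and rotation) initializations guards
against the narrow basin of fine-textured images, at negligible cost since
the coarsest image is 1/64 of the original area.

All transforms act as *inverse maps* (output pixel → input sampling
coordinate, bilinear), so an estimated transform is directly the one that
resamples the moving image onto the template. Warped-pixel support masks
exclude out-of-bounds samples from every score.

## Warp step

The FOV is tiled into M × M patches (M = 8 at cellular resolution, 12–15
for axons, where neighboring structures move more independently). Nominal
tiles of ⌈H/M⌉ px are extended by round(0.3·H/M) px on every interior edge
(19 px for 512/8), so adjacent patches overlap; after warping, overlaps are
averaged (a feathered blend exists behind a flag, off by default, since
plain averaging is the method's stated rule). Pixels no patch can supply
retain their input value.

Estimation is temporally downsampled: non-overlapping 500-frame block means
(a trailing remainder shorter than half a block merges into the previous
one — a warp from very few frames is noise; frames of a merged remainder
reuse that block's transforms), each locally normalized, each patch fit by
ECC against the same fixed template — the locally normalized mean of the
middle 5500 frames of the rigid-corrected session (clipped to the session
when shorter). Every block's fit starts from identity rather than chaining
from the previous block, so errors cannot accumulate across a session.
Patch transforms are expressed in patch-local coordinates (origin at the
patch's upper-left), which keeps the 6 parameters well-scaled for the
gradient step; the serialization (HDF5) stores them in this convention
together with the grid geometry.

## Across-session registration

Given mean and max projections of a reference session G and a moving
session H (all four locally normalized): (1) a pyramid Euclidean ECC fit on
the mean pair and on the max pair; the transform with the larger full-FOV
score wins and is applied to *both* moving summaries — mixing per-summary
transforms at this stage is deliberately not allowed; (2) per patch of an
M × M grid (M = 8 by default, independent of the within-session M —
across-session distortion is smoother), an affine ECC fit on both summary
pairs, no pyramid (step 1 already removed the large displacement), keeping
per patch whichever summary scores higher; a patch failing on both keeps
identity. The result is M² + 1 transforms plus a per-stage selection
record. The per-patch mean/max selection is what makes the procedure
robust when neurons are visible in only one summary statistic — or only in
one session.

Transported label masks (ROI images) use nearest-neighbor sampling with a
per-pixel majority vote over overlapping patches, so masks remain
label-valued; continuous images use bilinear sampling with overlap
averaging.

## Quality metrics

- **mMD**: both conditions are 50-frame block-averaged (suppressing the
  noise contribution to maxima), max-projected, and the pixel means of the
  two projections subtracted (post − pre). Motion spreads bright structure
  over more pixels of a max projection, so negative means improvement.
- **mCM**: the mean over frames of the Pearson correlation between each
  frame and a mean image — the stack's own mean (*self*) or the compared
  condition's (*cross*). Computed on every raw frame by default (a stride
  option exists for speed, off by default); metrics cover the full FOV,
  since edge replication keeps borders valid.

## Synthetic test bed

The generator renders what the model assumes, with known ground truth:
somata as Gaussian blobs (radius 3–6 px, stratified jittered-grid placement
so every patch holds landmarks) on a dim background, each with a constant
baseline plus Poisson-timed transients (instantaneous rise, exponential
decay, τ = 15 frames — simplified GCaMP-like kinetics; exact kinetics are
irrelevant to registration); an axon mode draws curvilinear segments
instead. Jitter is a reflected random walk (σ = 1 px per frame by default,
bounded at ±8 px). Noise is Poisson shot noise plus additive Gaussian read
noise (σ = 3).

Slow distortion is a *single global quadratic displacement field*, ramped
linearly from zero to its endpoint over the session and scaled so the
largest local rotation, shear/scale and translation stay within the stated
bounds (defaults 3°, 0.03, 3 px). Each patch's ground-truth affine is the
field's first-order Taylor expansion at the patch center, and the movie is
rendered through the *same* warp-and-stitch operator the correction uses.
The field is smooth on purpose: independent per-patch affines would place
displacement discontinuities at patch seams, which real tissue never shows
and which the overlap averaging would render as ghost structures; with a
smooth field, adjacent patches disagree in their overlaps only by the
field's curvature (hundredths of a pixel at these magnitudes). By default
the field's net translation is removed, keeping the slow distortion
orthogonal to the jitter the rigid step estimates.

Session pairs for across-session tests share a cell layout but have
independent transients and noise; the moving session's summaries are
additionally displaced by a rotation about the FOV center plus translation,
then barrel-distorted (r′ = r(1 + k·r²) about the center; the default
k = 1e-7 at 512 px puts ~4.7 px at the corners), with 10% of cells silenced
in one session.

What passing these tests does **not** show about real data: performance
under fast non-rigid deformation (outside the model), under occlusions or
z-drift (structure appearing/disappearing within a session), with
structured noise (line noise, flyback artifacts), or at landmark densities
far below the generator's. The generator's blobs are also static in shape;
real somata change morphology over weeks, which the across-session step
tolerates only through its per-patch robustness.

## Validation scales

End-to-end validation runs on 2000-frame 256 × 256 sessions (both M = 4 and
M = 8 grids) for the within-session pipeline and 512 × 512 summary pairs
for the across-session step — large enough that every stage operates in its
standard regime (4 estimation blocks of 500 frames, templates clipped to the
session) while a full run stays in the minutes range on one CPU core.
Ground-truth comparisons use corner displacement: the mean distance between
a patch's corners mapped through the recovered vs. the expected transform,
the expected one being the relative distortion between the block epoch and
the template epoch, composed with the rigid step's measured residual
translations.

## Known limitations

- Slow distortion only: transforms are constant within 500-frame blocks.
- Translation-only rigid step: no within-frame (line-by-line) correction.
- Affine per patch: curvature within a patch is unmodeled; increase M if
  the residual field is visibly non-affine at patch scale.
- The ECC failure criterion (score floor 0.3, determinant and support
  guards) is a configurable heuristic; pathological contrast can pass it.
- Identity fallbacks on landmark-free patches leave those patches
  uncorrected by design.
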