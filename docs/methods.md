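# Methods

This note documents the models implemented in `tracemap`, the parameters
that matter, the synthetic phantom that stands in for real histology, and
the numerical and design choices made where more than one reasonable
option existed.

## Coordinate conventions

Template world axes are (ML, AP, DV) — medio-lateral, antero-posterior,
dorso-ventral — in millimetres, matching the stereotaxic frame of the
reference atlas; AP values are stored with the signs the atlas prints
(rostral injections in the packaged reference table carry negative AP).
Voxel indices are 0-based; world coordinates sit at voxel centers,
`world = origin + index * spacing`. Every transform stored in a
`TransformChain` is a **forward point map** (raw section coordinates →
template mm). Registration algorithms naturally produce the opposite
(resampling) convention; affines are inverted analytically and
displacement fields with fixed-point iteration (tolerance 0.01 voxel,
max 50 iterations; the tolerance is enforced at grid nodes — off-grid
points add linear-interpolation error of the same order) before being
persisted. A chain round-trips through JSON bit-for-bit because Python
serializes doubles losslessly.

A 2D section point lifts to 3D on its *nominal* plane,
`AP = ap_origin + index * section_spacing`; cutting-angle obliquity is
absorbed entirely by the stack-to-template affine rather than modeled
per section.

## Affine reconstruction

The loop alternates (i) 3D affine registration of the reference onto the
current stack volume and (ii) per-section 2D rigid registration against
the virtual reference (the mapped reference resliced at the section's
plane). Both use Mattes-style mutual information via SimpleITK
(multi-resolution, regular-step gradient descent, fixed sampling seed so
reruns are deterministic). Defaults: up to 10 outer iterations — the
middle of the 8–12 range practical for real material — stopping early
when the mean per-section MI improves by under 2e-3 bits, since no
sharper convergence criterion is standard for this loop; a drop of more
than 10% between iterations aborts as divergence. A candidate 2D pose is
accepted only if its MI (evaluated with the package's own histogram MI)
is at least that of the incoming pose, so a section can never be made
worse by one more iteration; near-constant (empty) sections are skipped.

## Deformable reconstruction

Each section is warped toward the unweighted mean of its neighbors
within radius 1 (edge sections use the neighbors that exist); one sweep
over the stack is one iteration, 8 by default. The warp model is an
additive demons update — force `(target − I)∇I / (|∇I|² + (target − I)²)`
capped at 0.4 voxel per step, fluid-smoothed at σ = 1 voxel, composed
into the running field, which is then elastically smoothed at σ = 2
voxels. This Gaussian-regularized demons substitutes for a symmetric
diffeomorphic optimizer: the contract used downstream is the warp's
effect (between-section smoothness with bounded, invertible fields), not
the specific machinery. Between-section mean squared difference is
tracked every iteration; an update that would increase it is rolled back
and the loop stops, so the history is non-increasing by construction.
Fields whose displacement-gradient magnitude reaches 1 are re-smoothed
(invertibility guard).

Neighbor-average warping can, in principle, drag anatomy along the stack
axis where structure trends monotonically; at the default distortion
amplitudes this bias is below the working voxel and the later 3D
deformable stage corrects what remains.

## Template coregistration

Volumes are resampled to an isotropic working resolution and
median-filtered once with a 1-voxel radius; labels are resampled
nearest-neighbor and never filtered. The paper-scale default working
resolution is 0.075 mm; phantom runs use the phantom's native 0.25 mm
grid, which keeps a full run under a minute without changing the method.
After a 12-parameter MI affine, the deformable stage maximizes a
windowed cross-correlation (CC; window radius 2 working voxels by
default, configurable up to the 5-voxel kernel appropriate at finer
grids) combined at equal weight with a landmark term, under the same
fluid/elastic Gaussian regularization as above, at three resolution
levels (shrink 4/2/1, 40/25/12 iterations).

The CC force is the variational gradient of the local correlation: with
window-demeaned images A (warped moving) and B (fixed),
`(2 s_AB / (s_AA s_BB)) (B − (s_AB / s_AA) A) ∇A`.

**Landmarks.** Corresponding tissue sectors, supplied as label volumes
on both sides, are converted to point sets (all labeled voxel centers,
deterministically strided to at most 2000 per label). The landmark
metric is a symmetric nearest-neighbor expectation (PSE): per label, the
mean distance from each point to its nearest same-label point on the
other side, averaged over both directions and over labels. The exact
published form of this metric is unpublished detail; this symmetric
variant is a pseudo-metric (symmetric, non-negative, zero on identical
sets) and is what the package both optimizes and reports. During
registration the landmark force pulls each warped moving landmark voxel
toward its nearest fixed counterpart — but only when the offset exceeds
one voxel: sub-voxel offsets between voxelized point sets are lattice
noise, and nearest-neighbor matching of thin overlapping sets otherwise
produces spurious tangential sliding that measurably degrades nearby
tissue. For the combined objective the PSE value is reported alongside
CC in the per-iteration log (JSON lines when a log path is configured);
in the update itself each force is normalized to voxel scale before the
equal weighting, which serves as the unit normalization between an
intensity metric and a distance metric.

Final landmark alignment is evaluated by warping the moving landmark
volume through the recovered forward field and computing PSE between the
two voxelized sets — the same floor for both sides, so the value is
directly comparable with the affine-only (unwarped) one. With landmarks
enabled this final PSE is never above the landmark-disabled or
affine-only values in the paired-seed comparisons the test suite runs;
in regimes where both runs already sit at the lattice floor the two are
equal up to that floor.

## Cortical depth

The Laplace potential φ is solved on cortex voxels of the parcellation
with 6-neighbor finite differences (axis weights 1/h² for anisotropic
grids): Dirichlet φ=0 on background-adjacent (pial) neighbors, φ=1 on
white-matter-adjacent neighbors, reflecting (no-flux) at the
field-of-view boundary — the template brain never touches it, and
reflection makes truncated test slabs behave as if infinite. The SPD
system is relaxed by conjugate gradients to a relative residual below
1e-4 (verified after the solve; failure raises). Streamlines start at
every cortex voxel center and integrate the normalized gradient of the
extended potential with a midpoint (RK2) scheme at 0.25-voxel steps,
down to the pial surface and up to the white matter; at the exit step a
single bisection refines the crossing to a quarter-step, bounding the
per-direction quantization error at ~1.5% of a typical 1.5 mm cortex.
Thickness is the summed length, normalized depth the pial fraction, and
voxels whose normalized depth passes 0.5 within half a voxel form the
mid-thickness set. Voxels with vanishing gradient (possible at sharp
label corners) fall back to φ itself as normalized depth and are
counted and logged.

Mapped points take their depth from the nearest cortex voxel. Points
outside the brain get normalized depth 0, points in subjacent white
matter get 1; the nominal (mm) depth is clamped correspondingly to 0 and
to the local thickness — the published convention specifies the clamp
only for normalized depth, and clamping both keeps the two fields
consistent.

**Area assignment.** A point inside a cortical label keeps it; otherwise
it takes the label of the nearest cortical voxel center (Euclidean, mm),
ties broken toward the smaller label id for determinism. The fallback
distance is recorded per point and capped at 1 mm by default — no cap is
published, but an unbounded nearest-structure rule would assign
arbitrarily distant points; beyond the cap a point is flagged
unassigned and excluded from summaries.

**Summaries.** Per-area counts use extrinsic cells only: cells in the
injected area are intrinsic (tracer uptake near the needle track is not
interpretable as connectivity), so that area's percentage is undefined
and flagged. Optional grouping maps merge small areas into supergroups
before counting; an illustrative auditory "core and belt" grouping ships
as package data. Expert tables that report sparse connections as a range
("0.05–0.1") are parsed as intervals and enter correlations at their
midpoint. Because it is ambiguous whether zero-on-both-sides pairs
should count toward agreement, the Pearson correlation is reported both
with and without them.

## The phantom

The phantom emulates the *geometry* of the problem, not histology
itself: a hemispherical cortical shell (inner 4.5 mm, outer 6.0 mm —
about 1.5 mm of cortex, a primate-like thickness at marmoset brain
scale) over a white-matter core, on a 64³ grid at 0.25 mm isotropic,
divided into 6 equal angular sectors as areas, with 3 thin landmark
wedges straddling area boundaries (the analogue of hand-drawn sectors of
distinctive tissue). Intensity is a depth profile plus gentle per-area
contrast, azimuthal modulation and smooth noise, so MI and CC have
gradients everywhere.

Distortions are drawn once per seed and stored as exact forward
transforms: per-section rigid jitter (σ 0.2 mm, 1.5°), per-section
Gaussian-smoothed white-noise displacement fields (amplitude 0.15 mm,
smoothness 1 mm — small compression/stretch/bending), a global affine
(scales 0.97–1.03, shear ≤ 0.02, rotation ≤ 3°, translation ≤ 0.5 mm)
and a smooth 3D deformation (amplitude 0.2 mm, smoothness 2.5 mm,
tapered to zero at the grid border so the map is identity outside). All
amplitudes keep displacement gradients below 0.5, so every drawn map is
invertible; a draw that is not is rescaled and logged. Each stage draws
from its own RNG stream derived from the seed by a fixed offset, making
all outputs pure functions of (config, seed).

One injection (80 voxels in a 0.3 mm ball at mid-depth of area 1) and
600 cells are planted per case; cells spread over the other areas with
multinomial counts whose probabilities are drawn once from a flat
Dirichlet — some connections strong, some sparse, as in real tracer
data — at normalized depths uniform in [0.2, 0.8]. Cell positions are
pushed through the inverse ground-truth chain onto their (quantized)
section planes, and the ground truth is re-derived at the re-mapped
position, so section coordinates and truth are exactly consistent.

What passing phantom tests shows: the registration machinery recovers
known distortions of realistic magnitude, the transform bookkeeping is
exactly right end to end, and the depth/area/summary logic matches
analytic truth. What it does not show: robustness to staining artifacts,
tears, missing or replaced sections, masking errors, or
cytoarchitecture whose appearance varies between specimen and atlas —
the phantom's intensities come from the template itself, which makes
similarity metrics more informative than in real material. Replaced
sections are treated as ordinary sections by the reconstruction; repair
of torn material is upstream manual preprocessing, not modeled here.

## Problem sizes and runtime

Default phantom runs use the 64³ grid (64 sections of 64×64 px); a full
pipeline — reconstruction, coregistration, depth solve, mapping and
evaluation — takes well under a minute on one CPU, and the analytic
depth fixtures (9-voxel slab, 70³ shell) a few seconds. The published
scale (hundreds of sections at 40 μm, 139 cortical areas) runs the same
code paths at larger n; the module-level working resolution and
iteration counts are the knobs that trade accuracy for time.

## Known limitations

- The deformable components are Gaussian-regularized demons, not a
  symmetric diffeomorphic (velocity-field) method; invertibility is
  enforced by gradient checks and smoothing rather than guaranteed by
  construction.
- Mutual information uses a plain joint histogram (32 bins) without
  Parzen smoothing; for optimization only the ranking of nearby poses
  matters, and the rigid/affine stages delegate to SimpleITK's Mattes
  implementation anyway.
- Surface flattening is out of scope; shell phantoms get an analytic
  (longitude, latitude) chart as the flat-map coordinate of a record,
  which exercises the schema but is not a general cortical flattening.
- Laminar (layer-level) position is not assigned — normalized depth is
  the supported proxy.
- Landmark sectors are supplied, not detected; automating their
  delineation is future work.
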