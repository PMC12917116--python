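# Methods

This note documents the models, conventions, and numerical choices
behind `spineplan`, and what the synthetic-phantom validation does and
does not establish.

## Coordinate convention

All world coordinates are RAS+ millimetres: +X right, +Y anterior,
+Z superior (head). Voxel grids are axis-aligned with
`world = origin + index · spacing`; NIfTI volumes are written with a
diagonal affine and re-oriented to RAS on read. "Vertical" in every
measurement means the projection onto the *patient's* head–foot axis
(the pose-corrected +Z), matching how the quantities are read on
sagittal images rather than the scanner table axis.

## The phantom

The phantom is a set of analytic solids rasterized onto a voxel grid
(default 88×96×160 at 1.5 mm isotropic), emulating the content of a
lumbar localizer volume.

**Curvature model.** The lumbar curve is a circular arc in the
sagittal plane. A total lordosis angle θ (default 40°) is distributed
uniformly over the n disc levels: disc i (head→foot) is tilted by
`φ_i = θ·(i − (n−1)/2)/n` about the left–right axis, so adjacent disc
normals differ by exactly θ/n and the mid level of a 5-disc spine is
exactly axial. Disc centers are chained along chords at the mid-angle
between levels; this keeps the per-level normals in closed form for any
per-level height profile.

**Structures.** Discs and vertebral bodies are elliptic cylinders in
their level frames (disc semi-axes 17 mm AP × 25 mm LR, heights 10 mm
and 27 mm by default — normal adult lumbar dimensions); the canal is a
per-level elliptic tube whose AP diameter is the spec's canal diameter
and which spans exactly from the posterior disc edge to the spinous
process tip, so the canal-diameter landmark definition (posterior disc
edge midpoint to spinous process midpoint) equals the spec value by
construction. Spinous processes are boxes; psoas muscles are elliptic
cylinders (semi-axes 15×10 mm → CSA π·150 ≈ 471 mm²) lateral to the
vertebral bodies. Facet lines, recess borders, foraminal borders, and
the intra-facet line are planted as landmark constructions with the
spec's angles and distances, again exact by construction.

**Pathology is planted by deforming the spec, never by voxel editing**:
canal stenosis reduces the level's canal diameter (8 mm in cohorts),
recess stenosis reduces recess height/angle (2.2 mm / 24°), and a
herniation adds a posterior half elliptic cylinder of the requested
extent to the disc. The herniation's cross-section is constant along
the disc axis so that the "maximal axial cross-section" does not depend
on where the voxel slices fall. Cohorts plant pathology at the
mid-lumbar level, which is exactly axial — there the analytic axial
areas are exact. The herniated bump's flat base pokes laterally past
the curved canal boundary, so the canal-area denominator (canal ∪ bump)
is integrated numerically from the continuous geometry at 0.05 mm
resolution; this is still ground truth derived from the analytic
shapes, not from voxels.

**Rasterization.** Each solid is sampled at 3×3×3 sub-voxel offsets
and a voxel takes the label when a majority (≥14/27) of its subsamples
fall inside; later structures overwrite earlier ones (paint order:
psoas, sacrum, vertebrae, canal, spinous, discs, herniation). Majority
voting keeps rasterized areas unbiased; at 1.5 mm the psoas CSA is
reproduced within ~1–2%. A structure reaching the outermost voxel
layer raises an out-of-bounds error naming it, since it would otherwise
be silently clipped. The intensity volume assigns per-tissue mean
intensities (CSF and disc bright, muscle dark, loosely T2-like) plus
Gaussian noise (sd 5 by default).

**Pose** is a rigid rotation about the grid center plus a translation.
`generate_phantom` applies it analytically (implicit functions composed
with the inverse pose; landmarks forward-transformed), so posed truth
stays exact. `apply_pose` separately resamples an existing label volume
with nearest-neighbor interpolation, which is the lossy operation a
real pipeline faces; its round-trip error is bounded by one voxel per
structure centroid.

**Cohorts** are deterministic: each varied scalar takes stratified
mid-quantile values of its range, permuted by the seeded generator (a
single phantom therefore takes exact midpoints), and planted pathology
counts are exact (`round(p·n)` phantoms), never Bernoulli draws. The
standard evaluation cohort (`evaluation.STUDY_VARIATION`) varies
lordosis 20–37.5° (disc tilts up to 15°), canal 12–16 mm, recess
4–6 mm / 35–50°, foramen 15–21 mm, facet 30–50°, and table position
±5 mm, with prevalences 0.2 / 0.2 / 0.3 for canal stenosis, recess
stenosis, and herniation. Cohort pose rotations default to zero: the
axial-slice psoas CSA measurement is only comparable to its analytic
value on an unrotated patient, and disc tilts are already exercised
through the lordosis range.

## Heatmaps and losses

Targets are `256·exp(−‖x−k‖²/2σ²)` per disc channel; σ defaults to
6 mm, the same scale as the 6 mm identification tolerance, which keeps
adjacent-disc peaks (≈35–40 mm apart) well separated. Candidates are
strict 26-connected local maxima above a threshold (default 128, half
peak); plateaus of equal value that dominate their neighborhood yield
one candidate at the lowest linear index — a deterministic tie-break
verified against an exhaustive-scan oracle. The focal loss clamps
probabilities at 1e−7 (logged once); heat values are kept in raw units
(peak 256) for the MSE rather than normalized. Dice of two empty masks
is defined as 1.0.

## Labeling

The reference disc (L5/S1) is the most caudal candidate above a heat
threshold, Z-ties within half a voxel broken toward higher heat.
Template matching pools candidates across channels (a peak emitted in
the wrong channel should not corrupt the labeling), and searches
order-preserving injective assignments of the Z-sorted pool to the
head→foot label sequence by depth-first branch-and-bound with
partial-cost pruning; the cost is the sum over assigned unordered pairs
of `|D(c_i,c_j) − T(i,j)|`. Assignments first maximize the number of
labeled discs, then minimize cost; channels without a surviving
candidate are MISSING. The matcher is validated against plain
exhaustive enumeration on randomized instances (d ≤ 6, ≤ 3 candidates
per channel). Because the cost uses only pairwise distances it is
exactly invariant under rigid motion of all candidates.

The default distance template places discs 35 mm apart along the
circular-arc model (the same geometry as the phantom) and is fully
overridable from JSON, since no canonical template values exist.
Label fusion assigns each connected disc component the nearest
candidate's label within a 15 mm gate (≈ half a vertebral height);
conflicting claims resolve by proximity with a logged warning, and
vertebrae are named from their flanking discs (the vertebra between
L4/5 and L5/S1 is L5).

## Scan planning

Per-disc transverse normals take the principal axis of the disc mask's
world-coordinate covariance that is most aligned with +Z (sign flipped
toward +Z); near-isotropic masks (λ₁/λ₃ < 1.05) fall back to the +Z
normal with a warning. The plane center is the centroid of the most
posterior 5% of disc voxels — a noise-robust operationalization of
"the posterior edge point". The sagittal plane through the disc
centers is their best-fit plane (normal = smallest PCA axis, which is
±X for a midline spine); collinear centers fall back to the world X
axis. The coronal plane is orthogonal, contains the long axis, and its
anterior normal orients the saturation band: the band's near face sits
a configurable offset (default 10 mm) anterior of the most anterior
disc voxel, thickness 30 mm, and by construction cannot contain disc
voxels; a band that would leave the volume raises an error reporting
the maximum feasible offset.

The quality factor is defined here as
`(assigned/total) · exp(−mean_k |d_k − t_k| / t_k)` over consecutive
assigned-disc spacings — it equals 1 exactly when every spacing matches
the template and no disc is missing, is bounded in [0, 1], and
decreases monotonically with spacing deviation or missing discs. The
formula is this package's own construction satisfying those stated
properties; no canonical formula exists. "Best display" sagittal and
coronal slices are the least-squares fitted mid-planes, resampled
trilinearly at native spacing with out-of-volume pixels set to 0 and a
coverage fraction reported.

## Morphometry

All landmark-based measurements are pure geometry on `LevelLandmarks`
(from ground truth or from the voxel extraction routine): vertical
quantities are head–foot projections, angle measurements use the
undirected line convention (range 0–90°). Psoas CSA is the voxel count
of the side's psoas label on the axial slice through the named
vertebra's mid-level times the in-plane pixel area. The herniation
ratio is the maximum over axial slices of herniated-disc area divided
by canal area on the same slice, with the canal taken as the full canal
region including the space occupied by the herniated material.

MSU grading is operationalized as: grade 1 when the apex reaches less
than 50% of the posterior-margin→intra-facet-line distance, grade 2
from 50% up to the line, grade 3 beyond it; the zone comes from the
apex's mediolateral offset as a fraction of the intra-facet half-length
(A ≤ 0.5, B ≤ 1, C beyond). The published scheme describes the
size/location categories qualitatively; this partition is this
package's concrete geometric realization.

Diagnostic comparisons are strict (`<`), so boundary values (10 mm,
3 mm, 30°) are negative findings. The recess-angle direction is
config-switchable (`angle_direction: less|greater`) because both
conventions circulate; the default calls stenosis at angle < 30°.
Missing measurements diagnose as "indeterminate", never silently
negative.

## Voxel-based extraction and its limits

`extraction.extract_disc_landmarks` recovers the sagittal landmarks
from the rasterized masks using extreme one-voxel slabs with a
half-voxel outward face correction (majority-vote rasterization keeps
only majority-covered voxels, so painted faces sit about half a voxel
inside the true surface). Each extracted face is accurate to about
half a voxel; distances between two faces (canal diameter) compose both
errors, so the worst case is about one voxel. Extraction assumes
near-axial discs: a strongly tilted disc's world-axis extrema move away
from its mid-plane, so the routine is validated at the mid-lumbar level
(within ~10° of axial under the study conditions).

## What the validation shows — and does not

Passing the suite establishes that every algorithmic stage reproduces
analytic geometry on an idealized torso: plane normals within 2° mean
(the per-disc planner also strictly beats a single global axial
orientation whenever lordosis is nonzero), landmark measurements exact,
voxel-based areas within 2%, detection rates exactly equal to planted
prevalence, and labeling perfect under 1 mm candidate jitter. The
phantom deliberately omits MR physics (bias fields, k-space artifacts,
partial-volume fat/water effects), degenerative shape variation,
transitional vertebrae, and segmentation failure modes of a trained
network — so these results bound algorithmic correctness, not clinical
performance. The localization network itself (architecture, weights,
training) is out of scope; the losses are exposed as pure functions for
any external training harness.

### Numerical tolerances used in validation

* areas (psoas CSA): 2% of analytic value at the default 1.5 mm grid;
* herniation ratio: 12% worst-case across cohorts — the ratio divides
  two areas of only ~40–100 pixels each, so its quantization noise is
  an order larger than a single large area's;
* plane angles: 2° mean / 5° max over the standard cohort;
* two-face voxel-extracted distances: one voxel worst case, half a
  voxel in the mean;
* matching-error oracle agreement and loss identities: 1e−9 / 1e−12.

### Problem sizes

The evaluation cohort is 50 phantoms at 88×96×160 × 1.5 mm; the
matching oracle check runs 200 randomized instances (d ≤ 6, ≤ 3
candidates/channel); loss identities use 1000 random draws. These
sizes give stable statistics while keeping a full validation run in the
low minutes on one CPU.
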