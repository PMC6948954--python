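# Methods

This note documents the models, parameter choices and numerical
decisions behind `renolymph`, and what validation on synthetic phantoms
does and does not establish about real data.

## Conventions

Arrays are `(z, y, x)`, 0-based, matching TIFF page order.  All
physical quantities are micrometres internally; cubic millimetres
appear only in reported organ metrics (1 mm³ = 10⁹ µm³).  Voxel spacing
is always supplied by configuration and overrides file metadata —
cleared-tissue acquisitions routinely carry wrong or missing metadata.
The lateral pixel size has no safe default and must be provided; only
the axial step defaults (2.77 µm, the acquisition convention the
pipeline was designed around).

## Segmentation

Each marker channel is despeckled with a per-slice 3×3 median (the
standard "despeckle"; implemented as a 19-comparator median-of-9
min/max network for speed), optionally unsharp-sharpened, and
background-subtracted with a per-slice rolling ball.  The rolling-ball
background equals a greyscale opening with a ball element; for large
radii the opening runs on a 2–4× downsampled copy and is upsampled
back, the usual shrink trick.  The ball radius (default 50 µm) must
exceed the largest true structure.

**Thresholding.**  Li (minimum cross-entropy), Otsu, triangle and
manual thresholds are available.  The default for marker channels is
`robust_otsu`: Otsu restricted to the brightest percentile of voxels
(default 99%).  Plain histogram methods fail on wholemount lymphatic
channels because the foreground occupies 0.01–1% of the volume, so the
background mode dominates any global criterion; restricting to the
bright tail restores a balanced two-class problem.  When the bright
structures themselves exceed the tail size, Otsu would split *within*
the foreground; this is detected by the intensity mass just below the
candidate threshold (a populated band at ≥ 0.85·t that exceeds 1.5×
the mass above t) and the percentile is lowered stepwise until the
subset straddles the background/foreground gap.  Strictly two-valued
histograms fall back to a mid-range split.  The threshold actually used
is logged and written to the QC report.

**Colocalization** is at component level: a LYVE-1 connected component
is kept if it overlaps at least one PROX1⁺ voxel.  A voxelwise AND
would erase the cytoplasm of every cell, since PROX1 is nuclear and
LYVE-1 membranous.  Components smaller than `min_component_voxels`
(default 10) are discarded as shot noise.  Default connectivity is 26;
thin diagonal tubes fragment under 6-connectivity.  The largest
remaining component is the plexus; everything else becomes the
residual-component image that feeds cluster detection.  Ties for the
largest component are broken by the lexicographically smallest (z,y,x)
seed voxel, with a logged warning.

## Centerline morphometry

The plexus is thinned to a one-voxel 3D skeleton (topology-preserving
thinning); anisotropic masks are first resampled to the smallest voxel
size, because thinning assumes isotropy and a 2.77 µm axial step would
bias centerlines.  Skeleton voxels with ≥ 3 neighbors form junction
nodes (26-adjacent junction voxels merge into one node), degree-1
voxels are endpoints, maximal junction-free paths are branches, and a
junction-free closed loop (an isolated ring) becomes one self-loop
branch.  Centerline polylines are smoothed with a short moving average
(half-window 2 points, ends pinned) to suppress the digital staircase.

Thinning introduces three systematic artifacts, each handled
explicitly:

* **Split junctions** — one anatomical junction can thin into several
  skeleton junctions up to a tube radius apart.  Junction–junction
  stubs shorter than the sum of the two junction-blob radii (read from
  the 3³-max-filtered distance transform) are contracted; short
  self-loops left by contracting one of two parallel stubs are dropped.
* **Spurs** — terminal branches shorter than twice the local diameter
  (with a 4 µm floor) are peeled one at a time, shortest first, with
  degrees recomputed after each removal, so pruning can only remove
  leaves and never disconnects the graph.
* **Junction drift and tip retraction** — the skeleton junction point
  drifts off the true branch-axis meeting point by up to a parent
  radius, and terminal centerlines retract into the end-cap (sometimes
  far beyond one radius, a known behaviour of 3D thinning on short
  capsules).  Junction nodes are re-localized to the least-squares
  intersection of the incident branches' directions (principal
  component of a trimmed window, 1.2 r to 1.2 r + max(12 µm, 2 r) from
  the node), guarded to stay within the junction blob; terminal tips
  are recovered by marching a ray from the skeleton endpoint along the
  branch's end direction to the mask boundary and stepping back one
  tube radius (the cap protrudes one radius past the centerline's true
  end).

**Measurements.**  The branch radius at a centerline point is read from
the distance transform at the nearby ridge (trilinear sample of the 3³
maximum filter), which compensates the sub-voxel offset of discrete
skeleton voxels from the true medial axis; the mean uses interior
points only (within one local radius of an end the transform reflects
the junction blob, not the tube).  The final mean diameter averages
this estimate with the volume-equivalent cylinder diameter 2√(V/(πL)):
the two have opposite discretization biases, and on calibration
cylinders of radius 2–5 voxels their mean is accurate to a few percent
where either alone errs by up to 10%.  Branch volume assigns every
plexus voxel to its nearest branch centerline, so branch volumes sum to
the plexus physical volume exactly.  The per-kidney summary reports the
branch count, the spread (max − min) of branch lengths — the "range of
vessel lengths" is interpreted as this single per-kidney scalar — the
maximum per-branch mean diameter, and the total network volume.
Diameter color-coding bins default to < 20, 20–70 and > 70 µm.

## Cluster analysis

"No continuity with the plexus" is operationalized as a surface
distance: residual components whose minimum distance to the plexus
surface exceeds `continuity_radius` (default 5 µm) are clusters; nearer
components are flagged contiguous and excluded from all counts.  Voxel-
center distances overestimate surface distances by up to one voxel
diagonal, which is subtracted, so an adjacent component reads distance
0.  Raising the radius can only shrink the cluster set.  Cells per
cluster are counted as local maxima of the Gaussian-smoothed (σ = 2 µm)
PROX1 intensity inside the component, greedily merged below
`nucleus_min_distance` (default 7 µm ≈ one endothelial nucleus).  This
matches "number of PROX1⁺ nuclei" semantics at 10× resolution without
requiring full nuclear segmentation.  The census histogram uses size
classes 1–7 and "≥ 8".

## Organ volume and normalized metrics

The organ channel (autofluorescence when present, else LYVE-1) is
smoothed with σ = 5 *pixels* in-plane — the printed pixel convention —
with the axial σ scaled by the spacing ratio so smoothing is physically
isotropic.  The Li threshold is then refined by intermeans (IsoData)
iteration: on a smooth organ surface the minimum-cross-entropy
threshold sits far down the blurred edge skirt and inflates the volume
by ≈ 15%, whereas the intermeans fixed point puts the boundary at the
edge's half-height, recovering an analytic ellipsoid to < 1%.  Holes
are filled per slice and in 3D, the largest 3D component is kept, and
the volume is voxel count × voxel volume.  Branch density is reported
per mm³ — dividing a count by a volume yields an inverse volume, so
"per mm" in common usage is read as per mm³ — and occupancy as
100 × network volume / kidney volume.

## Group statistics

Per-kidney metrics assemble into a long-format table (kidney, group,
metric, value).  Shapiro–Wilk runs per group (skipped with a warning
below n = 3); Brown–Forsythe (median-centered Levene) across groups
selects the Welch path when p < 0.05, with a manual override.  The F,
W and t statistics are computed from their sum-of-squares definitions
(Welch's W with the Welch–Satterthwaite denominator df = 1/Λ) and are
cross-checked in the test suite against independent brute-force
formulas, scipy and pingouin.  Post hocs: Bonferroni (pairwise pooled
t, p·m capped at 1) for the classical path; Tamhane T2 (pairwise Welch
t with the conservative Šidák-type adjustment 1 − (1 − p)^m) for the
Welch path.  The family is all pairwise comparisons unless restricted,
and the family size is always reported.  Significance tiers follow the
4-star convention (*: p < 0.0332, **: p < 0.0021, ***: p < 0.0002,
****: p < 0.0001).  Monte-Carlo checks show type-I error within
0.05 ± 0.01 for both ANOVA paths at n = 5 per group (the Welch path's
true size at a 25-fold variance ratio is ≈ 0.052).

## The phantom generator

The generator emulates the features the pipeline must handle: a closed
ring anastomosis (centerline radius 60 µm, tube radius ≈ 14.7 µm) in a
plane near one pole of an ellipsoidal organ envelope, feeding a
bifurcating tree (default 3 generations; first-generation radii
11 ± 1.5 µm, taper 0.75 per generation; lengths 70 ± 12 µm with a floor
of twice the spanned junction-blob radii, since a branch shorter than
the junction blobs it connects is not a resolvable vessel segment);
PROX1⁺ nuclei (radius 3.5 µm) every 10 µm of centerline with 20%
jitter; isolated clusters of 1–8 cells (radius 5 µm, mutually
contacting spheres joined by thin cytoplasmic bridges so the rendered
cluster stays one connected component under voxelization) at ≥ 20 µm
from the plexus surface; strong LYVE-1-only macrophage blobs (radius
5–9 µm) and weak PROX1-only tubule patches (30% of foreground);
Gaussian noise at 10% of the foreground level by default, with
optional Poisson noise.  Confounders are placed clear of vessels,
clusters and each other so that every foreground voxel is attributable
to exactly one ground-truth object.  Tubes are rasterized by
distance-to-polyline in physical coordinates (exact under anisotropy);
a membership label image attributes every vessel voxel to its branch,
and per-branch ground-truth volumes are read from it.  Non-adjacent
tubes keep an 8 µm surface clearance; branches meeting at a junction
must clear each other outside a junction ball of one clearance-sum
radius, which also forbids a sibling crossing its parent and creating a
topological handle.  Placement is stochastic with retry budgets; a tree
that crowds itself is resampled wholesale (deterministically), and a
configuration that cannot be placed raises an error.  One global seed
expands into fixed per-stage substreams, so identical (config, seed)
yields bit-identical stacks and ground truth.

Default phantoms are generated on a 256³ grid at isotropic 2 µm voxels
(the anisotropic acquisition geometry is exercised separately by the
rasterization and skeletonization tests); the cluster-recovery
condition uses a 160³ field with a two-generation tree and 8 clusters,
and unit tests a 128³ variant.  These sizes are the package's validated
problem sizes; everything scales to larger fields through the same
configuration objects.

**What phantom validation does not show.**  Phantoms have hard-edged
tubes with no point-spread blur, no depth-dependent attenuation, no
vessel lumen, straight branches, and noise that is stationary across
the field.  Passing recovery tests therefore establishes the
correctness of the measurement chain under known geometry — not that
thresholds or continuity radii are optimal for any particular
microscope or clearing protocol.  On real data the manual-threshold
path and the logged QC report exist precisely because auto-thresholds
may need review.

## Validated accuracy (synthetic, at the sizes above)

Over ≥ 20 seeded phantoms with 10% noise: branch count exact on every
phantom; per-branch length mean absolute error ≤ 5% per phantom
(typically ≈ 2%; single branches can reach ≈ 10–12% when a skeleton
junction lands half a tube radius off, which is the accuracy limit of
medial-axis junction localization); per-branch diameter mean error
≤ 10% (typically ≈ 3%); total network volume within 1%.  Cluster
precision and recall 1.0 with cell counts within ±1.  Analytic
ellipsoid volume within 0.5%; occupancy and branch density within 1%
of ground-truth ratios.  The acceptance script recomputes all of these
from scratch at every run.

## Known limitations

* Junction localization error is bounded by the junction-blob radius;
  branches much shorter than the blob cannot be measured reliably (the
  generator does not produce them, and real ones would merge).
* Nucleus counting by local maxima saturates for very large, tightly
  packed islands; counts above ~12 cells would need true nuclear
  segmentation.
* The organ estimator assumes one dominant connected organ in the
  field; touching organs would merge.
* The Tamhane T2 adjustment is the Šidák-type conservative form; exact
  T2 critical values differ negligibly at these family sizes but are
  not implemented.
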