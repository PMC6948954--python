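# renolymph

3D quantification of the developing kidney's lymphatic vasculature from
cleared-organ confocal stacks — and a synthetic phantom generator that
provides exact ground truth for validating every stage of the analysis.

## The problem

During embryonic kidney development, lymphatic vessels emerge as a
ring-like anastomosis under the renal pelvis and grow into a branching
plexus, accompanied by a transient population of isolated
PROX1⁺/LYVE-1⁺ endothelial cell clusters.  Quantifying this system from
wholemount two-marker confocal imaging requires a chain of image-analysis
steps — dual-marker segmentation, centerline extraction, branch
morphometry, cluster detection and cell counting, organ-volume
normalization — followed by small-n group statistics across timepoints,
genotypes or treatments.  `renolymph` implements that chain as a tested,
scriptable pipeline:

* **Segmentation** — despeckle/background-subtract each channel,
  auto-threshold, keep LYVE-1 components that contain PROX1⁺ signal
  (component-level colocalization), and split the result into the main
  plexus (largest component) and residual components.
* **Morphometry** — 3D topology-preserving thinning of the plexus,
  centerline-graph extraction with junction/spur cleanup, and per-branch
  length *L*, mean diameter *d̄* (from the Euclidean distance transform
  along the centerline, cross-checked against the volume-equivalent
  cylinder 2√(V/πL)) and volume *V* (nearest-centerline partition of
  the plexus voxels, so ΣV equals the plexus volume exactly).  Per
  kidney: branch count *N*, length range (max − min), maximum mean
  diameter, total network volume.
* **Clusters** — residual dual-positive components with no spatial
  continuity to the plexus (surface distance > r_c, default 5 µm) are
  clusters; cells per cluster = PROX1⁺ nuclei, counted as merged local
  maxima of the smoothed nuclear channel.
* **Organ metrics** — whole-kidney volume V_K by Gaussian smoothing
  (σ = 5 px), Li thresholding with intermeans refinement, hole filling
  and largest-component selection; then branch density N/V_K (mm⁻³) and
  occupancy 100·V_network/V_K (%).
* **Statistics** — Shapiro–Wilk and Brown–Forsythe assumption checks
  select classical (F) or Welch (W) one-way ANOVA with Bonferroni or
  Tamhane T2 post hocs, pooled or Welch t-tests for two groups, and
  fold changes of group means.

The phantom generator builds the whole scene synthetically — ring +
bifurcating tree, nuclei along centerlines, isolated cell clusters,
LYVE-1-only macrophage blobs, weak PROX1-only tubule patches, an
ellipsoidal organ envelope, Poisson/Gaussian noise — with bit-exact,
seeded ground truth for every object, so recovery can be asserted
quantitatively without any real data.

## Worked example

```python
from renolymph import AnalysisConfig, PhantomConfig, generate_phantom, run_quantify

stack, truth = generate_phantom(PhantomConfig(), seed=1)
report = run_quantify(stack, AnalysisConfig(spacing=(2.0, 2.0, 2.0)))

print("branches:", report.network.n_branches, "(true:", truth.n_branches, ")")
print("total network volume (µm³): %.0f (true: %.0f)"
      % (report.network.total_volume, truth.graph.total_volume()))
print("occupancy: %.3f%% (true: %.3f%%)"
      % (report.organ.occupancy_percent,
         100 * truth.graph.total_volume() / truth.organ_volume))
```

prints, for this seed:

```
branches: 16 (true: 16 )
total network volume (µm³): 433864 (true: 436584)
occupancy: 0.981% (true: 0.985%)
```

All 16 branches (two ring arcs plus a three-generation bifurcating
tree) are recovered exactly; the network volume agrees with ground
truth to 0.6% and the kidney-volume-normalized occupancy to 0.4%.

The same pipeline runs from the shell, one stage at a time or end to
end:

```bash
renolymph simulate --seed 1 --out sim/
renolymph quantify --stack sim/phantom.ome.tif --config analysis.yaml --out kidney01/
renolymph compare  --table metrics.csv --metric n_branches --out result.json
```

`simulate` writes an OME-TIFF stack plus the true branch table (CSV),
the true centerline graph (SWC) and a ground-truth JSON; `quantify`
writes the plexus/organ masks, measured branch table, SWC, and a
`report.json` whose per-kidney metrics feed `compare`/`study`.

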