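# Methods

## Image model

The pipeline assumes modified-Nissl contrast: stained tissue is mid-gray,
unstained structures — vessel lumina and the resin outside the brain — are
bright. The phantom generator encodes this with three intensity classes:
tissue at `tissue_mean` (default 117), lumina and background at
`tissue_mean + lumen_offset` (default +40), an optional darker one-voxel wall
shell (`wall_offset`), additive Gaussian noise (`tissue_sd`, default 8),
clipped to [0, 255] and quantized to 8 bits. Background and lumina share one
intensity on purpose: both are unstained, and this is what makes the brain
contour separable by a single global threshold while penetrating lumina stay
bright inside it.

Grids are indexed `(z, y, x)` with z the coronal section index, voxel centers
at integer voxel coordinates, positions and radii in micrometres. Whole-brain
work uses 5×5×5 µm voxels; microvessel cubes use finer grids (the phantom's
microvessel study runs at 0.5 µm isotropic).

## Brain contour and dents

Per slice: 3×3 median filter (reflect edges), binarize at one global Otsu
threshold for the whole stack (dark side = tissue), fill holes, close/open
with small discs (default radius 2 px), then prune 3D connected components
below `min_component_voxels` (default 1000 — the value is not critical; it
only needs to separate off-brain debris from the brain, which is orders of
magnitude larger). Otsu is computed on the 256-bin histogram as the level
`t ∈ [0, 254]` maximizing between-class variance of `{≤t, >t}`, lowest t on
ties.

Dent extraction closes each slice with a Euclidean disc of radius 30 px
(150 µm at 5 µm voxels — wider than any pial vessel) and subtracts the
original mask. Disc and ball morphology is computed via exact Euclidean
distance transforms with the volume padded by the disc radius, which equals
structure-element morphology on an unbounded canvas; this keeps radius-30
closings exact and fast, and makes dent volume grow monotonically with the
radius (pixel-level set inclusions can still flip on a few voxels because
discrete discs of different radii are not exact homothets).

Dent tracing closes the dent volume with a small ball (default 3 voxels) to
bridge slice-wise discontinuities — replacing interactive cleanup of broken
branches — then skeletonizes and vectorizes it (type code 8).

## Threshold calibration and region growing

Region growing returns exactly the connected component (26-connectivity by
default, 6 selectable) of `{intensity ≥ t}` containing the seed. Calibration
scores every candidate threshold voxel-wise against a ground-truth mask
(positives = above-threshold voxels); cumulative histograms make the sweep
O(256) regardless of the candidate count. ROC points are reported; selection
uses only the floor rule: the smallest candidate with recall and precision
both ≥ 0.94. On the default phantom conditions this minimum sits 20–23 gray
levels above the image mean — with ~3% bright voxels in an interior cube, the
precision floor forces `t` to about 2.9 tissue standard deviations above the
tissue mean, i.e. +23 at SD 8, while recall stays ≥ 0.94 up to lumen mean −
1.55 SD ≈ +27. The window is therefore a property of the contrast and noise,
not a tuned constant.

Calibration is evaluated on an interior represented cube (tissue + vessels
only): the stack at large contains the bright outside-brain background, which
is not a candidate for vessel segmentation. In the pipeline, grown regions
covering more than half the brain volume are discarded with a warning — the
automated analogue of "do not segment background".

## Vectorization

Skeletonization is Lee-style 3D medial-axis thinning (scikit-image), followed
by iterative removal of terminal chains shorter than `prune_spur_len_um` that
end at a junction (whole two-endpoint components are never pruned), and
endpoint re-growth: thinning retracts open tube ends by roughly one radius,
so each endpoint is extended along its local chain direction until the
straight continuation leaves the mask.

Graph reduction places nodes at endpoints, junctions, and intermediate points
every `node_spacing_um` (default 5 µm) along each centerline run. Parent
links form a BFS spanning forest rooted at the highest-z endpoint of each
component; every non-tree edge is recorded in `loop_edges`. SWC cannot encode
cycles, so `loop_edges` are serialized to a `.loops.tsv` sidecar and are
counted exactly once by all length statistics. Type codes: 5 artery, 6 vein,
7 capillary, 8 pial dent trace.

Radii use the half-voxel inscribed-sphere convention: the reported radius is
the largest multiple of 0.25×(min voxel size) such that no background voxel
center lies within r plus half a voxel of the node — an isolated voxel gets
radius 0.5 voxel. It is computed in closed form from the anisotropic EDT,
taking the maximum over the node's 3³ neighborhood because a thinned voxel
can sit one voxel off the true medial axis. `distance_transform` mode returns
the unsnapped distance. Digital cylinders of radius 2–12 voxels are recovered
within ±0.5 voxel (at the boundary of that band: the digital boundary itself
is ambiguous to half a voxel).

Known limitation: for vessels only a few voxels wide, the half-voxel
convention under-renders cross-sections — a radius-3-voxel tube renders at
~72% of its digital area. The traced-over-true area ratio D therefore sits
near 0.65–0.75 for capillary-dominated scenes sampled at 0.5 µm (capillary
radii 1–2 µm), and approaches 1 as radius/voxel grows. Recall and precision
of the tracing are unaffected (≈ 0.93 / 1.0 on the microvessel phantom).

## Quantification

*Validation (R/P/D)* renders the traced graph back to the truth grid as
tapered capsules and compares on slices sampled every 70 µm. `B1`/`B2` are
the ground-truth/traced totals, `A1`/`A2` the traced/true areas, `D = A1/A2`.
In region mode (default) a single "overlap count" B can exceed the totals
when overlaps fragment, so the recall numerator counts truth regions touched
by the tracing and the precision numerator counts traced regions touching the
truth; both equal the naive B in the unfragmented case. A voxel-wise mode is
also provided. D is reported both pooled (ΣA1/ΣA2) and as a per-slice mean.

*Fv* is vessel voxels over region voxels per diameter bin (small D ≤ 8 µm,
medium 8–20, large > 20); graph input is rasterized per bin with segment bin
= mean of endpoint diameters, and a voxel claimed by several bins counts in
the largest, so bins partition and sum to the total. *Nl* sums centerline
segment lengths per bin over the region volume, in mm/mm³ (the natural unit
at these densities — cortical capillary beds are ~10³ mm/mm³). Region labels
leave vessel lumina unlabeled, so vessel voxels and segment midpoints are
attributed to their nearest region (EDT-based), and the region volume in the
denominator includes the vessel voxels assigned to it.

*Shrinkage*: resin embedding shrinks the specimen linearly by s = 25.9 ±
1.6%. Corrected lengths scale by 1/(1−s), volumes by 1/(1−s)³, so
`Nl_corr = Nl·(1−s)²` and Fv is invariant (an isotropic scale cancels in a
volume fraction; both raw and corrected tables are emitted so either reading
is available). When the graph is available, diameters are corrected *before*
binning (a measured 7 µm vessel is 9.45 µm in vivo and moves from the small
to the medium bin); a closed-form correction of an already-binned report
cannot re-bin and says so.

*Distribution matrices*: per vessel label, the voxel-count proportion in each
region plus an `unassigned` column; rows sum to 1 (±1e-9) and the mean across
subjects stays row-stochastic. Pial branches without segmented lumina are
rasterized from the dent trace at the literature radii (artery 150 µm, vein
250 µm) before counting.

*Branch levels*: branches are maximal parent-chains between branch points;
each is assigned level 1 (mean D > 90 µm), 2 (40–90) or 3 (≤ 40) and a
hemisphere by mean x against a sagittal plane (default mid-x). Only the
diameter rule is used; a bifurcation-order rule would need an explicit root
ordering that the diameter rule already induces in practice.

*Region comparison*: one-way ANOVA from between/within mean squares
(`F = MSB/MSW`, p from the F distribution), plus a pairwise two-group grid
(identical to squared two-sample t tests).

*Annotation*: vessel names follow `orientation(-orientation)*-region-kind`
with 1–3 orientations, or `orientation-branch of-<parent vessel>` when only
the parent distinguishes the branch.

## Phantom generator

The phantom is procedural: a superellipsoid brain (exponent 2.5, semi-axes
0.42× the volume extent); pial vessels as surface-following tubes whose
voxels are subtracted from the brain mask, so surface dents are exact;
penetrating trees attached below the surface, growing inward by recursive
binary branching with tapering radii (factor 0.7 per level) to
`branching_depth`; and a capillary mesh of straight 20–80 µm segments
(diameters 2–4 µm wide, populating the capillary bin) placed near tree
terminals until the capillary length density reaches
`capillary_density_target` (default 500 mm/mm³ at whole-brain scale, 900 for
the microvessel cube — the physiological order for cortical capillary beds).
Region labels are Voronoi cells of random interior seeds, defined on brain
minus vessel lumina. `brain_geometry="full"` produces an all-tissue cube — a
microvessel field sampled from inside a region, with no brain surface (and
hence no pial vessels).

Interior vessels keep a margin of two maximum radii from the pial zone:
pial lumina are bright like the outside background, so a penetrating lumen
touching one would merge with the background under a global threshold. Real
penetrating vessels do connect to pial vessels; the margin trades that
fidelity for a well-posed single-threshold segmentation, which is the
behavior under study.

Determinism: one `numpy` PCG64 generator seeded from `params.seed` drives all
draws in a fixed order; identical parameters give bit-identical scenes,
masks, labels and SWC.

What the phantom does not model: optical blur and partial-volume intensities
(vessel boundaries are crisp, so segmentation is easier than in real data at
equal contrast), staining gradients and illumination drift, anatomically
realistic branching topology and artery/vein pairing, and hemodynamic
plausibility. Passing tests therefore demonstrate correctness of the
operations and calibration behavior under the stated contrast model, not
performance on real stacks.

## Problem sizes

Default study sizes: 96³ voxels (whole-brain style, 5 µm), 224³ (microvessel
style, 0.5 µm), and a 256³ end-to-end pipeline exercise; these preserve all
structural scales of the method (tube radii 1–25 µm, closing disc 30 px)
while keeping each study in the tens of seconds on one CPU.
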