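# Methods

This note documents the models, numerical choices and deliberate design
decisions behind the package, and what the synthetic phantoms do and do
not establish about real CT angiography data.

## Coordinate and image conventions

Volumes are axis-aligned scalar grids in Hounsfield units (HU), voxel
indices 0-based, `world = origin + index · spacing` (mm). Axis 2 is the
cranio-caudal slice axis; all reformations emit one output row per axial
slice so that z distances are preserved at full slice resolution
("projected", not "stretched", CPR). Oblique DICOM geometry is rejected
rather than silently resampled; the internal orientation is fixed and
documented because workstation conventions (LPS vs RAS) vary and nothing
in the processing chain depends on the anatomical sign of x/y. Arclength
and segment intervals are half-open `[start, end)` so that consecutive
segments partition a path without overlap. DICOM and 16-bit PNG outputs
store `HU + 1024` as unsigned 16-bit with rescale metadata: exactly
invertible for integer HU (fractional HU are rounded on write). An 8-bit
PNG requires an explicit `(center, width)` window.

## Phantoms

The generator rasterizes tubes around polyline axes by exact
point-to-axis distance with one-voxel linear edge antialiasing;
sub-voxel tubes are additionally scaled by their cross-section's share of
a voxel so that an occluded extent (radius 0) paints nothing. The default
two-leg tree mirrors the standard run-off segmentation (21 segments per
leg in three regional groups) with plausible adult calibres (iliac
4 mm … tibial 1.5 mm); left and right legs are exact mirror images.

HU palette defaults: soft tissue 40, lumen 400, bone 1000, calcification
800, stent 2000, vein 300, Gaussian noise SD 10 — plausible 80-kV CTA
values with the arterial enhancement at +360 HU, comfortably above the
150-HU bolus-trigger floor that the spec invariant enforces
(`lumen_hu − background_hu ≥ 150`). All levels are configurable; none is
a claim about any particular scanner.

Stenoses taper the local radius with a raised-cosine profile over the
lesion length, reaching `(1 − severity)·r` exactly at the lesion centre:
smooth, differentiable, analytically known minimum. Occlusions zero the
radius over their extent. Calcifications are half-annulus crescents
(1.5 mm thick) on a fixed side of the wall; stents are full cylindrical
shells (1 mm). The accompanying-vein overlay adds a parallel tube at a
configurable in-plane offset. For the venous-switching scenario the
tests use a 6 mm offset (rather than the 3 mm default) so that artery
and vein are separated by soft tissue: with touching lumens no control
point can anchor the course, because crossing between vessels is free —
clinically the accompanying veins also run a few millimetres from the
artery.

What the phantoms do **not** model: beam hardening, photon-starvation
noise, contrast-bolus kinetics, motion, vessel wall texture, tortuosity
beyond gentle slopes, and anatomical variants. Tests passing on phantoms
therefore establish the *correctness of the algorithms* (geometry,
sampling, optimality, statistics), not clinical reading performance.

## Tracking

The cost image is `floor · (1 + (d/scale)²)` capped at 10⁶, where `d` is
the HU distance to the enhancement window (default `[background + 150,
stent)` — the 150-HU enhancement trigger is the only anchored number;
everything enhancing like contrast, including early-filling veins, is
cheap, which is precisely the clinical failure mode). Minimum-cost paths
are Dijkstra on the 26-neighbourhood with edge cost `mean(endpoint voxel
costs) × physical step length` (`skimage.graph.MCP_Geometric`); tests
verify exact cost-optimality against branch-and-bound enumeration and an
independent Dijkstra. Ties are resolved by the library's internal order —
only the optimal cost is contractual.

Recentering moves each point to the centroid of the connected
above-threshold region containing it in the plane orthogonal to the local
tangent (plane resampled at half the in-plane spacing), iterated at most
10 times to 0.05 mm. The threshold defaults to the full-width-half-maximum
level: soft tissue is estimated as `window.low − 150` (the trigger
definition) and the lumen level as the median HU along the raw tracked
path, the threshold being their mean. The search window is 4 mm — larger
windows let the centroid be captured by adjacent lumens near bifurcations
and parallel vessels. Points with an empty cross-section (occlusions) are
flagged and left in place. Paths are then resampled to one point per
slice by first z-crossing, z-monotonising vessels that locally reverse.

On the noiseless lesion-free two-leg phantom, tracking from the aortic
root plus the six distal endpoints alone recovers every centerline within
1 voxel RMS; residual error concentrates at bifurcations where the lumen
cross-sections genuinely merge.

Step detection reports every slice whose in-plane centerline displacement
exceeds a threshold (3 mm in the tests): the artery→vein switch happens
as an in-plane Dijkstra traversal at a single slice, so it appears as one
abrupt jump, while genuine vessel slopes move well under 1 mm per slice.

## Rendering

The viewing geometry rotates about z: screen-x unit
`u = (cos a, sin a, 0)`, ray `v = (−sin a, cos a, 0)`, a ∈ [−90°, +90°].
CPR samples the in-plane line through each slice's path point along `u`,
±halfwidth (default 10 mm). Multipath CPR uses a fixed screen-wide column
grid anchored at the projected volume corner (at 0° it coincides with the
voxel x-centres); columns are partitioned among paths by nearest
projected abscissa, ties to the leftmost-on-screen path, columns farther
than halfwidth from every path show context (−1024 or a 20 mm thin-slab
MIP centred at the nearest path's depth). A warning (not an error) is
raised when two paths with *different* anatomy project onto the same
abscissa over most of their course, as expected for near-lateral views;
shared trunks are exempt. Because CPR columns are path-centred and mpCPR
columns are screen-fixed, the single-path reduction "mpCPR ≡ CPR" is
exact per column wherever the two abscissa grids coincide (always, for a
straight axis-aligned path), and holds as value equality at matching
lateral offsets in general.

All attributed pixels are order-1 (trilinear) samples; each image records
its per-pixel 3-D sampling position so HU conservation is auditable
against an independent sampler (tested exactly). Out-of-volume CPR
samples read −1024. MIP rays are instead *clamped* to the volume support:
a ray maximum must not be diluted by outside padding, so a constant
volume projects to a constant image. Bone segmentation is
threshold (700 HU) → 26-connected components ≥ 64 voxels → morphological
closing → one-voxel dilation; the dilation suppresses the partial-volume
rim of cortical bone that would otherwise survive as bright halos in the
bone-suppressed MIP.

Rotational invariance of the CPR is verified on a cylinder with a
Gaussian radial profile (σ = 6 mm) rather than a hard-edged tube: a
band-limited field isolates renderer error from lattice aliasing. On a
128×128×160 grid the 21 views agree within 0.25 HU; a sharp rasterized
edge would contribute tens of HU of aliasing regardless of the renderer
and mask any defect being tested for.

## Stenosis grading

The lumen profile measures, per slice, the area of the above-threshold
region connected to the centerline point in the orthogonal plane
(half-voxel plane resampling), and the effective circular diameter
`2·√(area/π)`. Since human readers grade visually, a quantitative
reference rule had to be chosen: `d_ref` is the median diameter of the
segment's assessable slices after discarding the narrowest 20%, which is
robust against the lesion biasing its own reference. The grade is
`100·(1 − d_min/d_ref)` clipped to [0, 100]; significant iff strictly
> 70 (exactly 70% is *not* significant); occluded slices carry zero
diameter, so any occlusion grades 100%; a fully unassessable extent is
rated non-assessable (low-contrast category by default, which callers may
override from other evidence such as stent or prosthesis artifacts).

Thresholds: grading quality is best at the full-width-half-maximum level
(mid-way between soft tissue and lumen, 220 HU for the default palette),
which makes the measured radius unbiased on antialiased phantoms; the
lower `background + 100` default used by the CLI trades a small positive
area bias for robustness when the enhancement is poor. On noiseless
phantoms (0.5 mm in-plane) graded percentages recover built-in severities
within ≤ 5 points across 30–90%, and the > 70% classification is correct
on noisy phantoms (SD 15 HU) in 20/20 seeded trials.

Segment mapping locates each modelled segment's world-z extent on its
canonical grading path and converts it to that path's arclength; thirds
of the long arteries are equal-arclength splits, and consecutive
intervals share boundaries exactly, so sub-segments partition their
parent artery.

## Diagnostic performance

Segments not depicted by the reference standard or rated in any
non-assessable category are excluded before any statistic and accounted
for explicitly (`2×2 total + excluded = segments offered`, a tested
invariant). Percentages are rounded half away from zero to integer
percent (one decimal for the non-assessable fractions); the rounding rule
is pinned cell-by-cell against a published two-reader peripheral-CTA
reader-study table shipped as package data. Three of its 88 cells are
printed inconsistently with their own numerator/denominator pairs (the
count pairs cross-check against the accuracy cells, so the counts are
authoritative); those cells are flagged in the fixture and the regression
test asserts the count-derived value for them.

The published NPV count pairs are not always equal to `tn/(tn+fn)`
reconstructed from the same row's sensitivity/specificity pairs (the
study apparently computed NPV on a slightly different segment subset);
this module computes NPV from the 2×2 as stated in its contract, which
reproduces the printed overall percentages in three of four strata and
differs by one point in the fourth.

For paired modality comparisons the reference study used generalized
estimating equations in SPSS with unreported link and working
correlation. The contract here is a reproducible substitute: a cluster
bootstrap of the difference in proportions — patients resampled with
replacement (default 10 000 replicates, seeded), two-sided p as
`2·min(P(Δ* ≤ 0), P(Δ* ≥ 0))`. Cluster summaries are put in a canonical
order first, so the p-value is exactly invariant to patient relabelling
and to segment order within patients. Calibration: type-I error 0.044 at
α = 0.05 over 500 simulated null cohorts (40 patients × 20 segments,
accuracy 0.90); power ≥ 90% for 0.93-vs-0.85 at the same size. A GEE
variant (`method="gee"`, exchangeable correlation, robust variance, via
statsmodels) is provided for cross-checking but is not the contract,
since the original's exact settings cannot be known.

## Problem sizes

Test and acceptance workloads are scaled to desk size as the package's
own choice of study conditions: two-leg phantoms 96×96×120 at 1 mm,
single-vessel grading phantoms 64×64×80 at 0.5 mm in-plane, rotational
invariance on 128×128×160, 500 bootstrap null cohorts at 400 replicates.
The library itself is resolution-agnostic; the renderers and tracker
operate identically on clinical-size grids (512×512×2000), only slower.

## Known limitations

* Centroid recentering biases toward the merged lumen at bifurcations;
  a model-based bifurcation detector is out of scope.
* The column-partition rule for overlapping vessels at near-lateral
  angles is a documented reconstruction (nearest projected abscissa);
  the original workstation's compositing is unpublished.
* Stretched/straightened CPR variants, semitransparent volume rendering,
  oblique acquisitions and compressed DICOM transfer syntaxes are not
  implemented.
* The phantom's lesion vocabulary (focal stenosis, occlusion, crescent
  calcification, shell stent) does not cover diffuse disease or
  in-stent restenosis texture.
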