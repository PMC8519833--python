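# Methods

`mammometry` measures breast morphology from textured frontal 3D torso
scans the way a clinician measures it with a tape: distances along the
skin between anatomical landmarks, summarized into a single Symmetry
Index (SI). This note records the models, conventions and numerical
choices behind each stage, what the synthetic phantom does and does not
emulate, and the known limitations.

## The measurement protocol

Fourteen sticker landmarks are marked before scanning: sternal notch
(SN) and xiphoid (Xi) on the midline, and per side the nipple (N),
lower breast pole (LBP, on the inframammary fold), lateral breast pole
(LaBP), medial and lateral upper breast poles (MUBP, LUBP) and the
coracoid process (CP). Seven distances are computed per breast:

| name | endpoints |
|---|---|
| SN_N | sternal notch → nipple |
| LBP_N | inframammary fold → nipple |
| UBP_N | derived upper breast pole → nipple |
| XI_N | xiphoid → nipple |
| LABP_N | lateral breast pole → nipple |
| BREAST_WIDTH | midline point at nipple height → nipple → LaBP |
| IMF_LENGTH | medial fold terminus → LBP → lateral fold terminus |

The upper breast pole (UBP) is not marked. A guideline is drawn through
MUBP and LUBP; the UBP is the intersection of that infinite line with
the plane through the nipple parallel to the sagittal plane, snapped to
the Euclidean-nearest point on the skin (a point off the skin has no
tape-measure meaning). Because the algorithm finds the true
intersection while a human examiner estimates the point on a ruler, the
automatic UBP–N reading is systematically the *shortest* realizable
distance — the package asserts `UBP_N ≤ min(d(MUBP,N), d(LUBP,N))` as an
invariant.

Two endpoint conventions are not fixed by the protocol and are our own,
recorded in the configuration of every run:

* **BREAST_WIDTH** starts at the intersection of the sagittal-plane
  trace on the chest surface with the transverse plane through the
  nipple (the on-surface midline point at nipple height), runs through
  the nipple, and ends at LaBP.
* **IMF_LENGTH** runs from a medial to a lateral fold terminus through
  LBP. The termini come from two optional extra stickers (the phantom
  draws them by default) or from injected surface points; no
  curvature-based fold tracer is attempted.

## Sagittal plane from a frontal-only scan

A 180° scan has no back, so no vertebral landmark is available. SN and
Xi fix the plane's vertical in-plane axis. Those two points plus their
midpoint are collinear and cannot fix a plane by themselves; the missing
degree of freedom is taken from bilateral symmetry: the normal is the
mean left→right vector over the N, CP and LaBP pairs, orthogonalized
against the SN–Xi axis and normalized, with the plane anchored at the
SN–Xi midpoint. The plane therefore contains SN and Xi exactly, and on
a perfectly symmetric subject it coincides with the true mirror plane.
CP participates only here — it stabilizes the normal — and appears in no
distance.

## Sticker detection

Sticker classes are reference colors with a tolerance. Matching runs in
HSV with a hue-weighted distance,

    d² = (w_h · Δh · min(S₁,S₂) · 255)² + (w_s · ΔS · 255)² + (w_v · ΔV · 255)²

with w_h = 6, w_s = 1, w_v = 0.5; the hue term is damped by the smaller
saturation because hue is meaningless for gray. This tolerates the
brightness variation baked into scan textures far better than raw RGB.
Matched pixels form 4-connected blobs; blobs under 5 px are dropped; per
class the largest expected-count blobs survive (ties broken by lowest
pixel index). The default palette is ten evenly spaced saturated hues
(pairwise metric separation > 125 against a tolerance of 45; skin tone
is > 130 from every class). One color encodes one anatomical label;
left/right is resolved geometrically, not by color.

Each blob pixel center is located in the UV atlas (an STRtree over the
faces' UV triangles), expressed barycentrically, and lifted to 3D; the
sticker midpoint is the surface point nearest the 3D centroid of those
lifts. Because detection happens entirely in texture space, it is
exactly invariant under rigid motion of the mesh.

Labeling defaults to scan-derived body axes: up is the Xi→SN direction,
facing is the area-weighted mean surface normal, and anatomical left is
`up × facing`. This makes the whole pipeline equivariant under rigid
motion without any configuration. Explicit axes (with a
`flip_vertical` override for upside-down exports) are available for
scanners with known conventions, and a combined midline color class is
supported, in which case SN vs Xi is decided by height along the up
axis.

## Geodesic distances

A tape measure follows the skin, so distances are over-surface
geodesics (a straight-line mode exists for comparison):

1. every mesh edge receives 3 Steiner points (default);
2. all vertex/Steiner nodes on a face's boundary are joined by straight
   segments, giving the complete intra-face graph;
3. Dijkstra (scipy's sparse csgraph) finds the shortest node path, with
   query endpoints wired as temporary nodes into their containing face;
4. the polyline is shortened by sliding each interior node along its
   supporting mesh edge (red–black coordinate descent, vectorized
   ternary search, early stop at 10⁻⁹ relative improvement per sweep).

Step 4 removes the angular quantization of the node graph: on a planar
mesh the path converges to the exact chord (error < 10⁻¹⁰ in the 3–4–5
benchmark), and on a 10 cm sphere at 0.33 cm edges the great-circle
error is ~0.01%. Paths stay on the surface because each segment remains
inside the face that produced it. Distances are made exactly symmetric
by canonically ordering the endpoint pair before the query. Equal-length
path ties are resolved deterministically by the solver; reruns are
bit-identical.

Mesh geodesics converge under refinement on smooth surfaces (< 0.5%
when halving edge length on the benchmark surfaces). On the phantom the
crease fillet (curvature radius 0.25 cm) is under-resolved at the
default 0.6 cm edges, so absolute values shift by ~1% when the mesh is
refined; the recovery tolerance max(2%, 2 × edge length) absorbs this.

## Symmetry Index and statistics

For each measurement the left/right ratio is `min(L,R)/max(L,R)`; the
SI is 100 × the mean ratio over the included measurements. It is 100
exactly when every pair agrees, strictly decreases when any single
ratio decreases, and is side-swap- and scale-invariant. All seven
measurements are included by default; UBP_N can be excluded
(`--exclude-ubp`), reflecting the clinical practice of dropping the one
measurement whose manual counterpart is estimation-limited.

Manual-vs-automatic agreement uses the Wilcoxon signed-rank test on
per-patient means of left and right ("R + L" convention): zero
differences dropped, tied absolute differences midranked. For up to 25
effective pairs the two-tailed p comes from exact enumeration of the
null (subset-sum generating polynomial over doubled ranks — identical
to summing all 2ⁿ sign assignments, verified against brute force for
n ≤ 12); above that, a normal approximation with continuity correction
and tie-corrected variance. The reported statistic is W = min(W⁺, W⁻).
When every difference is zero the test is reported as undefined (NaN),
never as p = 1. At n = 23 the exact test's attainable size is 0.0484;
2000-replicate simulation reproduces it (≈ 0.05).

Descriptive tables report n, min, max, median and sample SD of the
per-patient (L+R)/2 means per measurement and method, plus per-method
SI rows. The method-comparison table has 8 rows: the seven measurements
and the SI.

## The phantom

Real scans cannot be shipped, so validation runs on a parametric
phantom: a height field z = f(x, y) over the chest wall (x lateral,
y cranial, z anterior, cm), built from an elliptical trunk plus two
spherical-cap mounds. Each mound is a radial bump *relative to the
local trunk height* — `sqrt(r² − d²) − (r − p)`, zero at the crease
radius ρ = sqrt(r² − (r−p)²) — joined through a softplus ramp of width
0.25 cm. The fillet locus is an exact circle in the parameter plane and
stands in for the inframammary fold. The apex height is a fixed
fraction (0.61) of the cap radius, so mounds scale self-similarly; the
asymmetry factor scales the left radius by (1 + factor). Defaults: a
32 × 26 cm cropped frontal field, 12 cm trunk half-depth, 5.6 cm cap
radius, 0.6 cm mesh edges, 18 px/cm texture, 0.6 cm stickers, skin-tone
texture with σ = 4 Gaussian channel noise.

Design choices that matter for testing:

* **Landmarks are exact mesh vertices.** The analytic landmark layout
  (midline points on the sternal line; mound landmarks at fixed angles
  on the crease: MUBP 120°, LUBP 60°, LaBP 0°, LBP 270°, fold termini
  210°/330° from the lateral direction) is resolution-independent, and
  the nearest grid node is *moved onto* each landmark rather than the
  landmark being snapped to the grid. Ground truth therefore does not
  change when the mesh is refined.
* **Mirror-exact symmetry.** The grid has an even cell count laterally
  (a vertex column on the midline) and the quad diagonals are mirrored
  about the midline, so a zero-asymmetry phantom is exactly symmetric
  in mesh, texture layout and ground truth; its ground-truth SI is
  exactly 100.
* **An independent length oracle.** Ground-truth lengths are geodesics
  of the *smooth analytic surface*: path-length minimization over the
  parameter plane (L-BFGS-B with analytic gradients, coarse-to-fine over
  8/16/32 interior points), reporting the densely resampled arc length
  of the optimized path — the raw chord objective undershoots near the
  crease fillet and is never reported. This oracle shares the
  measurement endpoint definitions with the pipeline but none of its
  machinery (no mesh, no graph, no Dijkstra); a dense-mesh Dijkstra
  cross-check on one phantom agrees to ~1%.

What the phantom does *not* emulate: realistic population shape
variation, ptosis, soft-tissue deformation between scans, scanner
reconstruction noise, baked-in shading or specular highlights in the
texture, occlusions, and UV atlases with multiple charts or seams.
Passing the phantom suite therefore demonstrates the pipeline's
geometric and statistical correctness under controlled conditions, not
its robustness to real scanner artifacts.

## Problem sizes and determinism

Default sizes keep a full phantom cycle (generation, ground truth,
detection, measurement) around five seconds: ~4.6 k faces per mesh,
~580 × 470 px textures, ~300 k-edge geodesic graphs. The validation
suite uses ten analyzed phantoms across three asymmetry levels, a
23-scan cohort for structural counts, and 2000 Monte-Carlo replicates
for the Wilcoxon calibration. Every random quantity flows from an
explicit seed: phantom generation and cohorts are bit-reproducible, and
the measurement pipeline itself is deterministic (no randomness at
all), so repeated runs on the same scan produce identical files.

## Known limitations

* Single-chart UV atlases are assumed; stickers split across texture
  seams would fragment into multiple blobs.
* The sticker midpoint is the nearest-surface snap of the blob's 3D
  centroid; on sharply curved skin this can sit a few millimetres from
  the decal's true center (bounded by half a sticker radius in all
  tests).
* Geodesics are approximate (graph + edge sliding), with accuracy set
  by edge length and Steiner density rather than an exact polyhedral
  algorithm; the defaults resolve clinical distances to well under a
  millimetre on benchmark surfaces.
* The Euclidean mode measures chords, not skin distance, and is meant
  only for sensitivity comparisons.
* IMF termini must be marked or injected; there is no automatic fold
  detection.
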