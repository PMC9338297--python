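# Methods

`spiralflow` quantifies the uteroplacental vasculature of perfused
micro-CT specimens: from a co-registered vessel-class segmentation it
extracts a centerline graph, annotates it with sub-voxel radii, computes
spiral-artery morphometry, and estimates total spiral-network conductance
with a network-Poiseuille model. Because ground truth is unknowable for
real specimens, the package ships a synthetic phantom generator whose
geometry, classes and terminal roles are known exactly; every stage is
validated against those phantoms.

## Input model

The unit of analysis is one implantation site: a 3D intensity volume with
isotropic voxel size (μm) plus a label volume with the five-class code
table `{0: background, 1: spiral, 2: radial, 3: canal, 4: uterine}`. The
segmentation itself is produced upstream (expert manual segmentation
assisted by preprocessing); the package provides the preprocessing —
block-mean downscaling (default factor 0.5), isotropic spherical median
filtering (default radius 2 voxels), and a three-class multi-Otsu
pre-classification into background / transitional / vessel over a
256-bin histogram — but treats the final label volume as given.

Coordinates: voxel indices are 0-based; a node at index `i` sits at
`(i + 0.5) * voxel_size_um`. All geometry downstream of graph
construction is in μm.

## Skeletonization

All vessel classes are merged into one binary mask and thinned to a
one-voxel-wide curve skeleton. We use *serial* homotopic thinning: voxels
are deleted one at a time, ordered by Euclidean distance transform
(outside-in; lexicographic tie-break), and only when *simple* under the
(26, 6) foreground/background connectivity pair (Malandain–Bertrand
characterization: one 26-connected foreground component in the
26-neighborhood and one 6-connected background component in the
18-neighborhood touching a face). Curve tips (≤ 1 foreground neighbor)
are never deleted in the final phase. Two phases are used: first the bulk
erodes down to a medial core anchored at distance-transform plateau
maxima; then the core is thinned to curves with endpoint preservation.

Serial deletion makes three properties hold *by construction*: homotopy
preservation (components and cycles of the skeleton equal the mask's,
verified independently via an Euler-characteristic oracle on the cubical
complex), idempotence, and determinism. Parallel subiteration schemes do
not share this guarantee; we found a widely used implementation that
deletes an even-width digital cylinder *entirely* when its axis falls
exactly between voxel columns. Such lattice-symmetric inputs are
degenerate (no real specimen is grid-aligned); the phantom generator
avoids them with a sub-voxel placement jitter, and the serial thinner
degrades gracefully (topology is always preserved) if one is supplied.

Known limitation: blunt tube ends retract by roughly one vessel radius —
an intrinsic property of homotopic thinning, shared by all curve
skeletons. Junction positions are accurate to about one voxel; end
retraction only affects free-ended vessels.

## Graph extraction

Skeleton voxels become nodes; 26-adjacent voxels are linked, with two
cleanups that correct digital artifacts: (i) a diagonal edge is dropped
when a strictly shorter two-edge path connects the same voxels (removes
spurious 3-cycles at staircase corners), and (ii) a chain that returns
26-adjacent to an earlier voxel of itself is shortcut (removes retraced
runs through two-voxel-wide corridors). Segments are maximal chains
between junctions (degree ≥ 3) and terminals (degree 1); junction-free
cycles are anchored at their lexicographically smallest voxel. Each
segment's vessel class is the majority class of its nodes' label-volume
voxels, ties broken by the chain midpoint.

Pruning runs to a fixed point and interleaves three operations:

* terminal spurs shorter than `max(spur_factor × junction radius,
  min_spur_len)` are removed (`spur_factor` 2.0, `min_spur_len` 2 voxels);
* junction–junction links shorter than `max(contract_factor × end radii,
  min_spur_len)` are contracted to a single junction (`contract_factor`
  2.0) — these micro-links are thinning artifacts inside thick junction
  regions;
* junctions reduced to degree 2 merge their two incident segments.

The pipeline supplies provisional radii from the mask's distance
transform before pruning, so both radius-relative rules are active even
though calibrated radii do not exist yet; provisional values are cleared
afterwards. Subnetworks (connected components of segments) with fewer
than 30 segments are removed — phantom networks hold only a handful of
segments, so phantom-driven runs configure this threshold to 1.

To make node-based statistics comparable across specimens, each network
is resampled to exactly 10,000 nodes: the budget is allocated to segments
proportionally to arc length by the largest-remainder method (shared
junction nodes counted once), and nodes are placed at equal arc-length
spacing along each chain. The allocation is exact: the resampled network
always holds precisely the requested number of nodes.

## Radius estimation and recentering

At every node a fan of `n_rays = 36` rays is cast in the plane
perpendicular to the local tangent; each ray marches in 0.25-voxel steps
through the tri-linearly interpolated binary mask and stops at the first
0.5-crossing (linear interpolation of the bracketing samples — the step
that makes sub-voxel output possible). The raw radius is the median ray
length. Tangents are central differences over a ±1.5-voxel arc window
(adjacent resampled nodes are far too close to define a direction).

Node positions are corrected for the staircase artifact before
measurement: the ray-endpoint centroid map is iterated to its fixed point
(≤ 4 iterations, 0.01-voxel tolerance — a single application only halves
the off-axis displacement, which follows from circle geometry: the mean
boundary distance seen from a point offset `d` from the center lies at
`d/2`). Displacements larger than 0.75 voxel are reverted: the staircase
artifact is sub-voxel by nature, so larger drift means the fan latched
onto a neighboring structure (typically a fat feeder vessel near a
junction). Each chain is then smoothed with a ±1-voxel arc-length moving
average (junction nodes pinned). Without the clamp and smoothing,
piecewise-linear lengths of densely resampled chains are inflated by
sub-voxel jitter — every residual wiggle adds length.

Raw radii carry a small resolution-dependent bias, removed by a
three-parameter power-law calibration `true = a·raw^b + c` fitted by
least squares against a built-in suite of noiseless digital tubes of
known radius (2–15 voxels; axis-aligned, face-diagonal and body-diagonal
orientations; the map is expressed in voxel units, so one model serves
any voxel size). The fit refuses clearly unusable data (< 5 pairs, < 3
distinct radii, or raw not increasing with truth on average) and clamps
outside its fitted range. On held-out cylinders of 3–15 voxel radius the
calibrated estimates land within 0.25 voxel of truth for ≥ 95% of nodes
and agree across orientations to ≤ 0.5 voxel.

## Morphometry

Radii (and diameters = 2r) are summarized on a *nodal* basis, lengths and
volumes on a *segmental* basis. Segment length is the piecewise-linear
arc length of the chain; segment volume sums conical frusta
`(π l/3)(r₁² + r₁r₂ + r₂²)` between consecutive nodes. Both integrals use
a chain subset with ≥ 2 voxels of arc spacing: with ~10,000 nodes on a
small network the raw spacing is a tiny fraction of a voxel, and geometric
sums at that density measure position noise, not anatomy; 2-voxel spacing
leaves smooth geometry unchanged (curvature-induced shortening < 0.5% at
the phantoms' coil radii) while removing the noise term. Statistics are
restricted to vessels strictly exceeding 10 μm in radius and length
(nodes by their own radius; segments by mean chain radius and length) and
to the spiral class by default.

## Hemodynamics

Each segment is a chain of laminar Hagen–Poiseuille resistors,
`R_i = 8μ l_i / (π r̄_i⁴)` per consecutive node pair with the
pairwise-mean radius; the segment conductance is the reciprocal of the
series sum. Terminals of the spiral subnetwork are classified by
proximity (default 2 voxels, configurable — phantom feeders overlap their
spiral branches, so junction voxels carry the adjacent class and the
default suffices): radial-adjacent terminals are flow inlets,
canal-adjacent ones outlets, nearer class winning when both are in range
(tie → inlet), neither → sealed wall. The network problem imposes the
pressure gradient (default 1 kPa) between the inlet and outlet
reservoirs and enforces mass conservation at interior nodes; the
resulting symmetric positive-definite sparse system is solved by direct
factorization per connected component (components lacking an inlet or an
outlet carry zero flow; if none has both, the solution reports zero
conductance with a diagnostic rather than raising). Total resistance is
`R = ΔP/Q` with `Q` the summed outlet flow; by linearity `R` is
independent of the applied gradient, and conductance `G = 1/R` is
reported. Interior conservation residuals stay below 1e-10 of `Q`.

The dynamic viscosity defaults to 3.5 mPa·s (typical whole blood at high
shear) and is configurable; group *ratios* of conductance and the
pressure-invariance of `R` do not depend on it, but absolute conductances
scale with `1/μ`.

## Synthetic phantoms

Tubes are rasterized by the center-inclusion rule (a voxel is foreground
iff its center lies within the interpolated radius of the centerline
polyline); foreground/background intensities are 200/20 with optional
Gaussian noise on the intensity volume only — the label volume is the
exact geometry, playing the role of the upstream manual segmentation.

A synthetic implantation site holds one radial trunk (radius 38 μm,
length 420 μm), three helical spiral arteries branching from it, and a
short canal stub at each helix end, inside a 128³ volume at 8 μm voxels.
Spiral tube radii are drawn from U(26, 34) μm (≈ 3–4 voxels, the scale of
mouse spiral arteries at mid-gestation), coil radii U(50, 65) μm, pitch
U(130, 160) μm, winding U(1.5, 2.1) turns. Geometry respects explicit
clearance constraints so that thinning recovers the intended topology:
attachments sit ≥ 120 μm from the blunt trunk ends (end retraction) and
~90 μm apart (junction distinctness); helix sectors are azimuthally
separated; canal stubs are short enough that their skeleton barely
extends the spiral chain. The whole site is jittered by a sub-voxel
offset to avoid lattice-aligned degeneracies.

Two-group cohorts share per-pair random geometry; group B multiplies
every *spiral* tube radius by `group_b_diameter_scale` (default 0.85)
and every spiral arc length by `group_b_length_scale` (default 1.38,
implemented exactly by extending the winding angle at fixed coil
geometry). Feeder vessels (trunk, canal stubs) are identical across
matched groups: the controlled effects model spiral-artery remodeling
specifically, matched feeder anatomy makes feeder-related measurement
contamination cancel in group ratios, and the scaled site still fits the
volume. Per-site
seeds derive deterministically from the cohort seed. The generator's
ground-truth summary (arc-length-weighted mean diameter, mean spiral arc
length) gives the exact target effects: the ratio of group means is 0.85
and 1.38 by construction.

What the phantoms do *not* emulate: CT physics (beam hardening, PSF,
reconstruction artifacts), segmentation error (labels are exact),
vessel taper, elliptical cross-sections, and networks with hundreds of
segments per site. Passing tests therefore demonstrate correctness of
the measurement chain on known geometry, not robustness to segmentation
noise.

## Validation summary (what the test suite computes)

* Skeleton: homotopy (tube / Y / torus), idempotence, thinness, axis
  accuracy on cylinders.
* Graph: segment decomposition examples, cycle anchoring, spur/contract
  pruning fixed point, subnetwork filter (5/29/30/120 → 30/120),
  largest-remainder resampling ({50, 30, 20} @ 100 → {50, 30, 20};
  exactly 10,000 nodes on phantom networks).
* Radius: sub-voxel recovery (≥ 95% within 0.25 voxel on 3–15-voxel
  cylinders, both orientations), calibration identity/offset recovery,
  recentering convergence.
* Morphometry: frustum and filter examples, node-basis vs segment-basis
  semantics.
* Hemodynamics: closed-form single tube (1e-9 relative), series/parallel
  laws, ΔP-invariance, conservation at 1e-10·Q on a 200-segment tree.
* Statistics: exact Mann–Whitney equals brute-force enumeration for all
  n, m ≤ 6.
* End-to-end: on a 6 + 6 cohort (128³ sites) with diameter ×0.85 and
  length ×1.38, pipeline-estimated group effects land within 3
  percentage points of the generator's ground truth and group-B
  conductance is lower in ≥ 5 of 6 matched pairs.

Problem sizes used by the tests and the acceptance script (one 128³ site
per run plus a 12-site cohort; 10,000-node networks) were chosen as
representative desk-scale versions of the full study design.

## Statistical comparison

Groups of per-site values are compared with the two-tailed Mann–Whitney
U-test; the exact null distribution is used for tie-free samples with
n·m ≤ 400, otherwise the midrank/tie-corrected normal approximation with
continuity correction. The original study additionally fit linear
mixed-effects models (litter random effects) for diameter and length;
that analysis is an off-the-shelf model applied to the per-site table
this package produces and is intentionally out of scope here — the
per-site Mann–Whitney comparison is provided for every metric.
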