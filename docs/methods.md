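# Methods

This note documents the models, estimators, numerical choices and known
limitations of `axonmorph`. It is written for users who need to judge
what the package's validated behavior on phantoms does — and does not —
imply about real EM sections.

## Input model

The unit of analysis is a 2D semantic label image of an EM cross-section
with classes background (0), axon lumen (1) and myelin (2), carried with
a pixel pitch in nanometres (8 nm in the reference acquisition setup,
after 2× downsampling from 4 nm; the downsampling kernel in the pyramid
builder is 2×2 block averaging for grayscale and 2×2 majority vote for
labels, with ties resolved to the lowest class code — averaging class
codes would be meaningless). Coordinates are (row, col), 0-based; patch
tilings are half-open so every pixel belongs to exactly one patch.
Lengths are reported in μm and areas in μm².

## Instance extraction

Foreground uses 8-connectivity (background 4), the standard
digital-topology pairing. Lumen components smaller than `min_area_px`
(default 50 px at 8 nm, ≈ 0.0032 μm²) are treated as segmentation
specks; they are dropped but counted in the QC table, so the filter's
effect is always auditable.

Touching sheaths merge into single semantic components. They are split
by eroding the myelin class `k_erode` times (default 2, enough to sever
1–2 px bridges), labeling the surviving remnants as seeds, and assigning
every original myelin pixel to its geodesically nearest seed. The
geodesic assignment is computed with marker-based watershed flooding on
a flat surface restricted to the myelin mask, per semantic component
(flooding order equals geodesic distance from the markers). The
`max_bridge_px` cutoff (default 10 px) discards severed-bridge pixels
that lie far from every seed; the distance used there is Euclidean
distance to the nearest seed pixel, a proxy for geodesic distance that
is exact on the convex-ish sheath geometries this targets.

Erosion can also fragment a single thin ring into arcs. A genuine
bridge split leaves each piece enclosing its own interior, so pieces
that enclose nothing are merged back into the adjacent piece sharing
the longest border, smallest piece first; components whose erosion
leaves no remnant are kept whole. Both rules make an isolated annulus
behave exactly like plain connected-component labeling, which is the
correct limit for the splitting step.

Pairing is topological: a sheath is paired with the axon its hole-filled
region entirely contains. Sheaths containing no axon are flagged
unpaired; sheaths containing several axon components pair with the one
whose centroid is nearest the sheath centroid (the others are flagged);
axons with no sheath are unmyelinated and excluded from metrics.
Membership of an instance in a patch or anatomical subregion is decided
by its axon centroid — deterministic and independent of instance size.
Instances touching the image border are excluded from diameter and
thickness statistics (truncated shapes bias moment fits) but still count
toward density.

## Estimators

**Areas** are pixel counts times the pixel area; **G-ratio** is
`sqrt(A / (A + M))`, strictly decreasing in myelin area, 1 in the
unmyelinated limit, and — because the pixel-area factor cancels —
exactly the square root of an integer count ratio.

**Diameters** come from the ellipse with the same second central
moments as the lumen pixel region. A filled ellipse with semi-axis *a*
has second moment *a²/4*, so the full axis length is 4·√λ for each
eigenvalue λ of the moment matrix; each pixel contributes its own
unit-square variance (1/12 per axis) so small regions are not
underestimated. Collinear (single-row) regions are rejected rather than
assigned a spurious 1-px minor axis. The fit is exactly equivariant
under 90° rotations and translations.

**Thickness, distance-transform estimator** (the primary one, being
shape-agnostic): twice the mean Euclidean distance transform of the
sheath mask evaluated on its skeleton. Two discretization effects act
in opposite directions — the transform measures to background pixel
*centers*, overshooting each continuum boundary by about half a pixel,
while the jagged discrete skeleton sits slightly below the transform's
ridge — and cancel to under half a pixel on analytic annuli (a 20-px
wall measures 19.5–19.7 px across sub-pixel placements), so no
correction is applied by default. The mean (not median) over skeleton
pixels is used, switchable by argument. Broken rings are measured
anyway and flagged.

**Thickness, ellipse estimator**: mean of the semi-major and semi-minor
axis differences between ellipses fitted to the filled outer region and
to the lumen. On constant-thickness elliptical phantoms with aspect
ratio ≤ 2 the two estimators agree within 10%; the ellipse variant
drifts for strongly eccentric or irregular sheaths, which is why it is
secondary.

**Density** is the count of axon centroids per patch divided by the
physical patch area (268.435456 μm² for a full 2,048-px patch at 8 nm;
printed summaries round this to 268). Partial boundary patches keep
their counts but report no density — counts at unequal area are not
comparable.

**Spatial maps** average a metric over instances per patch, mask
patches with fewer than `n_min = 5` instances (tiny-n means are noise),
and z-score the surviving patch means with the population SD; at the
patch counts involved the population/sample-SD distinction is
negligible, and population SD makes the mean-0/SD-1 invariant exact.
When several specimens are mapped, normalization is per specimen.

**Statistics.** Morphometric distributions here are heavy-tailed, so
group comparisons use the two-sided Mann–Whitney U test with midranks.
For tie-free samples with n₁+n₂ ≤ 12 the p-value comes from exact
permutation; otherwise from the normal approximation with tie and
continuity corrections. The cutoff matters: exhaustive enumeration over
every achievable U shows the approximation's worst-case two-sided error
is 0.015–0.088 across all sizes with n₁+n₂ ≤ 12, so only the exact path
meets a 0.01 agreement guarantee there. Shapiro–Wilk is reported as a
gate message only (never an automatic method switch) and subsamples to
n = 5,000 with a fixed seed, since the statistic is outside its
validated range at whole-section instance counts (10⁵–10⁶). No
multiple-testing correction is applied by default, matching raw-p
reporting conventions; Bonferroni and Benjamini–Hochberg adjustments
are available.

## The phantom generator

Phantoms emulate the *label-level* structure of white-matter EM:
non-overlapping irregular elliptical lumens wrapped in annular sheaths,
densely packed by dart-throwing placement with disjoint bounding
circles (≥ `min_gap_px` = 4 px apart, so sheaths are never
8-connected), rasterized at the working pitch. Boundaries are perturbed
by a low-order radial harmonic, r(θ) ∝ 1 + α·cos(kθ+φ) with k ∈ {3,4,5}
and default amplitude α = 0.08; harmonics of order ≥ 3 leave second
moments unchanged to first order, so diameter truth is preserved to
O(α²) ≈ 0.3%.

Two modes exist because the bundled group presets' printed means are
not jointly consistent with a perfect-ellipse model (the ellipse area
implied by the printed diameters is ≈ 0.35 μm² against a printed axon
area of 0.401 μm²), so each validated quantity is generated in the mode
that controls it exactly:

* **area mode** samples axon area A and myelin area M from truncated
  normals; the lumen boundary is numerically normalized to enclose
  exactly A and the outer boundary is its radial scaling by
  √((A+M)/A), so true areas and G-ratio are exact by construction.
  Aspect ratios are drawn from a truncated normal (1.5 ± 0.3, ≥ 1) and
  orientations uniformly — plausible defaults, not published values.
* **geometry mode** samples long/short lumen diameters and wall
  thickness; the sheath is the outward *normal* offset of the lumen by
  the sampled thickness, rendered via the Euclidean distance transform,
  so true thickness is exact even for perturbed boundaries (offset area
  P·t + πt² is recorded as the myelin-area truth).

All positive quantities truncate at ±3 SD and at zero; axon areas carry
an additional 0.01 μm² floor (equivalent diameter ≈ 0.11 μm, the
smallest caliber that carries a sheath), which matters only for the
wild-type preset whose 3-SD band otherwise reaches zero. Area mode
additionally resamples the far-tail (sub-percent for the bundled
presets) of (A, M) draws whose implied wall is below `min_wall_um`
(0.02 μm ≈ 2.5 px at 8 nm): a real sheath is a multilamellar wrap with
a physical minimum width, and thinner walls cannot rasterize as closed
rings. In geometry mode the two diameter draws are sorted per instance
so long ≥ short, which shifts the effective minor-axis mean slightly
below the nominal distribution mean (≈ −0.005 μm for the bundled
presets, well inside the validated tolerance). Identical spec + seed
yields bit-identical masks and truth tables; the gradient variant
plants a row-linear trend either in a shape parameter (re-deriving the
dependent truth columns) or in placement density (with an acceptance
ramp normalized to peak at 1 and a deliberately low canvas fill, since
near-saturation dart-throwing rejects preferentially in dense rows and
would flatten the planted trend).

What the phantoms do **not** emulate: EM gray-scale texture,
unmyelinated axons and organelles, segmentation errors (false splits or
merges from a real model's output), spatially correlated packing, or
sheaths that share boundaries over long arcs. Passing recovery tests
therefore validates the measurement chain given correct semantic
labels; it says nothing about segmentation quality upstream.

## Validation problem sizes

The recovery suites use 1,000-axon phantoms at 8 nm pitch (canvases
around 9,000 px square) for group-mean recovery of G-ratio, thickness
and minor-axis diameter; a 220-sheath phantom with walls uniform over
0.10–0.22 μm for the thickness-error bound; and 16 nm pitch for
structural tests where sub-pixel accuracy is not under test. These
sizes put Monte-Carlo error well below the tolerances being checked
(e.g. SE of the mean G-ratio ≈ 0.003 at n = 1,000) while keeping a full
run in minutes on one CPU.

## Known limitations

* The splitting step assumes sheath bridges are thin relative to walls;
  heavily confluent myelin (long shared boundaries) will under-split.
* The Euclidean proxy in the `max_bridge_px` cutoff can differ from the
  true geodesic distance for strongly concave components.
* Whole-section group comparisons treat the axon as the analysis unit;
  with one specimen per group this is pseudo-replication, and the
  package reports n at both levels but cannot resolve the design
  limitation.
* The ellipse thickness estimator is biased for non-elliptical sheaths;
  it is reported for cross-checking, not as the primary value.
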