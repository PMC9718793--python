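# Methods

This note documents the models, conventions and numerical choices behind
each stage of the toolkit, what the synthetic generators do and do not
emulate, and the known limitations.

## Conventions and units

Meshes are held in millimetres with the occlusal surface toward +Z (the
apicobasal axis defaults to +Z and travels with the mesh).  Height maps are
held in micrometres, image-like: row 0 is the maximum-y row, storage is
row-major, and values are registered at cell centers.  Unit conversion
happens only at I/O boundaries (`read_mesh(units="µm")` rescales to mm).
Feature tables and band transects are CSV with explicit column schemas.

## Missing-data filling

Confocal measurements drop out on steep or non-reflective facets.
Non-measured cells are filled with a radial-basis interpolant of the
nearest measured samples (thin-plate-spline kernel by default, 64
neighbors, first-degree polynomial tail so planes are reproduced exactly).
The kernel is a configuration choice, not a claim about any particular
metrology package.  Filled values are clamped to the measured range ± 10%
of the range so an overshooting spline cannot invent new global extrema.
Measured cells are never modified, which makes the fill idempotent.

## OPCR

- Raster standardisation: `rpt` square rows along the mesiodistal (y)
  extent; cell spacing = extent / rpt; per-cell elevation is the highest
  surface intersection above the cell center (max-z rule), so overhanging
  geometry records the top surface.
- Aspect: direction of steepest descent from central differences; one-sided
  differences at footprint edges.  Bin k is the half-open interval
  [offset + 45k, offset + 45(k+1)), so a boundary aspect lands in the
  higher bin.
- FLAT cells have slope ≤ `flat_tolerance` (default 0, i.e. only exactly
  flat cells) and join no patch.
- Patches are 4-connected components (8-connectivity available); only
  components of ≥ `min_patch_size` cells (default 3) are counted; the total
  across the eight bins is the per-rotation count.
- Eight rotations at 45°/8 = 5.625° increments, averaged.  The rotation
  increment follows the standard rotated-patch-count convention.

This is the 2.5-D (raster) formulation.  Mesh-native 3-D patch counting
gives different absolute values and is out of scope; comparisons should
stay within one formulation.  Aspect values that sit within floating-point
noise of a bin boundary (e.g. a plane dipping at exactly 225°) can split a
patch at the rotation whose boundary they straddle; this knife-edge is
inherent to discretised aspect binning.

## SSFA

- Relative area: the grid is decimated by a step k, each decimated square
  split into two triangles; relative area = Σ 3-D triangle areas / Σ
  projected areas.  The scale reported is the projected area of one
  triangle, k²·dx·dy/2.  The projected total is accumulated by the same
  summation path as the 3-D total so a plane is exactly 1.0.
- Scale series: steps grow by √2 (areas double) from k = 2 up to half the
  region, giving ~10 scales on a 128² region.
- Asfc: OLS slope of log A_rel vs log s over every window of 5 consecutive
  scales; Asfc = −1000 × the most negative slope; ties go to the finer
  window, whose finest scale is Smc.  A non-decreasing curve yields 0.
- epLsar: directions 0°…175° in 5° steps; per direction, parallel transects
  (36 by default) sampled by bilinear interpolation at 1.8 µm segment
  spacing; relative length = Σ√(ℓ² + Δz²)/Σℓ.  Mean lengths are normalised
  to exact proportions (sum 1) and composed on doubled angles because
  orientations are axial; epLsar is the resultant length.  The reported
  direction is the orientation of maximal transect relief; the texture
  (scratch) orientation is its perpendicular, exposed separately because
  the literature is inconsistent about which one is "the" direction.
  The 1.8 µm / 5° defaults are the legacy convention and are configurable.
- HAsfc(9×9): non-overlapping cells, remainder rows/columns dropped at the
  far edges; heterogeneity = median(|Asfc_i − median|)/median, defined 0
  when the median is 0 or all cells agree.  Sub-cells of a 9×9 partition
  support fewer scales than the full region, so the per-cell slope window
  is clamped to the available scale count.
- Absolute SSFA values are convention-dependent (scale series, window,
  segment length); cross-study comparison is only meaningful within one
  implementation.  Published absolute means from other metrology software
  are therefore treated as reference context, not as recomputable targets.

## 2-D microwear

Pits have length:width < 4:1, scratches > 4:1; the undefined boundary case
(exactly 4:1) is classed as a scratch, documented and overridable.  The
macrowear gate tests max(length, width) > 500 µm, since the defining
threshold ("larger than 0.5 mm") does not name a dimension.  Features are
pooled across a tooth's micrographs before means (consistent with
several-hundred-feature per-tooth counts); per-micrograph summaries and
both dispersion readings (SD of pooled features; SD across micrograph
means via the per-micrograph path) are available.  Features crossing the
image border count when their midpoint is in frame.  `detect_features`
reduces connected components of a binary mask to best-fit ellipses
(major axis = length, minor = width); it exists to close the loop on
synthetic micrographs, not to replace operator digitisation.

## Macrowear volumetrics

Volumes use the divergence theorem on consistently wound triangles.  A
crown open only at its base is closed with a fan cap to the boundary-loop
centroid; the loop direction inherited from the face winding keeps the
orientation consistent.  Meshes with more than one boundary loop are
rejected with the loops listed.  Percent volume lost assumes the intact
and worn crowns are size-matched; a worn volume exceeding the complete
volume warns rather than fails.  Facet and occlusal-crown regions are
supplied as vertex masks (they are outlined manually in practice); a face
counts only when all three vertices are inside the mask.  The facet angle
is measured between the facet's total-least-squares plane and the
apicobasal axis (0° = parallel to the axis, 90° = horizontal facet).
Reported coverage and percent-lost values are also emitted rounded to the
printed precision used in comparative tables (integer % or one decimal).

## Band chronology

A band is one dark + light couplet; the boundary CSV records couplet
boundaries only.  Widths are successive boundary differences; the mean is
reported both as the mean of per-band widths and as span/count (identical
for complete transects).  The width trend along the transect is the OLS
slope of width against band index.  Transects not flagged complete always
report their count as a minimum.  The replacement-rate bound applies only
when a fully erupted, essentially unworn functional tooth shows no
replacement germ: mineralisation of the successor has not begun, so the
replacement interval is at least the formation time.

## PCA

`prcomp` conventions: center, scale by sample SD, SVD; sdev = singular
values/√(n−1); proportions = sdev²/Σ.  Loadings are sign-fixed (largest
magnitude entry per component positive) so results are invariant to row
order.  Zero-variance columns are reported by name when scaling.  Group
confidence ellipses (68% normal-theory, the common biplot default) are
emitted as polylines.

## Synthetic generators

- Crowns: cone, hemisphere, ellipsoid with closed-form volumes; a
  horizontal wear cut has a closed-form removed volume, and a target
  removal fraction is solved analytically (cone) or by bisection to
  machine precision.  Optional denticle ornamentation forfeits the closed
  form, in which case truth volumes are measured on the watertight mesh.
- Surfaces: self-affine background by spectral synthesis (amplitude ∝
  k^−(H+1) for Hurst exponent H) normalised to a target RMS, plus stamped
  Gaussian-profile grooves (scratches; von Mises orientations on doubled
  angles) and radial depressions (pits); random missing-data holes.  The
  stamped feature list is the ground truth.
- Feature populations: pit/scratch classes drawn at a nominal pit
  fraction, with ratio distributions strictly inside the class definitions
  so classification recovers the draw exactly; recovery tests then check
  the sampling error against the binomial CI.
- Bands: cumulative widths with optional multiplicative lognormal noise
  (parameterised by CV), linear width trend, and a working/balancing
  width ratio.
- The two-population study-like suite uses pit fractions 0.7267 and 0.8254
  with isotropic scratch orientations, emulating the pit-dominated,
  low-anisotropy regime of browsing taxa.

Same seed, same bits: every generator is a pure function of its spec and a
caller-held generator.  What the generators do **not** emulate: real
enamel/dentine material contrast, operator digitisation bias, confocal
speckle and slope-dependent dropout structure, taphonomic surface damage,
and real crown ornament.  Passing tests therefore demonstrate correctness
of the measurement pipeline on known geometry, not field accuracy on
fossil material.

## Problem sizes

Default test and reproduction runs use 128²–256² height maps, meshes of a
few thousand faces, 10,000-feature populations and ≤ 200-band transects —
sizes at which every stage completes in seconds while leaving the
estimators' behaviour unchanged.

## Known limitations

- 2.5-D OPCR only; no mesh-native 3-D patch counting, DNE or RFI.
- No ISO 25178 field parameters or wavelength filtering before SSFA.
- Automated facet segmentation and image-based band segmentation are out
  of scope; masks and transects are operator inputs.
- Native binary metrology formats are not read; a plain-text matrix or
  XYZ-grid export stands in.
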