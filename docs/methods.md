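# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `osteoslice`, and what its synthetic-data tests
do and do not establish about real scans.

## Data model and coordinate frame

A specimen is a binarized, isotropic voxel stack (slice, row, col) with
the shaft along axis 0, plus metadata: total bone length `L` (mm),
voxel size `a` (mm; default 0.00689, a typical rodent-femur scan
resolution), the distal-end reference slice, and the growth-plate
reference slice (identified manually on the reconstruction — the most
proximal slice with a continuous chondrocyte seam; the package never
detects it).

Percent bone length is anchored at the distal end (= 100%) and
decreases by `100·a/L` per slice moving proximally. Only the distal
part of the bone needs to be scanned; the distal anchor makes frames
comparable across specimens of different lengths. The mapping is
affine and invertible to within one slice.

### Alignment

Instead of rigid co-registration to a reference specimen (a
semi-automated, operator-dependent step), each stack is rotated so the
first principal axis of its foreground voxel cloud coincides with the
slice axis: Rodrigues rotation, trilinear interpolation, re-binarization
at 0.5 (volume-preserving in expectation), iterated up to three times
to a 0.5° residual. Cross-specimen comparability comes from the shared
percent-length grid, not from a shared pose. Consequences: axial spin
about the shaft is unconstrained, so per-slice eccentricity
*orientation* is not comparable across specimens (the eccentricity
magnitude is rotation-invariant). Degenerate inputs (foreground in one
slice plane) are rejected.

## Compartment segmentation

Per slice (2D, matching the slice-wise analysis design):

1. periosteal region = hole-filled morphological closing (disk radius
   `closing_radius_px`, default 3) of the largest connected foreground
   component; the closing is computed with explicit padding because a
   naive closing erodes at the array border;
2. cortex = foreground 8-connected to the periosteal boundary. Bone
   bridging cortex and trabeculae is split by a "bridge cut": the
   cortex is eroded by `bridge_cut_px` (default 2), the surviving core
   re-dilated, and any residue component larger than a few pixels is
   reassigned to trabecular bone. This is the single most
   judgement-laden rule in the pipeline (trabeculae merging into the
   cortex are genuinely ambiguous); the depth is configurable and the
   residue threshold deliberately small so that on trabecula-free
   sections the cortex equals the raw foreground exactly;
3. trabecular ROI = periosteal region minus cortex minus a guard band
   (default = closing radius) measured from the endocortical boundary,
   so endocortical roughness is not counted as trabeculae;
4. trabecular bone = foreground ∩ ROI.

QC: a slice is flagged "open cortex" when hole-filling added no
enclosed cavity *and* the section has convex deficiency > 10% (an
unsealed "C" section, as opposed to a legitimately solid one); a stack
errors out when > 20% of non-empty slices are flagged.

## 2D estimators

Areas are exact pixel counts times `a²`. Perimeters are marching-squares
contour lengths at the 0.5 iso-level of a σ = 1 px Gaussian-smoothed
mask: on a digitized disc of radius 40–50 px a raw binary contour
overestimates the true perimeter by ≈5% (staircase bias), while the
smoothed contour is within ≈0.5%. Contours touching the image border
are left open so structures cut by the field of view contribute no
artificial edges.

- Plate-model trabecular metrics (default, the convention of standard
  2D analyses): Tb.Th = 2·B.Ar/B.Pm, Tb.N = (BA/TA)/Tb.Th,
  Tb.Sp = 1/Tb.N − Tb.Th (the identity holds by construction).
- Local (model-independent) thickness: mean over bone pixels of the
  largest inscribed disc diameter, via descending-radius covering of
  the Euclidean distance transform.
- Annular cortical thickness: Ct.Th = 2·Ct.Ar/(Ps.Pm + Ec.Pm).
- Polar moment: J = a⁴·(Σᵢ rᵢ² + n/6) about the section centroid; the
  n/6 term is the summed per-pixel self-moment (a unit square about its
  centre), which makes the single-pixel case well defined and removes a
  small systematic underestimate.
- Eccentricity: √(λ₁/λ₂) of the second-central-moment matrix of the
  filled periosteal section (= semi-axis ratio for an ellipse, ≥ 1).

Degenerate slices (no bone, no ROI, empty cortex, saturated ROI) yield
zeros plus a flag, never NaN, so per-slice tables stay rectangular.

## Profiles and Trabecular Extent

Native distributions (one sample per slice) are cubic-spline
interpolated onto the shared 1% grid (trabecular window 60–100%,
cortical 40–80%) for cross-specimen statistics; no extrapolation
(half-a-native-step slack at the window ends), no smoothing.

Tb.E crossings are located on the *native* profile — "first
occurrence" is resolution-sensitive, so the coarse grid is never used
for it — by scanning proximally from the growth-plate reference and
linearly interpolating between the bracketing slices. Conventions:
thresholds never reached are reported as the full-range distance with a
`censored` flag (kept out of group tests, with logged counts, rather
than NaN); a threshold already above BA/TA at the reference level
yields 0 with the same flag. Whether sub-slice interpolation matches
other implementations that snap to whole slices is unknowable; the
difference is bounded by one slice (6.89 µm at native resolution).

## 3D estimators

- BV/TV: voxel counts.
- Bone surface BS: marching-cubes mesh area at the 0.5 iso-level of a
  σ = 1 px smoothed volume (same rationale as in 2D; measured sphere
  BS/BV error ≤ 0.4% at r = 12–20 px), *without* padding, so bone cut
  by a VOI face is left open instead of capped — cut faces are not
  bone surface.
- Direct thickness (Tb.Th, Ct.Th) and separation (Tb.Sp): volume-weighted
  mean maximal-inscribed-sphere diameter, descending-radius EDT
  covering on the native grid. The distance transform measures to
  background voxel *centres*; with structures rasterized about integer
  voxel centres the bias is below 2% for features ≥ 6 px (a 2× linear
  upsampling variant was evaluated and rejected: it rounds corners
  inward and biases thickness low).
- Tb.N = (BV/TV)/Tb.Th (plate-model number, the common vendor
  convention).
- Tb.Pf = (S₁ − S₂)/(V₁ − V₂) with surface/volume before and after one
  dilation by a 3×3×3 structuring element; positive for convex
  (rod-like), lower/negative for concave (plate/network) structures —
  interpreted as an ordering, not an absolute scale.
- Euler characteristic χ = V − E + F − C of the cube complex of
  foreground voxels (26-connected foreground / 6-connected background
  duality); Conn.D = (1 − χ)/VOI volume. Verified against known Betti
  numbers (ball 1, solid torus 0, two balls 2, hollow shell 2).
- uPi = Tb.Th(direct)/(2·BV/BS): the plate model predicts
  2·BV/BS = thickness for an ideal plate, half the diameter for an
  ideal rod, so uPi ≈ 1 and ≈ 2 respectively; deviations upward mean
  rod-dominated architecture.
- Cortical VOIs: Ct.Th is direct 3D; areas, J and eccentricity are
  per-slice values averaged over the VOI (chosen over a single
  whole-VOI fit; for a uniform tube the two coincide).

VOI presets: metaphyseal trabecular 81–85%, epiphyseal trabecular
93–97%, diaphyseal cortex 58–62%, metaphyseal cortex 81–85%, plus a
76–80% metaphyseal variant for users who prefer a more proximal
window.

## Statistics

Equal-variance Student t-test for independent samples at every grid
point (Welch available behind a flag), means ± SE (SD/√n), signed and
absolute differences, and p-bands on half-open intervals with
boundaries at .05/.01/.001/.0001 (p = .05 is non-significant; p = .01
falls in the .05 band). No multiple-testing correction is applied
across grid points by default — the per-point tests are reported as a
map, and a 41–61-point grid implies that many tests; a Holm option
exists for family-wise control. Normality screening uses
Anderson–Darling and Lilliefors (KS with estimated parameters; the
plain KS against a fully specified normal would be anti-conservative).
Zero-variance grid points degenerate to p = 1 (equal means) or the
smallest positive float (different means), flagged rather than NaN.

## Synthetic phantoms

The generator emulates a distal long-bone segment: per-slice elliptical
annulus cortex with piecewise-linear outer/inner radii (total area
growing and cortical area shrinking distally, as in a metaphyseal
flare), optional trochanter-like bump, equal-area elliptical sections
(so Ct.Ar is ratio-independent and eccentricity equals the imposed
ratio), and a trabecular lattice — parallel plates or a square rod
grid along the shaft — clipped to the medullary cavity with a margin
larger than the segmentation guard band.

The lattice area fraction targets an analytic profile: an epiphyseal
plateau distal of the growth plate and a linear decay (`density_decay`
per slice) proximally. The decay is realized by pruning whole lattice
elements in a fixed seeded order, included greedily while the realized
area is below the slice's target area — so BA/TA tracks the target to
within one element and the decline is carried by falling trabecular
*number*, not thinning. Ground truth records both closed-form section
values (ellipse areas, perimeters via complete elliptic integrals,
polar moments, plate-model thickness) and the exact voxel counts of
what was rasterized; the two are kept separate because rasterization
itself carries percent-level bias.

Default phantom conditions are a deliberately scaled-down study:
voxel size 0.05 mm, ~310 slices spanning the distal ~42% of a 36.81 mm
bone (the nominal rodent femur length), lattice feature size 6 px,
period 15 px (peak BA/TA 0.40, epiphyseal target 0.35), decay 0.004 per
slice. At full scan resolution the same geometry would be ~22,000
slices; the scaled frame exercises identical code paths with identical
percent-axis semantics. Feature sizes are kept ≥ 6 px so rasterization
error stays inside the documented tolerances (≤3% areas/fractions, ≤5%
thicknesses).

Group simulation operates at two levels: *profile level* draws
per-specimen, per-grid-point mean-preserving lognormal noise
(σ = √ln(1+CV²)) around the analytic curves, with multiplicative effect
bands applied to one group — this is what the statistical calibration
and recovery simulations use (1000+ independent null points run in
seconds); *voxel level* generates full phantom cohorts with mild
geometric variation for end-to-end runs. Per-point independent noise
means profile-level simulations do not model the along-axis
correlation real specimens have; calibration results are per-point
properties and transfer, but joint (band-level) error rates on real
data will differ.

## What the tests do and do not show

The validation establishes that the estimators recover closed-form
truth on ideal geometry at realistic feature sizes, that the statistics
are calibrated under their own model, that imposed site-specific
effects are localized to within the grid resolution, and that the
pipeline is deterministic end to end. It does not establish robustness
to segmentation-threshold choices upstream of the package (input is
already binarized), to heavily damaged cortices (beyond the QC flags),
or to the vendor-specific details of the original interactive
workflows the automated alignment and segmentation replace; parameter
defaults here cannot be claimed identical to any vendor macro.
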