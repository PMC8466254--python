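# Methods

## Problem setting

In static computer-assisted implant surgery (sCAIS) a surgical guide is
manufactured from a virtual plan made on a CBCT volume that has been
registered to a digital dental cast. Postoperatively, the placed implant is
compared with the plan. This package models the measurement chain — rigid
registration, deviation metrology, and the group statistics — and provides a
synthetic cohort generator so the whole chain can be exercised and
calibrated without clinical data (CBCT volumes and scanned casts are
identifiable and not publicly shareable).

## Deviation metrics

An implant fixture is reduced to two points, the platform (coronal) center
and the apex center, in one fixed right-handed millimetre frame. With
planned axis **a** (unit vector platform→apex) and center displacement
**d** = placed − planned:

- global deviation = ‖**d**‖ (at platform and at apex);
- depth deviation = **d**·**a** at the platform, signed, positive = deeper
  (apical); reports may fold it to |depth|;
- lateral deviation = ‖**d** − (**d**·**a**)**a**‖ at platform and apex;
- angular deviation = arccos of the clamped dot product of the two unit
  axes, in [0°, 180°].

Lateral deviation is implemented as the perpendicular *component* of the
center-to-center displacement (not the intersection of the placed axis with
the planned-level plane). This decomposition convention makes
global² = lateral² + depth² exact at the platform, matches common metrology
practice, and is enforced to 1e-9 in tests. Apex metrics use the actual
placed apex center; with planned and placed fixtures of equal length the
difference from axis-projection conventions is negligible, and actual
centers are what a postoperative scan yields. All six metrics are invariant
under a common rigid motion of both fixtures; distance metrics scale
linearly under uniform scaling while the angle is unchanged.

Degenerate fixtures (platform = apex) are rejected. For tiny angles the
arccos evaluation limits attainable precision to about 1e-6 degrees; tests
use that tolerance where an exact zero angle is expected.

## Registration

The cast→CBCT superimposition is the absolute-orientation problem
min Σ‖R·sᵢ + t − tᵢ‖² over proper rotations, solved in closed form:
centroid subtraction, cross-covariance SVD, determinant correction so a
reflection is never returned (including planar and adversarial
configurations), equal weights (no weighting information exists for
operator-picked points). At least three correspondences are required;
collinear sources (smallest singular value < 1e-8 × largest of the centered
configuration) are rejected as ill-posed because a rotation about the line
is unconstrained. The solution is validated against exact recovery of
random transforms (1e-9) and against a generic numeric optimizer on noisy
instances (1e-6).

Diagnostics follow the fiducial-error vocabulary: FRE is the post-fit RMS
residual; TRE at a target x is ‖(R̂x + t̂) − (Rx + t)‖ against the true
transform, available only in simulation. `lateral_axial_tre` resolves the
TRE displacement at an implant center against the planned axis, because the
buccal–lingual registration-error pathway manifests as *lateral* implant
error.

Pre/postoperative CBCT matching is the same operation on jaw landmarks; no
separate code path, and no ICP/surface refinement is modelled (the clinical
software's operators pick discrete corresponding points).

## Synthetic cohort generator

The generator is a declared surrogate; none of its distributions are claims
about the clinical data-generating process.

**Geometry.** Surface landmarks lie on a parabolic arch (radius 25 mm) in
the occlusal plane, with the outward in-plane normal of the arch recorded
per point as the buccal–lingual direction. Fiducials sit on a
radiographic-template surrogate 4 mm outside the arch and 4 mm above the
plane. Planned implants occupy six fixed arch sites with axes within 5° of
the occlusal direction, length 10 mm. The true cast→CBCT transform is a
seeded rotation ≤ 5° and translation ≤ 10 mm per axis.

**Noise model.** Cast-side (source) points are noise-free — desktop model
scanners are an order of magnitude more precise than CBCT, and the clinical
literature attributes registration difficulty to CBCT-side artifacts.
CBCT-side fiducial localization noise is isotropic Gaussian
(σ = 0.1 mm). Surface-point noise is anisotropic: σ = 0.1 mm in-plane and
σ × 3 along each point's buccal–lingual normal, emulating metal
streak artifacts, which extend from the crown and project buccal–lingually,
smearing exactly the surfaces an operator must match.

**Placement model.** The planned implant is mapped through the *estimated*
transform — i.e. displaced from its true position by the TRE field at
platform and apex, which preserves the angular component of
misregistration — then perturbed by guide mechanical error: lateral offset
(σ = 0.3 mm per perpendicular axis), depth offset (σ = 0.4 mm), and a tilt
(σ = 1.5°) about a random perpendicular axis through the platform. These
sigmas are surrogates for sleeve tolerance and guide flexure; their true
magnitudes are not separable from published data and are documented here as
assumptions.

**Design and effects.** The default design reproduces the margins of the
unbalanced in-vivo study layout: 56 fully guided implants with
registration-method split 21/35, jaw split 23/33 and guide-support split
28/20/8, realised as a fixed 2×2×3 cell table consistent with those
margins. Group effects are mechanistic: the dental-surface group registers
on artifact-inflated surface landmarks while the fiducial group uses
markers; maxillary and distal-extension guides multiply the guide sigmas
(less stable support). The effect magnitudes were calibrated once against
the published group contrasts — surface-noise scale 4.1 reproduces the
≈ 0.32 mm lateral-apex contrast between registration groups, and guide
multipliers 1.95 (maxilla) and 1.9 (distal extension) reproduce the ≈ 1.66×
published lateral-platform group-mean ratios — and then frozen.
`GroupEffects.null()` switches every contrast off for calibration runs.

**Independence.** Each simulated implant receives its own registration-noise
and guide-error draws. This mirrors the analysis assumption that implants
are independent observations (the clinical analysis treats them so, though
implants within a patient share a registration in reality — a limitation of
both the study design and this surrogate). Sharing one registration
realization per group would induce cluster correlation and invalidate the
type-I-error calibration that the null generator is required to satisfy.

**What passing tests show.** Calibration results on this generator
(type-I error ≈ 5%, uniform null p-values, mechanism recovery) validate the
*pipeline* under Gaussian, independent, well-specified conditions. They do
not establish robustness to the skewness, patient-level clustering, or
operator effects of real cohorts.

## Statistics

- Descriptives: sample SD (n−1), quartiles by linear interpolation between
  order statistics (the common statistical-package default).
- Two-sample t: pooled Student by default, Welch by flag, two-sided, from
  raw samples or (mean, SD, n) summaries. The default is pooled because the
  published lateral-apex registration contrast reproduces from summary
  statistics under pooled (p ≈ 0.0461 vs printed 0.0464) while the jaw
  contrast reproduces better under Welch (0.0025 vs 0.0023); the source
  analyses are ambiguous on the variant, so both are exposed. Two groups
  with zero variance and equal means return p = 1 by convention.
- One-way ANOVA: classic between/within decomposition; Tukey–Kramer
  pairwise comparisons use the studentized-range distribution with the
  unequal-n standard error.
- Factorial ANOVA: OLS with sum-to-zero contrasts and partial (type III)
  sums of squares — the appropriate convention for unbalanced designs, and
  equal to sequential SS on balanced ones (tested). Interaction terms with
  empty cells are dropped with a warning. Factor columns are renamed
  internally so user column names cannot collide with formula syntax.
- Sample size for a two-group t test: smallest equal n per group whose
  exact noncentral-t power reaches the target. At d = 0.5, 80% power,
  α = 0.05 two-sided this gives n = 64 per group; published sample-size
  statements of ~30 for those inputs do not match any standard two-sample
  formula, and the calculation here is not forced to agree.
- No multiplicity correction across the six outcome metrics by default
  (mirroring field practice); a Bonferroni flag is available.

## Problem sizes and numerical choices

Monte-Carlo checks use fixed seeds and these sizes, chosen to give
comfortable Monte-Carlo error on one CPU: 2000 cohorts for type-I-error
calibration (binomial SE ≈ 0.5% at 5%), 500 cohorts for the KS uniformity
check of factorial term p-values, 1000 replicates for TRE orderings and the
artifact-mechanism contrast, 10⁴ pairs for the decomposition identity. The
mechanism contrast is computed with guide error off so that the measured
lateral apex deviation isolates the registration pathway; with guide noise
at its defaults the same ordering holds but the contrast at base sigma is an
order of magnitude smaller than the guide noise and would need far more
replicates to resolve.

Exit codes in the CLI: 0 success, 2 configuration/parse error, 3 ill-posed
computation. All CSV numerics are written with full precision, decimal
point, mm and degrees.

## Known limitations

- No mesh metrology or DICOM/STL handling: fixtures are two points, and
  registration consumes pre-extracted landmark coordinates.
- No patient-level random effects; implants are independent by construction.
- Gaussian surrogates everywhere; real deviation distributions are skewed
  norms of correlated components.
- The guide-error and registration-error magnitudes are assumptions, not
  estimates; only their calibrated group contrasts are tied to published
  values.
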