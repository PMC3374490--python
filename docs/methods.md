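# Methods

## Model and assumptions

The sclera is treated as an axisymmetric thin membrane: a revolved
ellipsoid whose axis of revolution runs through the center of the optic
nerve head (ONH) to the holder fixture. A superior-view camera sees one
meridian of this surface as a planar edge; digital image correlation
(upstream of this package, and out of its scope) supplies the tracked
2D positions of edge points at a reference pressure P0 and at each
inflation step. Under axisymmetry, the 2D edge kinematics determine the
full surface deformation in the meridional (Φ) and circumferential (θ)
principal directions; shear strain and bending are neglected, and
membrane stress is taken constant through the wall thickness, which
this analysis does not use.

Per eye the chain is:

1. **Ellipse fit** (`edge_geometry.fit_ellipse`): direct algebraic
   least squares with the ellipse-specific constraint (Halir–Flusser)
   for the starting value, refined by geometric (orthogonal-distance)
   Levenberg–Marquardt. The geometric stage makes the fit exactly
   invariant under rigid motions and stable at the sub-micrometre noise
   scale on millimetre-sized eyes; the reported residual is the rms
   orthogonal distance.
2. **Meridian parameterization** (`parameterize_meridian`): each point
   receives its ellipse angle (eccentric anomaly, counterclockwise from
   the major axis — the natural parameter an angle-polynomial fit
   refers to), its reference arc length s via the closed-form
   incomplete-elliptic-integral perimeter (so |dX/ds| = 1 analytically),
   its meridian angle Φ from the axis of revolution, and the reference
   diameter D(s) = twice the perpendicular distance to the axis. The
   axis is the ellipse axis closest in direction to the camera's
   vertical (e2), through the ellipse center.
3. **Regions**: the traced ONH-to-fixture arc is split into five
   arc-length bands R1…R5 (equal by default, configurable fractions).
   The exact angular extents of the regions are not prescribed by the
   protocol, so the equal-band default is a documented assumption.
   R1 (peripapillary) and R5 (at the fixture) are excluded from
   analysis because the membrane assumptions fail near the ONH and the
   glued holder.
4. **Displacement fit** (`kinematics.fit_displacement`): u = x − X per
   matched point; each Cartesian component is least-squares fitted to a
   4th-order polynomial in the reference ellipse angle, independently
   per pressure step. Strains use analytic derivatives of the fit,
   chained through the analytic angle-to-arc-length derivative of the
   reference ellipse — never pointwise numerical differentiation of
   noisy data. With s the reference arc length, the meridional
   Green–Lagrange strain ½(|dx/ds|² − 1) equals
   dX/ds·du/ds + ½ du/ds·du/ds exactly; both forms are implemented by
   the same expression. Circumferential strain is ½[(d/D)² − 1] with
   d = twice the axis distance of the displaced point. Strains are
   referenced to the P0 configuration, i.e. to a pre-stressed state;
   this is documented, not corrected.
5. **Statics** (`shell_statics`): per step, a fresh ellipse is fitted
   to the deformed trace; the meridional curvature radius r_m follows
   from the conic closed form and the transverse radius from the
   shell-of-revolution construction r_t = r·|P′|/|P′·â| (r = distance
   to the axis â). Equilibrium gives n_Φ = p·r_t/2 and
   n_θ = p·r_t(2r_m − r_t)/(2r_m). This assignment of the two radii is
   fixed by the cylinder limit (r_m → ∞ must give the hoop force p·R
   and axial force p·R/2) and by the identity n_Φ/r_m + n_θ/r_t = p;
   descriptions that swap the two radii verbally are statically
   inconsistent. Pressures are converted at 1 mmHg = 133.322 Pa;
   resultants are reported in N/m.
6. **Evaluation and averaging**: strains and resultants are computed at
   8 equally spaced interior arc-length locations spanning R2–3 and 4
   spanning R4, then averaged to one stress-resultant–strain curve per
   region per step.
7. **QC**: a step whose displacement-fit rms exceeds 3× the 0.46 µm
   tracking noise floor is invalid ("poor displacement fit"); above
   50× it is treated as broken point correspondence. An eye with more
   than half its steps invalid is excluded, with reasons recorded.
   Anchoring the thresholds to the stated measurement error keeps the
   exclusion rule interpretable.
8. **Groups** (`aggregate_groups`): per (region, quantity, step), two
   groups are compared with Mann–Whitney U, three or more with
   Kruskal–Wallis, Bonferroni corrected across pressure steps within
   each (region, quantity) family.

Left eyes are mirrored in e1 to the common nasal–temporal orientation
before analysis; since every stage is rigid-motion invariant this only
fixes the labeling convention.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| reference pressure P0 | 7 | mmHg | middle of the 6–8 mmHg unwrinkling range |
| analyzed steps | 10, 14, 18, 22, 26, 30 | mmHg | loading ramp analyzed from 10 to 30 mmHg; the exact step list is configuration, not constant |
| polynomial degree | 4 | – | the displacement-fit order of the analysis |
| evaluation points | 8 (R2–3) + 4 (R4) | – | per-region sampling of the curves |
| noise floor | 0.46 | µm | displacement error budget: 0.36 (pixel calibration) + 0.10 (correlation) |
| QC factors | 3× / 50× / 50% | – | step invalid / correspondence broken / eye excluded |
| mmHg → Pa | 133.322 | – | unit convention; mm internally, µm accepted with a unit flag |
| ratio epsilon | 1e-4 | strain | anisotropy ratios undefined (NaN) below this denominator |

## The synthetic-data generator

Ground truth needs a *known deformation*, not a constitutive solve, so
the generator prescribes kinematic maps on a revolved ellipsoid
(default semi-axes 1.7 mm equatorial — half the ~3.4 mm caliper width
of an adult mouse eye — and 1.9 mm polar; visible arc from 0.25 rad off
the ONH pole to π/3 before the fixture; 40 tracked points, a documented
guess since the tracked-point count is not part of the protocol). Three
deformation families, all scaled by a load factor
g(p) = ((p−P0)/(30−P0))^γ with γ = 0.5 by default (sublinear strain
growth mimics collagenous stiffening):

- **ellipsoid**: the deformed shape is again an ellipsoid with scaled
  semi-axes. Deformed-trace ellipse fits are then exact, which makes
  this the reference family for curvature/stress-resultant checks
  (agreement to ~1e-8 N/m) and the default for cohort studies.
- **stretch**: λ_Φ(t), λ_θ(t) prescribed as polynomials in the meridian
  parameter; the deformed meridian is reconstructed from the arc-length
  ODE z′ = −√(λ_Φ²|X′|² − r′²), with curvatures in closed form from the
  analytic derivatives. Unrealizable or contracting (λ < 1) fields are
  rejected as unphysical.
- **displacement**: quartic-polynomial displacement components in the
  meridian parameter — exactly the function class of the analysis's
  4th-order fit. On this family the noise-free pipeline recovers truth
  strains to round-off (< 1e-6 asserted; ~1e-15 observed), so it
  isolates estimator defects from representation bias.
  `random_displacement_field` draws physical members by projecting a
  randomized ellipsoid-scaling map (with mild angular modulation and a
  small rigid axial shift) onto quartics and validating λ ≥ 1.

On the other two families the quartic representation bias of the
method itself is ~1e-4 in E_Φ (e.g. 8.6e-5 for a uniform 5% dilation of
a circular meridian) and ~1e-6 in E_θ; tests on those families use
tolerances of that order. This bias is intrinsic to the
polynomial-displacement method, not to this implementation.

Truth strains are E = (λ² − 1)/2 per direction; truth resultants come
from the exact deformed curvatures through the same equilibrium
formula, which satisfies the normal-equilibrium identity to machine
precision by construction — the identity check therefore validates the
curvature computations, and the independent validation of the formula
itself is the sphere/cylinder limits and the finite-difference
curvature oracle.

Measurement noise is i.i.d. Gaussian per coordinate on every trace
(reference included), sd 0.46 µm by default. With this noise the
200-replicate mean absolute strain error of the pipeline is ~2.8e-4
(meridional) and ~1.4e-4 (circumferential); the regression tests freeze
bounds of 6e-4 and 3e-4 (about twice the measured means) so they fail
on genuine degradation, not on seed luck.

Cohort simulation adds biological variability chosen once as realistic
for inbred mouse eyes: a per-eye lognormal stretch-amplitude multiplier
with 20% CV and 2% CV on the semi-axes. The default full-load stretch
scales (1.02 equatorial / 1.018 polar) put peak strains near 2–3%, the
scale seen in murine inflation data. A cohort-wide
`circumferential_factor` scales the equatorial stretch amplitude to
emulate a circumferentially stiffer group; 0.7 (a 30% reduction) is
detected circumferentially at every analyzed step with n = 20/20 eyes,
while identical null groups essentially never reach familywise
significance (the per-eye amplitude induces nearly identical ranks
across steps, so the effective number of independent tests is small
and the Bonferroni-corrected familywise rate stays well under nominal).

Cohort-level generators: IOP series draw a fellow eye about a 12.2 mmHg
baseline (tonometry noise sd 2 mmHg) and a treated eye adding an
exponentially decaying elevation (peak 8 mmHg, τ = 12 days; ~92
mmHg·days over six weeks, within the reported cohort-mean range); axon
sampling draws per-field counts around the surviving density, with
dispersion 0 meaning deterministic and dispersion d > 0 a
gamma-modulated Poisson (rate CV d, pure Poisson as d → 0+);
morphometry draws Gaussian cells from a built-in table of group
means/SDs for the two mouse strains at 4 and 17 months, control and
glaucoma.

What the generator does **not** emulate: viscoelastic creep and the
ramp-hold/recovery segments (only the loading ramp is modeled), contact
mechanics at the fixture, regional scleral thickness (the analysis does
not use thickness), image-correlation failure modes other than
broken correspondence, and non-axisymmetric real-eye geometry. Passing
tests therefore demonstrate correctness of the estimator chain under
the stated model, not accuracy of the thin-shell idealization for real
tissue.

## Metric conventions

- **Positive integral IOP** is read as the integral of the positive
  part of the pointwise treated-minus-fellow difference — not the
  difference of the two total areas — matching its use as a cumulative
  exposure and guaranteeing non-negativity. Trapezoids on the union of
  measurement days restricted to the overlapping range; sign crossings
  located by linear interpolation; no extrapolation.
- **Axon counts**: mean sampled field density × individual nerve area,
  rounded to the nearest axon; percent loss is relative to the pooled
  fellow-eye mean count and may be negative.
- **Rounding** for comparison against coarsely printed percentages:
  round half away from zero (`round_half_away`), one decimal for
  percent metrics unless integers are quoted.

## Numerical choices

- Ellipse arc length and its inverse use incomplete elliptic integrals
  (`scipy.special.ellipeinc`) and Brent root finding (xtol 1e-13) — no
  quadrature error in the parameterization.
- Point-to-ellipse projection is a damped Newton iteration on the
  stationarity condition of the squared distance; traces lie close to
  their fitted curve, where the projection is unique.
- The displacement least squares uses a plain Vandermonde solve; the
  ellipse angle spans ~2.3 rad, where a degree-4 basis is well
  conditioned.
- Strain evaluation refuses extrapolation outside the traced arc.
- Transverse curvature is undefined where the meridian tangent is
  normal to the axis (at a pole); this raises rather than returning a
  limit, and the analyzed regions never include a pole.
- Batch outputs are written with `%.17g` floats and parsed back with
  round-trip precision, so reruns with identical config and seed are
  byte-identical; output tables carry dataset id and a SHA-256 config
  hash prefix as provenance.

## Open design points resolved here

- Whether displacement polynomials are fitted per step or jointly:
  independently per step (matches the stated workflow; avoids coupling
  steps through a shared fit).
- Whether curvatures come from per-step deformed ellipse fits or from
  displaced points directly: per-step deformed ellipse fits (smooths
  tracking noise; exact on the ellipsoid family).
- The identity of the analyzed pressure steps: configuration with
  default {10, 14, 18, 22, 26, 30} mmHg.
- Edge traces model a single ONH-to-fixture half-meridian; under
  axisymmetry the second (mirror) silhouette arc adds no information,
  and a two-sided trace can be supplied as two eyes of one animal.

## Known limitations

- The quartic displacement basis biases E_Φ at the 1e-4 level for
  deformations outside its span; this is the method's own bias and is
  quantified, not removed.
- Stress resultants inherit ellipse-model error when the deformed
  meridian is not elliptical (~1e-5 N/m on smooth synthetic fields).
- Strains are relative to the pre-stressed P0 state.
- The group tests treat eyes as independent; the both-eyes robustness
  check shows agreement within 1 SE on symmetric synthetic data but is
  not a substitute for animal-level modeling.
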