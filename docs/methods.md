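# Methods

This note documents the models implemented in `ratknee`, the choices made
where the design was genuinely open, and what the synthetic cohort can and
cannot demonstrate.

## Synthetic cohort

The cohort emulates 10 hind limbs from 5 animals (bilateral; left limbs are
generated in left orientation and mirrored to a right-side representation,
`is_mirrored` set).  All specimens deform one fixed template grid, so vertex
`i` corresponds across the cohort by construction.  This replaces the
deformable mesh registration of an imaging pipeline with identity
correspondence — a deliberate stand-in: the package validates the shape
model and solver machinery, not a registration algorithm.

Geometry (right representation; +X lateral, +Z femur→tibia, origin at the
epicondylar midpoint; mm throughout):

* **Femoral condyles** — bands of spheres (radius 2.6 mm) centred on the
  epicondylar axis, spanning 0–160° of sagittal arc so the 80° standing pose
  faces the plateau symmetrically.  Because the bearing surface is a sphere
  centred on the flexion axis, posing is geometrically exact at any flexion
  angle.
* **Tibial plateau compartments** — concave dishes (planform radius 2.0 mm,
  centres ±2.3 mm) defined as the condylar sphere profile offset distally by
  the summed cartilage thickness plus a paraboloid mismatch, so the initial
  cartilage-to-cartilage gap over a compartment is exactly
  `g(r) = κ r²/2`.  The conformity `κ` is the single number controlling
  contact area at a given load.
* **Shafts, patella** — cylinders and a closed ellipsoid; carried through
  the shape model but unloaded (patellofemoral contact is out of scope).
* **Landmarks and ligament attachments** are dedicated marker vertices, so
  they ride through mirroring, posing, alignment and PCA reconstruction
  automatically.

Mesh resolution: 0.3 mm average element size for bones, 0.2 mm for the
patella.  The articular contact patches are refined to 0.08 mm: the
foundation solver resolves cartilage compressions of a few micrometres, and
at 0.3 mm the chord sagitta of a faceted sphere (≈6 µm) would dominate the
gap field; at 0.08 mm the worst-case facet error is ≈0.5 µm.  Articular
slopes were kept below ≈1 (condyle radius well above the plateau planform
radius) because facet error grows as 1/cos of the surface slope.

Nominal dimensions are not reported for the original specimens, so they were
set to plausible rat-knee scale and tied to published group outcomes: the
medial conformity is chosen so that the uniform-scale calibration (below)
lands near scale 1 with the contact patch well inside the plateau (contact
that reaches the patch rim saturates the area at the patch size and breaks
the size–area scaling the calibration relies on), and the lateral conformity
is set from the published neutral medial:lateral contact-area ratio
(κ_lat = 1.175 κ_med).

**Variation model.**  Six parameters vary multiplicatively: global scale,
condyle spacing, medial and lateral conformity, cortical and
articular/subchondral density.  Between-animal SDs (2 %, 1.5 %, 10 %, 10 %,
5 %, 5 %) and smaller within-animal SDs (0.5 %, 0.4 %, 3 %, 3 %, 1 %, 1 %)
give limb pairs that are near-identical within an animal and distinct across
animals, qualitatively matching bilateral rodent anatomy.  Each animal and
limb consumes an independent seeded substream, so cohorts are reproducible
and limbs are statistically exchangeable.  The density field is two-level
(cortical shell ≈1.2 g/cm³, articular/subchondral ≈0.6 g/cm³) with
animal-level multiplicative variation — enough structure to make the SSAM
appearance block non-trivial, with no claim to trabecular realism.

## Shape and appearance model

Specimens are vectorised as `[coordinates…, densities…]` in template order.
Fitting performs rigid generalized Procrustes alignment of the coordinate
block (iterated to an RMS mean change < 1e-10, 100-iteration cap; uniform
scaling available but off by default), then PCA of the weighted matrix.  The
appearance weight defaults to equalising the two blocks' total training
variance, since no weighting convention is reported for the original model.
All nonzero-variance components are retained by default (at most n−1);
component signs are fixed by making the largest-magnitude loading positive.

Sampling draws 20 uniform scores per component within ±3 SD, one mode at a
time.  Fitting a target is the least-squares projection
`bᵢ = cᵢ·(x − x̄)/σᵢ`.  **Clipping:** sampled scores are always constrained
to ±3 SD; *fitted* scores are not clipped by default.  On a bilateral cohort
the within-animal modes carry tiny eigenvalues, so the SD-normalised score
of a left-out limb along them is routinely tens of SD; clamping those scores
discards genuine geometry and biases the validation, while the unclipped
projection is the best-approximation in the span.  Clipped fitting remains
available (`clip=True`) for diagnostics.

Leave-one-out validation is limb-level: each limb is predicted by a model
trained on the other nine, with the contralateral limb of the same animal
retained in training (the study design being emulated).  Errors are RMS/max
vertex distances in the model-aligned frame, reported per body, alongside
the RMS distance of the target to the training mean shape as a baseline.

Because the generator is a 6-parameter, nearly linear manifold and 8–9
components are available, leave-one-out reconstruction on the synthetic
cohort is near-exact.  Passing therefore certifies the correspondence,
alignment, projection and reconstruction machinery — it does **not** predict
the residual error the same model would achieve on real micro-CT anatomy,
whose variation is not low-dimensional.

## Contact model

The continuum finite-element stage of the original workflow is replaced by
an elastic foundation: pressure on a tibial element with initial gap `g` is
`p = (E'/t)·max(0, u − g)` with `E' = E(1−ν)/((1+ν)(1−2ν))` ≈ 102.68 MPa
(E = 6 MPa, ν = 0.49) and `t = 0.5 mm` (two 0.25 mm layers in series), `u`
the rigid femoral approach.  This is the standard desk-scale surrogate for
thin cartilage on much stiffer bone (bone modulus ~GPa by the density law,
three orders above cartilage, hence treated rigid) and admits a closed-form
oracle: a sphere of radius R indenting a flat foundation satisfies
`F = π E' R u²/t`, `A = 2πRu` — the solver is held to within 2 % of this.

Joint coordinate system: origin at the epicondylar midpoint, X along the
epicondylar line (lateral), Z perpendicular to the plateau (femur→tibia,
orthogonalised against X), Y = X × Z.  That literal cross product yields a
left-handed triad under the world convention used here; the axes are kept
exactly as defined (they remain orthonormal) and +Y is anterior in the
generated cohort.  All rotations name their axis explicitly, and the varus
sense is resolved geometrically (the rotation that lowers the medial condyle
toward the tibia), so handedness never enters silently.

Gaps are measured per tibial cartilage element by casting a ray along −Z to
the femoral cartilage surface and subtracting the two cartilage thicknesses;
element areas are projected along Z (small-slope contact patches).  Ray
casting is a vectorised fixed-direction Möller–Trumbore with a 2-D spatial
hash for candidate pruning.  The 0.1 mm pinball radius is the candidate
cutoff: elements with a larger initial gap are never considered contact
pairs; their summed area is reported as a `near_contact_area` diagnostic.

* **Fraction mode** (0/50/100 % varus): per-compartment forces are
  prescribed as (50/50), (75/25), (100/0) % of 2.94 N — the neutral split is
  even, matching the observed neutral distribution — and each compartment is
  solved independently by bisection on `u` (1e-6 N tolerance, bracket grown
  geometrically, ≤200 iterations; peak-pressure ties break at the lowest
  element index).  Ligament pretension forces are reported but excluded from
  this balance, which is what makes total-force conservation exact by
  construction.
* **Angle mode** (0/3/6°, the experiment's equivalents of 0/50/100 %): the
  femur is tilted about the JCS Y axis and a single translation `u` is
  solved so contact force plus the vertical ligament components balances
  2.94 N.  Ligament reference lengths are taken at the flexion-posed neutral
  configuration, so each spring carries `k·L_ref·pretension` there (slack
  length `L₀ = (1 − pretension)·L_ref`; pretension read as reference-pose
  engineering strain, the simplest reading of an unstated convention).
  With the default pretensions the ligament pull exceeds the applied load,
  so angle-mode contact forces are substantially higher than 2.94 N; with
  zero-stiffness ligaments the mode conserves the applied load to 1e-4 N.

A consequence worth stating plainly: compressions are micrometres while a 3°
tilt separates the lateral surfaces by ~0.1 mm, so in angle mode the lateral
compartment lifts off almost immediately and the emergent medial force
fraction saturates at 1.0 by 3°.  Monotonicity of medial/lateral outcomes
versus varus severity therefore holds in the weak (non-strict) sense.  The
same physics means a prescribed-zero-force compartment has exactly zero
pressure-bearing contact area; published nonzero lateral areas under a
"fully unloaded" condition can only correspond to near-field (within-pinball)
contact reporting, which is why that diagnostic is carried alongside the
strict `p > 0` area.

## Calibration

No specimen dimensions are published, so absolute contact areas are matched
by calibration rather than taken from anatomy.  A single uniform scale on
all nominal linear dimensions (conformities scale inversely; the standoff
stays equal to the summed cartilage thickness) is found by Brent root
finding so the zero-variance nominal specimen's medial contact area at
100 % varus hits a target, using the monotone `A ∝ √scale` law of foundation
contact; bracket 0.25–4×, target met within 1 %.  Because published areas
are group means over 10 knees, a second cohort-level refinement applies the
same scaling law until the seeded cohort's mean matches the target (two
iterations suffice).  Sampling variation of 5 animals moves the cohort mean
by ~±0.2 mm² around the nominal value, which is why the cohort-level step
exists.

## Film emulator and statistics

The pressure-film measurement model applies, per trial, multiplicative
lognormal noise (unit mean), saturation at a ceiling, a detection floor
below which elements register nothing, and optional quantisation; peak and
stained area are averaged over 3 trials.  The film physics parameters are
plumbing, not calibrated to a specific film product.  With zero noise, zero
floor and no quantisation the emulator is the identity, which is the
degenerate-pipeline test anchor.

Statistics are knee-level: Shapiro–Wilk normality, one-way ANOVA (scipy),
Tukey HSD (statsmodels, cross-checked in tests against scipy's
studentized-range implementation).  Because the original factor structure is
unspecified, comparisons run both across varus levels within a model type
and across model types within a level, per outcome and compartment.  Cells
where both groups are identical (the unloaded lateral compartment) have an
undefined F and are reported as NaN and excluded from summary minima.
Summary tables round group means to 2 decimals and compute deltas on the
rounded means; the headline "maximum change" aggregates are taken over the
two FEA model types for pressure and all three model types for area — the
published aggregates are internally consistent only under those conventions,
and the table builder flags, rather than resolves, the inconsistencies (the
quoted maximum lateral-area decrease of 1.76 mm² is not reproducible from
the per-model decreases, whose maximum is 1.42 mm²).

## Numerical and reproducibility choices

* One master seed; every stage (generation, film, sampling) draws from
  deterministic substreams, so a study rerun is bit-identical.
* Bisection everywhere a monotone scalar balance is solved (robust against
  the kinked force–displacement curve of element-wise contact).
* Meshes serialise as ASCII PLY with a `density` vertex property, or STL
  plus an exact sidecar vertex table (`%.17g`, round-trip parsing); configs
  as JSON/YAML; records as versioned CSV.
* Degenerate inputs are errors, not silent results: constant samples for
  Shapiro–Wilk, all-constant ANOVA, loaded compartments with no candidate
  contact, coincident epicondyles.

## Problem sizes

Default meshes carry ≈20k corresponded vertices per specimen (≈80k-entry
shape/appearance vectors); a full 10-limb study (leave-one-out SSAM, three
varus levels for specimen-specific and predicted geometries, film emulation,
statistics) completes in well under a minute on one CPU, and the sphere
oracle uses ≈450 elements of 0.05 mm.  These sizes were chosen so the whole
validation cycle runs interactively.

## Known limitations

* The cohort's variation is a 6-parameter family; real anatomical variation
  is far richer, so the near-zero leave-one-out errors here are a machinery
  check, not a claim about real data.
* The elastic foundation ignores tangential tractions, finite-thickness
  shear coupling and bone compliance; peak-pressure magnitudes are
  surrogate-scale, and comparisons across conditions (not absolute peaks)
  are the meaningful output.
* Menisci are absent by design (meniscus-deficient scope), the patella is
  unloaded, loading is static, and cartilage is linear elastic and
  homogeneous.
* Knee-level statistics ignore the limb-within-animal correlation of
  bilateral cohorts; a mixed-effects treatment is deliberately out of scope.
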