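# Methods

This note records the models, numerical choices and design decisions behind
`femurbench`, and what the synthetic benchmark does and does not establish.

## Units and frames

All computations use the mm–N–MPa–tonne unit system (densities converted
from g/cm³ to tonne/mm³), so stresses emerge in MPa and forces in N. The
anatomical frame of a right femur is built from three landmarks: the
superior-inferior (SI) axis is the unit vector from the knee centre to the
femoral head centre (the mechanical axis); the medial-lateral (ML) axis is
the knee-centre → lateral-epicondyle direction Gram–Schmidt-orthogonalised
against SI (the raw direction is generally not perpendicular to the
mechanical axis, a step the frame definition leaves implicit); the
anterior-posterior (AP) axis is ML × SI, which points anterior for a right
femur. Local force components are ordered (SI, ML, AP).

## Synthetic femur generator

The geometric substrate is a deterministic extrusion mesh: filled elliptical
cross-section disks (one centre node plus `nr` concentric rings of `na`
azimuthal nodes) are stacked along a shaft–neck–head centreline, consecutive
disks are connected into prisms, and every prism is split into three
tetrahedra with the lowest-global-index diagonal rule, which makes the
splits conforming without any lookup of neighbours. Node ordering is fixed
so all signed volumes are positive, and the INP writer emits the same
ordering. The construction needs no external mesher and is exactly
reproducible.

Anatomical features, all parametric:

* a spherical head (sections follow the sphere profile exactly, so a
  least-squares sphere fit over the head patch recovers the nominal radius
  to ~10⁻⁴ mm) on a neck of width 0.72 head diameters;
* neck-shaft angle (default 127°) and anteversion (default 15°) imposed by
  the centreline direction; section normals are slerped across the
  shaft–neck junction to avoid folding;
* a hollow-cortex shaft: ring radii place one ring exactly at the cortical
  boundary; the greyscale field ramps smoothly (smoothstep over the radial
  band position) from a cancellous level (default GV 1350) to a cortical
  level (default GV 1900), with 3 % multiplicative seeded jitter. These
  levels were chosen so the greyscale→density→modulus chain yields ~20 GPa
  cortical and ~12 GPa dense-trabecular moduli;
* metaphyseal flares: the shaft is narrowest at mid-diaphysis (default
  outer radius 15 mm, cortical thickness 5.5 mm, sized for the 93.4 kg
  subject) and widens by 55 % subtrochanterically and 18 % supracondylarly,
  like a real femur; the trochanteric region has a thin (~40 %) cortical
  shell over cancellous filling, and the neck carries a thick calcar
  (~75 % of diaphyseal cortical thickness);
* a protruding lateral greater-trochanter bump, whose most lateral surface
  node defines the p2 landmark;
* a condylar block (elliptical ML-wide flare) whose posterior-most ring
  nodes at ±symmetric azimuths define the posterior condylar axis used by
  the anteversion measurement.

Landmarks coincide with mesh nodes (section centres or ring nodes), so
deformity warps carry them along exactly. Attachment patches (gluteus
medius/maximus, iliopsoas, vasti, adductors, biceps femoris short head,
both gastrocnemius heads, patellofemoral and tibiofemoral contact, hip
contact = head patch) are surface-node neighbourhoods of anatomically
placed seed points. Four diaphyseal strain paths (medial, lateral,
anterior, posterior) are the surface node columns spanning 20–80 % of femur
length.

Default resolution is a 4 mm target edge length (~27k elements, ~5.6k
nodes) — deliberately coarser than a patient-specific 2 mm CT mesh so the
full benchmark runs in well under a minute on one CPU; halving the edge
length multiplies the element count by ~8 (azimuthal, radial and axial
densities all scale), and the resolution is a config knob. The test suite
uses 7–8 mm meshes.

## Material mapping

Apparent density ρ_app = 0.001029·GV + 0.114259 g/cm³ and Young's modulus
E = 6850·ρ_app^1.49 MPa are applied exactly as calibrated; at the top of
the nominal greyscale range (GV 4095) the chain yields a supra-physiological
ρ ≈ 4.33 g/cm³, which is flagged (`supra_physiological`) but not clamped.
Elements are partitioned into ten equal-width greyscale bins (quantile
binning would weight dense cortex differently; equal width is the simplest
reading of "sets of material properties"); each bin's representative
greyscale is the mean over member elements, so total stiffness is
approximately preserved; empty bins are dropped. Poisson's ratio is 0.3 for
every bin. Mass density reuses ρ_app. The in-repo sensitivity harness shows
the peak von Mises stress changes by ≈1 % from 10 to 20 bins (and far more
from 1 to 10), supporting the ten-set default.

## Gait-load fixture

The fixture emulates the *outputs* of an EMG-informed neuromusculoskeletal
pipeline at seven equally spaced stance instances — it does not model EMG,
kinematics or muscle dynamics. Muscle groups act at their patches along
straight anatomical lines with Gaussian activation bumps (peaks 0.4–1.8 BW,
2 % seeded variability). Joint contact forces are constructed as the
*reactions* they are in inverse dynamics:

1. the hip contact force direction is solved from the moment balance about
   the knee (its transverse part satisfies r × F = −c·M), while its
   magnitude follows a bimodal stance waveform peaking at 2.4 body weights
   with a shallow single-support trough;
2. the tibiofemoral force closes the net force, applied at the knee centre
   with a bounded centre-of-pressure migration (≤25 mm) that closes the
   axial torque the hip direction cannot react (hip contact CoP ≤10 mm
   assists);
3. the patellofemoral compression tracks the vasti activation, as the
   patella redirects the quadriceps tendon.

The closure fraction c (`balance_factor`, default 0.85) deliberately leaves
a ~15 % residual wrench. Sequentially linked pipelines do not hand the
isolated femur an equilibrated force system — segment dynamics, EMG noise
and model error leave exactly the "residual forces causing femoral motion"
that inertia relief exists to neutralise, and the benchmark's whole object
is how each constraint set copes with that residual. With a fully balanced
fixture all weakly constrained methods collapse onto inertia relief and the
comparison degenerates.

## Finite-element core

Standard constant-strain tetrahedra: per-element B-matrices from the
inverse Jacobian, isotropic elasticity in Voigt form (engineering shear),
vectorised assembly into a sparse symmetric stiffness, and a lumped mass
matrix (ρV/4 per node) — sufficient for rigid-body inertia in inertia
relief and cheaper than the consistent alternative. The analysis is linear
(small strain, small displacement): bone strains here stay ≲1100 µε,
firmly in the linear regime, and geometric nonlinearity is out of scope.

Constraints are handled uniformly as homogeneous multi-point-constraint
rows in a KKT (Lagrange-multiplier) system solved by sparse LU: Dirichlet
rows on nodes along arbitrary local directions, patch-average rows
(distributing couplings: a reference point's motion is the patch average),
patch-average rotation rows, and rigid couplings via six appended
reference-point DoFs tied to their patch nodes. Springs augment the
stiffness diagonal. Applied reference-point forces are spread over patches
with the moment-consistent distribution f_i = a + b × r_i (statically
equivalent to the force at the reference point, zero net moment), solved by
truncated least squares so degenerate (collinear/coplanar) patches remain
well-behaved. Singular or near-singular constrained systems are detected by
factorisation failure or a residual check (‖Ku + Cᵀλ − f‖ ≤ 10⁻⁸‖f‖).

Inertia relief uses the mass-orthogonality Lagrange augmentation (unique,
gauge-free) rather than 3-2-1 supports with zero-reaction verification;
the two agree to 10⁻⁸ in stress for self-equilibrated loads (tested).

Verification oracles: exact constant-strain patch test; cantilever tip
deflection within 7 % of PL³/3EI at a 60×8×8 mesh; superposition and
scaling linear to 10⁻⁹; von Mises closed forms (uniaxial σ, hydrostatic 0,
pure shear √3τ); rigid accelerations F/m for a uniformly pushed free body.

## Boundary-condition builders

DoF counts follow the method definitions: 0 (inertia relief), the whole
distal condylar region (fixed knee realises "all six DoF" by fixing the
translations of the distal 5 % of length, which removes all rigid modes of
a solid), springs only, 6 (isostatic), 6 (mid-shaft), and 3+2+3 with
couplings (biomechanical). Three readings deserve note:

* **Isostatic head constraint.** The head "centre" is the reference point
  coupled to the head cortex, so its ML/AP rows constrain the patch
  average — the head can deflect only along the mechanical axis. A
  `pole_node` variant pins the single surface node nearest the
  mechanical-axis–head intersection instead (it holds almost nothing: the
  node dimples locally at ~0.1 kN). The epicondyle direction defaults to
  AP; the SI variant is retained but leaves rotation about the mechanical
  axis nearly unconstrained and is flagged by the near-singularity check.
* **Biomechanical slider.** The slider axis is frozen at the undeformed
  p1–p3 line (small-displacement linearisation); the full hip force vector
  is applied at p1 and the slider rows react its transverse components,
  playing the acetabulum.
* **Springs tuning.** Default 8 N/mm per node on three bands (neck,
  epicondyles + medial counterpart, knee region). The artificial-reaction
  share — spring forces after subtracting the best-fit rigid drift of the
  spring nodes, over the summed applied force magnitudes — stays below 2 %
  (measured ~0.4 %); the share including the inherent grounding of the load
  residual is also reported. Stiffness, radii and counts are config-exposed
  because the method is known to be highly sensitive to them.

The PVMS artefact guard excludes elements within a configurable radius
(default 5 mm) of any attachment reference point and of any node
constrained by *any* of the compared methods, so the excluded region is
identical across methods and peak comparisons are unbiased.

## Deformation toolbox

Anteversion warps rotate nodes about the mechanical axis with a cosine
(smoothstep) ramp from zero at the distal condyles to the full angle just
below the lesser-trochanter level — C¹ ramps avoid the strain band a step
rotation would imprint, and the distributed-torsion reading is adopted
since the alternative (rigid proximal fragment) is not distinguishable
from the description. Neck-shaft warps rotate about the AP axis through the
neck base, ramped along the neck so the head moves rigidly and stays
spherical. Because both angle measurements are pure functions of the
landmark points, the warp angle is solved exactly on a landmark surrogate
(Brent root find, 10⁻¹⁰ deg) before any node moves; the mesh warp is then
applied in `n_increments` steps with an element-inversion check after each
(abort with a quality report rather than untangle). Greyscale values and
patch memberships ride along unchanged; warps are near-isochoric (<2 %
volume change) and exactly invertible (+20° then −20° restores nodes to
10⁻⁶ mm).

Angle conventions: NSA is the angle at the neck base between the neck axis
and the distal shaft axis; AVA is the signed angle, in the plane transverse
to the shaft axis, between the neck-axis projection and the medial
direction of the posterior condylar axis (anterior positive — the standard
clinical convention, which the method description leaves unstated).

## Outcomes

FHD is the displacement of the hip-joint centre relative to the knee-joint
centre (barycentric interpolation at the landmark points, nearest-node
fallback), resolved on SI/ML/AP. PVMS is the element maximum outside the
artefact guard. Cortical strain profiles sample, at each path node, the
absolute principal strain (max |eigenvalue| of the strain tensor) of the
nearest boundary-face element, in µε; a signed companion (eigenvalue of
largest magnitude) supports tension/compression pattern checks. R² is
computed with the inertia-relief series as truth (1 − SS_res/SS_tot about
the reference mean, not a symmetric correlation), and nRMSE normalises the
RMS error by the reference's dynamic range; both return flagged NaN for
constant references.

## What the synthetic benchmark shows — and does not

Green, robust across seeds and resolutions: the physiological bounds
(biomechanical FHD < 1 mm and PVMS < 60 MPa; cortical strains ≤ 1100 µε
for the isostatic, inertia-relief and biomechanical methods; SI FHD within
the 0–3 mm single-legged-stance range), the fixed-knee method producing the
largest resultant FHD on every geometry, the deformation-toolbox angle
recovery to 0.5°, and the material-set and FHD mesh-refinement
stabilisation (PVMS, a peak quantity, converges more slowly and is reported
rather than bounded).

Not reproduced here: the biomechanical method ranking first in PVMS-series
nRMSE against inertia relief, and its lateral-tensile/medial-compressive
strain pattern. In this synthetic system the weak springs and the isostatic
set carry ~0.1 kN and track inertia relief to nRMSE ≈ 0.01, while the
biomechanical head-slider plus greater-trochanter coupling suppress the
femur's natural neck-flexion mode (the trochanter tips ~0.2 mm laterally
relative to the constrained head), generating an internal ~1 kN couple that
shields and partly reverses proximal bending. That behaviour is inherent to
the constraint topology on this geometry and load set; whether it appears
on a given patient-specific femur depends on how closely the trochanteric
region's natural motion matches the constraint. The corresponding
acceptance checks are intentionally left failing rather than tuned away.

More generally, the synthetic system emulates *outputs* (plausible
magnitudes, directions, timing and residuals of an NMSK pipeline), not the
pipeline itself: no subject-specific geometry, no cartilage, no EMG, a
reduced muscle set with straight lines of action, and a parametric bone
that is smoother and more symmetric than any real femur. Passing tests
establish the correctness and the comparative mechanics of the constraint
formulations on a controlled system — not patient-level predictions.
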