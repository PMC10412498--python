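# Methods

This note documents the models, parameters and numerical choices behind
`cardioriis`, in the package's own terms.  The package studies systolic
left-heart hemodynamics with a closed mitral valve: a healthy scenario (H)
is compared against two mitral-regurgitation scenarios, one with a raised
heart rate (R1) and one with a dilated heart at the basal rate (R2).  All
inputs are produced by a synthetic phantom with closed-form ground truth,
so every stage of the image-to-hemodynamics chain is testable without
patient data.

## The phantom

The cavity is a union of three implicit primitives (lengths in mm): a
prolate ellipsoid ventricle (semi-axes 24, 24, 46, apex down) truncated at
the valvular base plane `z = 0`; a spherical atrium (radius 19) whose cut
by the base plane *is* the mitral annulus (radius 11.5) and which is
truncated above by the atrial outlet plane Σ1; and a straight aortic tube
(radius 8, tilted 42°) cut below by the base plane through its axis origin
and above by the aortic outlet plane Σ2.  Every sub-volume has a closed
form, so the discrete cavity volume can be checked against an analytic
oracle (the oblique base-plane cut passes through the tube axis, so its
wedges cancel and the tube volume above the plane is exactly `π r² L`).
The tube is straight rather than gently curved: a curved centerline would
break the closed-form volume without changing any tested behavior.

Meshing is grid-seeded Delaunay: interior seeds on a body-centred-cubic
lattice (its Delaunay triangulation is the high-quality tetrahedral
lattice), near-surface seeds projected onto the zero level set with a
tangential jitter that breaks coplanar-lattice degeneracy on the flat
caps, a centroid-inside filter, and removal of flat all-on-surface
slivers.  Interior seeds keep a clearance of 0.7 local cell sizes from the
concave junction rings (annulus, aortic orifice, outlet rims), where the
min-composed signed distance underestimates the true clearance.  The
boundary of the kept tetrahedra is closed and consistently oriented, so
divergence-theorem volumes are exact for the discrete shape.  Graded
resolution: a base size `h`, a finer size in a slab around the valvular
plane and along the whole aortic tube (where the immersed valves and the
outflow jet live).

Systolic motion is an analytic stretch of the ventricle referenced to end
systole (ES): wall points move by `d(X, t) = a(t) · λ(z) · (x, y, γ z)`
with longitudinal-to-radial ratio `γ = 0.5`, a cos² taper λ that reaches
zero strictly below the pinned outlet band, and the cosine ramp
`a(t) = a_max (1 + cos(π t / T_S)) / 2`, which starts and ends systole at
rest and makes cavity volume monotone.  The atrial and aortic walls are
not prescribed directly: their motion is the elastic extension of the
ventricular data (`μ_EXT = λ_EXT = 0.4 Pa`, atrial outlet pinned), which
mirrors how imaged ventricular motion is propagated to untracked
structures and, being energy-minimizing, keeps the moved mesh valid.  The
extension is linear, so all six frames are multiples of one unit solve.
`a_max` is solved by 1-D root finding so the ED→ES cavity-volume change
equals the target stroke volume (92 mL by default; scaled by the cube of
the dilation factor for R2).  The handful of boundary slivers that a given
seed's deformation would flatten are dropped and the motion recomputed;
an inversion that cannot be repaired this way is a hard error.

Image rendering emulates a short-axis stack (1 mm in plane, 8 mm across
slices) and two long-axis single slices.  A voxel's value is the
through-thickness average (7 points across the 8 mm thickness) of a sharp
cavity indicator sampled at the voxel's in-plane centre; the moving cavity
is evaluated by inverting the motion map with a fixed-point iteration.
The renderer does not model acquisition noise, bias fields, or misaligned
series — merging quality results therefore bound only geometric,
not photometric, behaviour.

Valve traces reproduce the radial protocol: 18 planes through the annulus
axis, 10° apart, two half-profiles of 32 spline samples each.  The healthy
coaptation ring is the circle `C(α) = m + R cos α (cos α, sin α, 0)` drawn
6 mm below the annulus: each point lies exactly in its plane, so the last
anterior and posterior points of every plane coincide — full closure is
imposed exactly, as in manual tracing.  The P2 prolapse displaces the
distal posterior profiles of the 60°–120° sector toward the atrium and
outward; the displacement amplitude is solved so the polygon between the
free margins has exactly the requested orifice area (40 mm² by default, a
severe regurgitant orifice).  Trace noise is isotropic Gaussian, σ =
0.3 mm per point (manual-tracing error at ~1.25 mm imaging resolution);
the imposed healthy coincidence survives the noise by construction.

## Image fusion

The short/long-axis merge builds an isotropic (1 mm) grid over the
short-axis box; each output voxel averages one nearest in-plane voxel per
source slice, weighted by a Gaussian of the 3-D distance (scale = half the
cross-slice spacing) with a hard cutoff at 1.5 slice spacings.  Background
voxels of long-axis slices are included with the same distance weighting;
output voxels beyond every cutoff are flagged background by a zero total
weight.  Convexity gives the range bound; exactness for affine intensity
fields holds wherever the contributing slices are symmetric about the
voxel.

## Valve reconstruction

Profiles are azimuth-sorted into the 1152 × 3 cloud; ring blocks (32 rings
× 36 points) are fitted by periodic cubic smoothing splines (smoothing
target = the expected squared trace-noise residual, i.e. interpolation in
the noiseless limit) and resampled at 1000 points per ring (the 32 000-row
cloud).  The sequence passed to the periodic fitter is explicitly closed;
duplicate coaptation rows collapse to their representative so profile
correspondence is preserved.  The surface is triangulated on the
profile-corresponded ring grid — margin rings traverse the coaptation seam
once per leaflet, so azimuth-uniform resampling would twist the
connectivity — and coincident free-margin points are welded into a seam:
a coapting valve becomes a single sealed membrane, a prolapse gap stays
open.  The mesh is then isotropically remeshed (conforming edge splits,
link-condition-checked collapses, tangential relaxation with projection
back to the surface; boundary vertices stay on the original boundary
polylines) to a uniform target edge (~2 mm at solver scale), reaching
edge-length CVs of 0.15–0.25 on the phantom valves.  Ring fitting is
exactly rotation/translation equivariant in the interpolation limit; with
smoothing, the spline library's knot selection is only approximately
isometry-invariant, which is why the equivariance property is asserted at
zero noise.

Wall attachment extends the annulus-to-wall gap harmonically over the
leaflet (uniform-weight graph Laplacian: positive weights give a discrete
maximum principle, so the free margin never moves more than the largest
annulus gap) and warps the valve onto the discrete wall.

Distances to the leaflet surface are exact nearest-triangle distances (a
k-d tree over triangle centroids only prunes candidates, with a
certificate that the true nearest triangle cannot be missed).  The
resistive layer is `δ(φ) = (1 + cos(π φ / ε)) / (2 ε)` on `|φ| ≤ ε`; the
distance is unsigned because the layer is even in φ and the sign has no
other use with an always-closed mitral valve.

## Flow solver

Incompressible Navier–Stokes in ALE form on the moving mesh, blood
density 1060 kg/m³ and viscosity 3.5 mPa·s, first-order semi-implicit
stepping: lagged convective velocity `w = uⁿ − u_ALE`, implicit viscous
and pressure terms, explicit subgrid viscosity, implicit resistive
penalties, one linear solve per step.  P1–P1 elements with element-constant
SUPG/PSPG stabilization.  Two deliberate stabilization choices:

- the PSPG parameter uses the steady scaling (no `1/Δt` term): with the
  transient term the parameter collapses at small time steps and pressure
  checkerboarding returns (the small-time-step instability of equal-order
  pairs); SUPG keeps the transient term;
- the convective term carries the skew-symmetrizing correction
  `+ ½ ρ (∇·w) u`, since the lagged ALE convective field is not discretely
  solenoidal and plain Galerkin convection can produce energy.

The resistive-surface reaction enters the stabilization parameter (so τ
shrinks inside the layer) but not the stabilized residual.  The penalty
integral is evaluated with both vertex (lumped) and element-level
quadrature — centroid plus the four face midpoints — so a membrane
crossing an element between its nodes still contributes resistance; this
matters at desk-scale resolutions where the layer is about one element
thick.  Outlet pressures act as weak normal tractions; the wall velocity
is imposed strongly; backflow control at the atrial outlet constrains the
tangential velocity components to zero (strongly, the outlet plane being
axis-aligned) in the regurgitant scenarios.  With no traction boundary
anywhere, one pressure degree of freedom is pinned.

The linear system (node-interleaved ordering for low fill) is factorized
sparsely and reused as a preconditioner for restarted GMRES on subsequent
steps, with refactorization every 8 steps or on slow convergence; relative
tolerance 1e-8.

The aortic valve is on/off: closed template a domed disk spanning the
root, open template a sleeve pressed against (slightly beyond) the wall so
its layer overlaps the no-slip region instead of eating into the lumen at
desk-scale layer thicknesses.  Opening is instantaneous on the first
positive ventricle-aorta slice-pressure jump; closure on the first
reversed aortic-plane flow after ejection has developed (the
developed-flow guard keeps the startup transient from shutting the valve);
one opening and one closure per systole.  Both valves ride the ALE
displacement; the prescribed surface velocity in the penalty is zero.

The subgrid viscosity is
`μ_sgs = ρ C Δ² σ₃(σ₁−σ₂)(σ₂−σ₃)/σ₁²` with the singular values of the
velocity-gradient tensor, C = 1.5 and one global filter width Δ = the
average mesh edge of the run.  The formula is implemented in ratio form
(removable singularity at σ₁ = 0 evaluated as zero, no underflow).

## Postprocessing

Flow rates and slice pressures come from exact plane sections of the
tetrahedral mesh (marching-tetrahedra cuts whose points are convex
combinations of two mesh nodes, so P1 fields integrate exactly).  The
mitral-orifice section is the disk just above the annulus restricted to
the orifice region — near-wall crease cells outside the annulus radius
carry recirculation, not transvalvular flow.  Regurgitant volume
integrates only atrium-directed orifice flow; a healthy run whose residual
layer seepage stays below 2 % of the stroke volume reports a regurgitant
volume of zero (the leak-bookkeeping threshold, fixed before the scenario
studies).  Peaks of the outflow curve are prominence-ranked with a minimum
separation of 5 % of systole; the middle-deceleration instant is the mean
of the second peak and the closure time.  Wall WSS uses the owner
element's velocity gradient; valve WSS interpolates a volume-weighted
nodal gradient onto the leaflet with the leaflet's own normals and the
effective viscosity.  The atrial turbulence ratio is the volume-weighted
mean of `μ_sgs/μ` over atrium cells above the annulus plane.

## Desk-scale study conditions

The reference-scale problem (mm-resolution meshes, Δt = 0.25 ms, cluster
hardware) is out of reach on one CPU, so the scenario runs use a
deliberately scaled-down resolution, chosen once: base mesh size 6.1 mm
with 3.15 mm in the valve slab and aortic tube (≈3 900 nodes, ≈19 000
tetrahedra), Δt = 2.8 ms (≈114 steps per systole), filter width = the
resulting average edge (≈3.8 mm), with the smooth volumetric/surface
probes (turbulence ratio, WSS means) sampled every other step.  Two resistive-layer parameters are
resolution-coupled rather than reference values: the half-thickness
`ε = max(0.75 mm, 0.42 h_fine)` — it must stay below half the regurgitant
slit width (≈1.8 mm), or the orifice smears shut — and the resistance
`R = 1e5 kg/(m·s)` in the scenario runner, strengthening the kinematic
constraint to compensate the thin, coarsely integrated layer (leakage
scales like ε²/R; the blocking benchmark keeps the reference values
R = 1e4, ε = 0.75 mm and passes at its finer channel resolution).  The
quantitative indices at this scale are *not* patient-scale predictions;
what the scenario comparison is expected to reproduce — and what the
acceptance checks assert — are the qualitative orderings: a competent
healthy valve (zero regurgitant fraction after leak bookkeeping, aortic
valve open from the start), regurgitation and delayed aortic opening with
the prolapsed valve, and an atrial subgrid-activity ratio that is much
larger in the regurgitant scenarios than in the healthy one.

Scenario time bases: H runs at 75 bpm with T_S = 0.32 s; R1 at 90 bpm
with T_S = 0.26 s and all waveforms rescaled to the shorter systole; R2
keeps 75 bpm, reuses H's T_S = 0.32 s (the shared motion protocol implies
it; the dilated systole length is not separately specified) and dilates
geometry, displacement and valve together by 1.25.  Outlet pressures: a
physiological aortic trace (80→120→100 mmHg) in all scenarios; a constant
10 mmHg atrial pressure for H; an elevated-V-wave atrial trace (10→35
mmHg, late-systolic peak) for R1/R2 — the regurgitant atrial table is a
documented stand-in with the literature's qualitative shape, as the
source waveform is not tabulated anywhere reusable.  mmHg converts at
133.322 Pa at the config boundary; everything inside the solver is SI.

## Known limitations

- The phantom's atrium contracts slightly with the taper during systole
  (real atria fill); its volume change is small and bookkept by the flux
  balance, but atrial inflow physiology is absent.
- At desk-scale resolution the stroke volume seen by the outflow tract is
  below the 92 mL cavity change (the atrium discharges part of its own
  volume through its outlet, and a few mL seep through the resistive
  layer); pressure drops and peak velocities carry the bias of the
  narrow synthetic aortic root.
- The frame-selection problem of noisy acquisitions (dropping unusable
  intermediate frames) is not modelled; the phantom's frames are all
  usable by construction.
- Mitral and aortic leaflet dynamics, chordae, and diastole are out of
  scope; the mitral valve is always closed and the aortic valve is binary.
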