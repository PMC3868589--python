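# Methods

`lvmech` identifies the time-varying bulk modulus K(t) of the human
left-ventricular (LV) wall over one cardiac cycle by inverse finite-element
analysis: at every time sample the measured cavity pressure is applied to a
quasi-static FE model of the wall and K is adjusted until the simulated
cavity volume matches the measured volume. The compressibility reported is
c(t) = 1/K(t).

## The forward model

**Geometry.** The wall is a thick shell between two coaxial prolate
ellipsoids truncated at two-thirds of the endocardial long axis (apex at
z = -a_endo, base plane at z = +a_endo/3). No linear dimensions are
prescribed; the shape is *solved* from the two volumetric constraints the
model fixes - cavity volume 50 ml and wall volume 73.6 ml - given an
endocardial aspect ratio a/b = 2 and a uniform wall thickness. For the
reference configuration this yields a_endo = 40.1 mm, b_endo = 20.0 mm,
thickness 9.2 mm - a physiologic human LV.

**Mesh.** Structured 8-node hexahedra: 7 equal transmural layers,
n_long longitudinal rows, n_circ circumferential divisions (default 12 x 6,
the published reference discretisation of 48 circumferential divisions is a
config switch), closed at the apex by a ring of collapsed hexahedra.
Because a coarse faceted surface inscribed in an ellipsoid underestimates
enclosed volume by several percent, the mesher by default *calibrates* its
two shape scalars so that the discrete cavity volume (divergence-theorem
surface integral closed by a virtual fan to the base-centre "pressure
node") and the discrete wall volume (quadrature sum) equal 50/73.6 ml to
~1e-12. The volumes, not the surfaces, are the model's defining data, so
the calibrated mesh is the faithful discrete object; `calibrate=False`
keeps nodes exactly on the analytic ellipsoids (used for the mesh
refinement study, which shows second-order convergence of the volume
error).

**Fiber architecture.** Rule-based. The helix angle varies linearly across
the thickness between printed per-region endpoints (8 regions:
septum/anterior/lateral/posterior x basal/apical, e.g. septum-basal -60deg
at the epicardium to +40deg at the endocardium), evaluated at each layer's
midwall coordinate (s in {1/14, 3/14, ...}). The transverse angle varies
linearly from -15deg at the apex through 0 at the equator to +15deg at the
base. Region azimuthal extents are not published; four 90-degree quadrants
starting at the -x axis (septum) are used, with the basal/apical split at
the longitudinal midpoint. Collagen fibers are radial. Fields are sampled
at the 2x2x2 Gauss points; the local frame (circumferential, longitudinal,
radial) comes from the interpolated ellipsoidal surface through each point.

**Material.** The passive matrix is a two-term Ogden solid on the
isochoric principal stretches (mu = 220/110 kPa, alpha = 11.77/14.34;
ground-state shear modulus sum(mu_i alpha_i)/2 = 2083 kPa) plus a
volumetric energy U(J) with tangent bulk modulus exactly K at J = 1. The
default U = (K/2)(J-1)^2 is the simplest convex choice (and the form used
by the commercial code the source experiment ran); a log-barrier variant
K(J - 1 - ln J) is available for strongly compressive regimes. Fiber
constituents are uniaxial linear reinforcements by volume fraction
(myofiber 0.7, collagen 0.015) acting on the Green-Lagrange fiber strain
from the stress-free reference; the myofiber modulus is the time-varying
active elastance E_a(t) = c_act p(t) with c_act = 500/16.93 = 29.5 (so E_a
caps at 0.5 MPa at peak pressure), collagen keeps E = 50 kPa. Collagen's
Poisson ratio (0.49) and density (1000 kg/m^3) are recorded but unused: a
uniaxial reinforcement has no transverse response and quasi-statics no
inertia.

**Active-fiber coupling - a forced design decision.** Coupling either
fiber family linearly (or tension-only) to the total fiber strain makes
the diastolic experiment *infeasible*, and provably so. During filling the
cavity can only grow by wall dilation (the Ogden matrix is ~2 MPa stiff in
shear, so at sub-kPa pressures deviatoric deformation is negligible); the
dilation stretches every fiber by ~30%. The available volumetric driving
stress is of order p Vc/Vw, while the myofiber resistance is
vf c_act p eps - both scale linearly with p, with a p-independent ratio of
~25. No pressure waveform can escape this; measured: with the linear law,
V(K -> 0) saturates near 62 ml against targets of 110-130 ml. The same
holds for collagen below p ~ 0.45 kPa (its 0.75 kPa effective stiffness is
fixed, not pressure-scaled). Meanwhile the published identified
compressibility (~3 1/kPa diastolic scale, peak K at end ejection under a
1% volume-matching rule, linear decline through isovolumic relaxation) is
quantitatively what a fiber-inert force balance produces. The package
therefore defaults both fiber families to a *compression-guard* coupling:
the reinforcement resists shortening below the reference length but is
inert for the tensile strains of dilation. The conventional `linear` and
`tension` branches remain one config switch away
(`materials.active_fiber_law`, `materials.collagen_fiber_law`) and are
exercised by the test suite.

**Loads and boundary conditions.** Follower cavity pressure on the
endocardial faces (always normal to the deforming surface); a linear
Winkler foundation of stiffness K_f = 0.02 kPa per mm of normal
displacement on the epicardium (the surrounding organs), evaluated on the
reference configuration; zero longitudinal displacement on all base-plane
nodes; and suppression of the three in-plane rigid modes through
tangential constraints at three base-ring nodes - the structural
counterpart of fixing the cavity pressure node laterally (by symmetry
these constraints carry essentially no load). The cavity itself is not
meshed: the enclosed volume is evaluated by the divergence theorem over
the deformed endocardial surface closed at the base opening.

## The FE engine

Total-Lagrangian, quasi-static, 2x2x2 Gauss quadrature. Volumetric
locking at high K is suppressed by mean dilatation: the deviatoric Ogden
response is integrated pointwise on the isochoric stretches while U acts
on the element-averaged volume ratio J-bar. Stresses are evaluated
spectrally without explicit eigenvectors: closed-form (Cardano)
eigenvalues and the Lagrange spectral-projector representation
S_dev = sum_i s_i prod_{j != i}(C - x_j I)/(x_i - x_j), with the products
kept unexpanded (this preserves the exact zero on repeated eigenspaces)
and the eigenvalues split by a 1e-6 relative jitter so the formula stays
conditioned through degeneracies; the resulting stress error is ~1e-6
relative, far below discretisation error.

Internal and external nodal forces are analytic. The consistent tangent is
built by vectorised central finite differencing of the exact element force
vectors (24 dofs per hexahedron, 12 per pressure face; half-step 1e-6 mm),
which is consistent with the mean-dilatation coupling and the
non-symmetric follower-pressure stiffness by construction; assembled
tangents agree with global finite differences of the residual to ~1e-7
relative. Newton-Raphson iteration uses a backtracking line search, an LU
factorisation that is reused while the contraction rate stays below 0.2
(rebuilt otherwise), convergence at relative residual 1e-6 (with a small
absolute force floor of 1e-4 kPa mm^2 covering the stress evaluator's
noise at the stress-free state), and automatic bisection substepping of
the joint load path (p, E_a, log K), up to 16 substeps.

Deep in the near-incompressible regime the radius of Newton's convergence
basin shrinks like mu/K: soft isochoric modes (stiffness ~mu) carry a
second-order volumetric penalty ~K, so for K/mu >~ 1e4 a direct step can
stall. `solve_step` then retries by continuation: soften K to 100 mu at
the old loads, advance the loads there, and ramp K back up in log space.
The reference LV identification never needs this (its K bracket tops out
at K/mu ~ 50); the incompressible-shell verification at K = 1e5 mu does.

The engine is verified against an independent semi-analytic oracle: a
hemispherical shell with the base-plane symmetry condition, inflated at
K = 1e5 mu_eff, matches the 1-D incompressible thick-shell relation
P(lam_a) = int W'(lam)/(lam^3 - 1) dlam within 0.5% at the default test
resolution (tolerance 2%).

## The inverse loop

At fixed loads the cavity-volume response V(K) is monotone decreasing
(verified by sweep), so each step is a 1-D root find in log K: a secant
iteration warm-started from the previous step's K (and seeded with the
previous step's sensitivity dV/dlnK), with log-space bisection of the
maintained bracket as fallback and direct endpoint evaluation when all
samples lie on one side of the target. A step terminates when
|V - V_target|/V_target <= 1% (the source experiment's convergence rule;
configurable - the parameter-recovery studies use 1e-4).

Three conditions are *flagged* rather than silently accepted:

* `bracket` - the target is unreachable inside [K_min, K_max]
  (default 0.01 to 1e5 kPa); the nearest endpoint is returned.
* `insensitive` - the tolerance band does not pin K down: with tolerance
  eps, the accepted ln-K window is ~eps V/|dV/dlnK|; the step is flagged
  when that window exceeds one natural-log unit (K undetermined beyond a
  factor e), with 0.1 ml/lnK as an absolute sensitivity floor. Near end
  systole the target volume equals the reference cavity volume while the
  pressure is still ~12 kPa, V(K -> inf) stays ~1% above the target, and
  any K over ~1e4 kPa satisfies the rule - the flagged value is a lower
  bound, not an identification.
* `max-iter` / `solver` - iteration budget exhausted or FE failure at
  every admissible trial.

Summaries report peak K over *unflagged* steps, peak compressibility, the
"nearly incompressible" duration (time with c below 5% of its cycle
maximum), EDV/ESV/SV and the ejection fraction. Identical configs produce
bit-identical output tables.

## Synthetic cycle generator

No machine-readable pressure/volume data exist for the source experiment;
the curves survive only as printed anchors. The generator reconstructs
both series by monotone piecewise-cubic (PCHIP) interpolation through the
anchors, which renders each phase monotone and the two isovolumic plateaus
exactly constant. Printed anchors: phase boundaries
0.1/0.21/0.3/0.43/0.5/0.65/0.8 s, V = 110 ml at cycle start (atrial
systole onset), EDV 130 ml, ESV 50 ml, peak pressure 16.93 kPa. Anchors no
printed value fixes were chosen once from standard human physiology and
are configurable:

* pressure at (t=0, phase ends): 0.5, 1.0, 10.6 (aortic opening), 16.93
  (peak, end of rapid ejection), 13.0 (aortic closure, ~100 mmHg), 0.7,
  0.35, 0.5 kPa;
* interior volume anchors: 75% of the stroke volume ejected by the end of
  rapid ejection (70 ml) and 11/12 of the refill completed by the end of
  rapid filling (105 ml).

Default sampling: 41 points (20 ms). The generator emulates anchor values
and phase structure, not beat-to-beat variability, measurement noise,
atrioventricular interaction or inertial pressure transients - so passing
tests demonstrate fidelity to the published anchor set, not to raw
catheter data. The three alternative lower-ejection-fraction datasets of
the published comparison have no printed anchors at all; the pipeline
accepts user CSV or custom anchor sets for them and makes no default claim
about their pressures.

## Problem sizes and tolerances used in verification

The shipped verification runs use desk-scale sizes chosen as the package's
defaults: the reference identification on the 12 x 6 x 7 mesh (588
elements, ~2000 dofs) with 41 time samples; parameter recovery on an
8 x 4 x 3 mesh with K* spanning 10-1e4 kPa at tolerance 1e-4; the shell
oracle on a 12 x 6 x 4 hemisphere. Mesh calibration makes the discrete
volumes exact at any resolution, and the identified K(t) changes by a few
percent between 12 x 6 and finer meshes (the identification compares like
with like: discrete target against discrete response).

## Known limitations

* The identified K near end systole is reported as a flagged lower bound;
  its numerical value under the 1% rule depends sharply on the unprinted
  end-systolic pressure decay (an effective net load of ~7-8 kPa would put
  the unflagged peak near 1.5 MPa; the physiologic ~13 kPa anchor used
  here puts it near 0.7 MPa with the saturated plateau above 1e4 kPa).
* The diastolic compressibility scale is set by the sub-kPa filling
  pressures and the foundation support; its peak (~tens of 1/kPa) is an
  order of magnitude above the published ~3 1/kPa, and the inferred
  "nearly incompressible" fraction of the cycle (~50-60%) is accordingly
  larger than the published <= 20%. Both are direct consequences of the
  printed inputs under a causal constitutive law; see the active-fiber
  discussion above.
* Quasi-static only: no inertia, no blood flow, no electrophysiology
  (activation enters solely through E_a(t) = c_act p(t)), no
  growth/remodeling, no patient-specific geometry.
* The apex uses collapsed hexahedra; stress fields in the cap ring are
  lower-order than in the regular shell.
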