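# Methods

## The mechanical model

The two blastomeres of the two-cell *C. elegans* embryo are modelled as
incompressible fluid bodies bounded by three surface patches — the
contact-free (outer) surface of AB, the outer surface of P1, and the shared
contact surface — each carrying a uniform, isotropic tension analogous to the
surface tension of a soap film.  The total mechanical energy is

    E = γ_AB·A_AB + γ_P1·A_P1 + γ_cnt·A_cnt

where `A` are patch areas.  The equilibrium shape minimizes `E` subject to
two constraints: each body's volume is fixed, and no part of the surface may
cross the eggshell, represented as a rigid ellipsoid acting through a
one-sided (contact-only, frictionless) constraint.  Tensions are
dimensionless, with `γ_P1 = 1` fixing the unit; lengths are in µm, so
pressures (energy sensitivities to volume, `∂E/∂V`) come out in tension/µm.

Two parameter regimes matter: the *homogeneous* model (`γ_AB = γ_P1 = γ_cnt`)
is a confined soap-bubble pair, in which the smaller P1 has the higher
pressure and the contact bulges slightly into AB; the *heterogeneous* model
lets `γ_AB` and `γ_cnt` vary, and with `γ_AB = γ_cnt ≈ 3.4` the larger AB
acquires roughly three times P1's pressure and the contact bulges deeply into
P1 — matching the embryo's observed shape.  A stable two-cell contact
requires the tension triangle inequality `|γ_AB − γ_P1| ≤ γ_cnt ≤ γ_AB +
γ_P1`; outside it the energy favours detachment or engulfment, and the
tension grid search excludes such combinations.

## Discretization and minimization

The surfaces are a single shared triangle mesh with a patch label per
triangle; contact triangles are stored once (oriented from AB toward P1) and
bound both bodies with opposite senses, which makes the two enclosed volumes
automatically consistent.  The initial configuration is two cubes of side
14.7 µm sharing one triangulated face, centred in the eggshell with the
shared face normal to the major axis and AB anterior.

Minimization is projected gradient descent on vertex positions:

* **Direction.**  The area-energy gradient is preconditioned by the inverse
  lumped vertex area (making steps resolution-independent), then projected to
  the constraint tangent space: volume-gradient components are removed in the
  preconditioner metric, which keeps the direction both first-order
  volume-neutral and a guaranteed descent direction.
* **One-sided shell constraint.**  A vertex on the shell is treated as
  equality-constrained (motion restricted to the shell's tangent plane) only
  where the shell actually presses on the surface; the contact force is
  estimated from least-squares Lagrange multipliers of the stationarity
  condition, and vertices with the wrong force sign are released.  After
  every trial step, vertices outside the ellipsoid are projected back to
  their nearest surface point (vectorized Newton on the Lagrange parameter of
  the nearest-point condition; a bracketed 1-D root finder with 1e-10
  tolerance serves as the scalar reference).
* **Line search.**  Backtracking with expansion on a simple-decrease
  criterion.  Constraint restoration perturbs the energy by a small noise
  floor (volume projection is iterated to a relative residual of 1e-9), so
  trial steps below ~1e-5 are uninformative; the step size therefore has a
  floor and can grow again after failures.
* **Volume constraints.**  After each trial step both volumes are restored
  exactly by a minimal-norm Newton correction along the volume gradients.
  Because a coarse polyhedron inscribed in the ellipsoid cannot hold the full
  target volume, targets are approached by a multiplicative ramp (25% per
  round) and any remainder is deferred to the next subdivision level.
* **Schedule.**  Minimize on the initial mesh, then three rounds of uniform
  4-way subdivision each followed by minimization (the default production
  resolution ends at 5 632 triangles), then a final polish phase without
  mesh-maintenance passes so that the stored state is stationary.
  Convergence is declared when the relative energy decrease over a 30-step
  window falls below 1e-4 % and both volume residuals are below 1e-4
  (relative).  Everything is deterministic; there is no randomness anywhere
  in the solver.
* **Mesh quality.**  Between descent phases, near-coplanar edge pairs are
  flipped toward Delaunay-like triangles (never across patch boundaries) and
  vertices are smoothed tangentially (triple-line vertices move only along
  the line), followed by re-projection of all constraints.  These passes are
  shape-neutral by construction but leave the state slightly off-stationary,
  which is why the final polish phase omits them.

## Pressures and curve depth

Pressures are reported as the least-squares Lagrange multipliers of
`∇E = P_AB ∇V_AB + P_P1 ∇V_P1` over all vertices, with shell-normal
components projected out at shell-active vertices.  An independent
finite-difference estimate (re-minimizing at `V ± 0.5 %` and differencing the
energies) is used as a cross-check in the test suite; the two agree to ~1 %
on free double bubbles.  On a free bubble the multipliers also reproduce the
Laplace closed forms `P_i = 2γ_i/R_i` and `P_AB − P_P1 = ±2γ_cnt/R_cnt` to
better than 2 %.

The mesh curve depth fits a total-least-squares plane to the triple line
(the boundary ring of the contact patch) and reports the signed distance of
the farthest contact vertex, positive when the bulge points from AB toward
P1.  The 2-D operator used on mid-plane traces is the analogous
chord-to-apex perpendicular distance with the same sign convention.

## Analytic reference: the unequal-tension double bubble

For free (unconfined) two-cell shapes the exact equilibrium is three
spherical caps sharing a circle, determined by Laplace's law, the Young
tangent balance at the triple circle, and the two volumes.  The package
solves this four-unknown system directly (`analytic_double_bubble`) and uses
it as a simulator-independent oracle.  For the 60:40 equal-tension bubble the
mesh solver agrees with the analytic radii, pressures and depth to ≲1 %.
This solver also shows the reference points of the tension models in the
absence of the eggshell: equal tensions give a pressure ratio of ~0.90, and
(3.4, 1, 3.4) gives ~3.1 with a much shallower contact bulge than under
strong confinement.

## Study conditions of the synthetic embryo

Real eggshell geometries and cell volumes for the original recordings are
not available, so the generator defines reference conditions: an eggshell of
half-axes 25 × 15 × 15 µm (±10 % per-axis jitter when sampling populations),
the two cells jointly filling 95 % of the shell volume, and the AB volume
fraction drawn from 0.55–0.60 (0.58 for the fixed reference geometry).
These reproduce the homogeneous model's published behaviour well (pressure
ratio ≈ 0.95 vs 0.9; depth ≈ −0.39 µm vs −0.4 µm).  For the heterogeneous
model the results are qualitatively right but quantitatively confinement-
sensitive: at 95 % packing the solver converges to a pressure ratio of
≈ 2.5 and a depth of ≈ +4.3 µm, whereas the free bubble gives 3.1 and
+1.85 µm — the published values (3.0 and +2.9 µm) lie between the two, i.e.
they correspond to an intermediate, unrecorded degree of eggshell
confinement (equivalently, a perivitelline volume between 0 and 5 %).  The
packing fraction is deliberately left at its declared default rather than
tuned to reproduce the published depth; the sensitivity itself is the
finding.

## Rendering and segmentation

The synthetic confocal stack places a thin Gaussian membrane shell
(σ = 0.35 µm) around the equilibrium surfaces (point-to-mesh distances
against a twice-subdivided copy of the mesh) and around the eggshell
ellipsoid, blurs with an anisotropic Gaussian PSF (0.2 µm lateral, 0.6 µm
axial), and samples onto 0.244 × 0.244 × 0.733 µm voxels; noise is Poisson
photon noise (200 photons at the membrane peak) plus Gaussian read noise
(σ = 2 counts), all driven by one seeded generator so stacks are
bit-reproducible.  Segmentation smooths with a Gaussian (σ = 0.5 µm,
configurable — no canonical value exists), resamples to cubic 0.733 µm
voxels, and floods the membrane intensity directly (it is already
ridge-like) with a marker-based watershed; the one-voxel boundary line is
then carved on the intensity crest — at every face-adjacent voxel pair with
differing labels the brighter voxel joins the boundary — so the line
straddles the membrane ridge, which is the geometry the half-boundary volume
correction assumes.  Cell volume uses the half-boundary correction
`V = (N_cell + N_bnd/2)·voxel volume` with face-adjacent (6-connected)
boundary counting; on digitized spheres of radius 8–30 voxels its error is
below 1 % (max 0.64 % in the acceptance run), but it is biased on sharply
cornered regions (a cube with a full boundary shell is underestimated), so
it is specified for smooth shapes only.  For voxel-wise comparisons the
boundary class, which true label maps lack, is resolved first: each boundary
voxel sits on the intensity crest, the true surface within it is displaced
toward its brighter neighbour, so the voxel is assigned to the region of its
dimmest face neighbour (nearest region when no intensity image is supplied).

## Tension fitting

The grid search scans `γ_AB, γ_cnt ∈ {0.2, 0.4, …, 10.0}` (514 admissible
combinations under the tension triangle inequality, enumerated in exact
rational arithmetic because the count is endpoint-sensitive), minimizes each
candidate, and registers the model vertices onto the target contour voxels
by ICP — directional nearest-neighbour correspondence, Kabsch rigid updates,
centroid + principal-axes initialization with the axis-sign ambiguity
resolved by RMSE, convergence at an RMSE improvement below 1e-6 µm.  The
reported score is the RMSE of the final correspondences; the admissible pair
with the smallest RMSE wins.  Equilibria are target-independent and can be
cached across targets (`grid_equilibria`).  Because the correspondence is
directional (model vertex → nearest target point), the target should be a
dense contour (segmented membrane voxels or a full vertex set); sparse
targets add an RMSE floor of about half their point spacing, which can
reorder close grid candidates.

## What the synthetic data do and do not show

Generators emulate the geometry, optics and noise of the original
recordings, but not: real perivitelline-space geometry, membrane
invaginations or blebs, spatially varying background, cytoplasmic
autofluorescence, or drift between frames.  Passing the closure tests
(render → segment → volumes within 3 %, Dice > 0.97; tension recovery exact
on noise-free targets and within one grid step under rendering noise)
therefore demonstrates internal consistency of the pipeline, not performance
on raw microscope data.  Kymograph path lines are supplied as labelled
tracks by the generator; selecting streaks from a real kymograph was a
manual step and is out of scope.

## Numerical choices and known limitations

* Test and example runs use reduced problem sizes chosen as the package's
  own defaults: fitting sweeps run at 1 408 triangles (`faces_per_edge=1`)
  and recovery grids are 3 × 3 around the optimum; reference equilibria use
  the full 5 632-triangle schedule.
* The pressure *ratio* in strongly confined heterogeneous states retains a
  few-percent mesh sensitivity (≈ 2.5 at three subdivision rounds vs ≈ 2.6 at
  four); depth and energy are stable to ≪1 %.  Free-bubble results are
  mesh-converged at the default resolution.
* The equilibrium is found by local descent from the standard two-cube
  initialization.  Continuation experiments (re-minimizing from a different
  model's equilibrium) can stall in higher-energy states, so comparisons
  between runs should use the deterministic default initialization.
* Degenerate inputs raise: non-closed bodies, coplanar point sets for the
  ellipsoid fit, collinear ICP sources, coincident watershed markers,
  contacts with fewer than three boundary vertices, non-positive
  normalization divisors.
* The ellipsoid fit is plain algebraic least squares on the general quadric
  with uniform point weights (no contour-voxel weighting scheme is defined
  for the original data) followed by eigendecomposition; on noise-free
  samples it is exact to ~1e-8, and with 0.2 µm isotropic point noise the
  semi-axes are recovered to better than 2 %.
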