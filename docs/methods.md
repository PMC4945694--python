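# Methods

`nucleoflux` models how cell spreading modulates the passive transport of
transcription factors from the cytoplasm into the nucleus.  The cell is an
idealized two-phase sphere — a nucleus of radius 5 µm concentric inside a
cell of radius 10 µm — whose spreading is imposed as a ramped boundary
displacement.  The resulting finite-strain field enters a transient
diffusion problem through a Jacobian-dependent diffusivity, and the
observable of interest is the diffusive flux at the nucleus–cytoplasm
interface relative to an undeformed ("roundish") reference cell.  A second,
independent component fits ellipsoids to binary 3D masks of segmented
nuclei and derives the population shape statistics used to parameterize
the spread configurations; a synthetic voxel-phantom generator stands in
for confocal data.

## Mechanics

Both phases are homogeneous, isotropic Saint Venant–Kirchhoff solids:
S = λ tr(E) I + 2µ E, with E = ½(FᵀF − I) the Green–Lagrange strain and
F = ∇u + I the deformation gradient (gradients with respect to reference
coordinates; total-Lagrangian setting).  This is the unique hyperelastic
law whose second Piola–Kirchhoff stress is linear in E through a constant
isotropic stiffness.  Defaults: E = 5 kPa (nucleus), 1 kPa (cytoplasm),
ν = 0.35 for both — a compressibility consistent with the ~10 % nuclear
volume gain observed for spread nuclei.  The solve is quasi-static: with
µm lengths, kPa moduli and ~1 s ramps, inertial stresses are ~15 orders of
magnitude below elastic ones, so each load step solves ∇·(S Fᵀ) = 0.
Reference density and body force are carried in the data model but unused
by default.

Discretization: 10-node quadratic tetrahedra on a structured octant of the
two concentric spheres (X, Y, Z ≥ 0, symmetry planes with zero normal
displacement), or 6-node quadratic triangles on an axisymmetric (R, Z)
quarter disc for azimuth-independent programs.  The structured generator
places a grid layer exactly on the interface sphere (conforming two-phase
interface, perfect adhesion by shared nodes) and snaps mid-edge nodes of
constant-radius layers onto their spheres, so curved boundaries are
integrated isoparametrically (octant volume accurate to ~1e-5 at desk
resolution).  Hexahedral cells are split by the translation-invariant Kuhn
scheme, which stays conforming across the collapsed cells at the center
and pole.  Default desk resolutions: target edge 1.4 µm in 3D (~5.6 k
tetrahedra, ~25 k displacement unknowns) and 0.35 µm in 2D (~2.4 k
triangles).  At these resolutions the headline fields are mesh-converged
to well within the tolerances quoted for them (the peak nuclear volumetric
strain changes by ~1 % between the 2D desk mesh and its double).

Newton iteration uses the consistent tangent (geometric + material parts
assembled through one operator G mapping element dof rates to F-rates; the
axisymmetric G carries the hoop term u_R/R), a backtracking line search on
the residual norm, modified-Newton reuse of the sparse LU factorization
within a load step, and automatic halving of load increments on failure.
Transient element inversion at intermediate iterates is tolerated; a
converged state with J ≤ 0 is rejected.  Convergence: free-residual norm
below 1e-8 relative to the step's initial out-of-balance force.

### Boundary program

Spreading is driven by the displacement of the outer boundary.  The
equatorial radial displacement is either uniform in azimuth (amplitude uₓ)
or varies smoothly as u_r(φ) = uₓ cos²φ + u_y sin²φ between the X and Y
axes.  Over latitude, the default profile extends this trace to the whole
outer surface as the diagonal sphere-to-ellipsoid map

    u(X) = (diag(aₓ, a_y, g) − I) X,   aₓ = 1 + uₓ/R,  a_y = 1 + u_y/R,
    g = volume_factor / (aₓ a_y),

i.e., the cell boundary deforms into an ellipsoid whose volume is scaled
by `volume_factor`.  This was a genuinely open design point, settled by
experiment: a thin equatorial Dirichlet band (kept available as
`profile="band"`) transfers only ~25 % of its amplitude to the nucleus,
concentrates J into a shear band at the interface near 65° latitude
(J ~ 0.4–0.5 at modest amplitudes, where the SVK tangent loses
ellipticity), and cannot produce the smooth, near-homogeneous strain
fields (J ∈ [0.9, 1.1]) that spread cells — and the model's own predicted
diffusivity and stress magnitudes — require.  The ellipsoidal map is also
an exact equilibrium field for a homogeneous body, which supplies the
Newton predictor and makes the solve robust.  The map prescribes the full
boundary displacement vector; for the uniform program its equatorial trace
coincides with prescribing the radial component alone, by symmetry.

`volume_factor` defaults to 1.3: at the reference operating point (uniform
amplitude 4 µm, see below) this reproduces the ~10 % nuclear volume gain
measured for spread versus roundish nuclei, which is the same observation
that motivates ν = 0.35.  The deformed nucleus then shows its maximum
volumetric strain ε_V = J − 1 of ~8 % at the nucleus top (uniform program)
or along a parallel near +65–75° latitude close to the X axis (azimuthal
program).

### Amplitudes and calibration

The uniform ("axisymmetric-equivalent") scenario prescribes the equatorial
boundary displacement a* = 4 µm directly.  The azimuthal scenario keeps
the azimuthal mean of its two amplitudes equal to a* and secant-calibrates
the X/Y split until the deformed nucleus in-plane aspect ratio matches the
spread-group elongation index b/a = 0.9 (the calibration solves run on a
coarsened octant; a hyperelastic quasi-static ramp's final state depends
only on the final amplitude, so few load steps suffice).  A general
`calibrate_amplitude` routine is also provided that secant-iterates
amplitudes to prescribed deformed nucleus extents within 1 %.

The measured spread-group major semi-axis (7.89 µm) is *not* usable as a
deformed-nucleus target in this model: driving the 5 kPa SVK nucleus to a
7.89 µm in-plane semi-axis forces volume-average stresses of 12–19 kPa and
J excursions to ~2 — an order of magnitude beyond every stress, strain and
diffusivity magnitude the model family predicts at its documented
operating point.  The a* = 4 µm boundary amplitude is the self-consistent
reading; the discrepancy is documented here deliberately.

### Stress summaries

Cauchy stress σ = J⁻¹ F S Fᵀ is evaluated per quadrature point and
volume-averaged over the nucleus with the current (deformed) measure
J dV₀.  Reported components: the normal stresses along the fitted
ellipsoid's major (X) and minor (vertical Z) axes and the in-plane (X–Z)
shear, in Pa, as magnitudes.  Note that for a symmetric octant under the
diagonal-map program the volume-averaged shear is structurally near zero
and the minor-axis average is far smaller than the major-axis one; other
averaging measures (line averages along the axes, averages of pointwise
magnitudes) give substantially different numbers, and the choice is
documented rather than hidden.

## Diffusion

Fick's second law ∂c/∂t = ∇·(D ∇c) is solved on the *reference* mesh with
the strain-dependent coefficient

    D(J) = D₀ (e^J − 1)/(e − 1),

which vanishes at full densification (D(0) = 0) and recovers the baseline
at J = 1.  The pull-back metric terms of a fully consistent Lagrangian
transport formulation are deliberately omitted — the coupling is a
spatially varying coefficient on the fixed reference domain.  This is a
fidelity choice, part of the model definition, and it matters: it means
deformation influences transport only through D(J), never through the
deformed geometry.

Parameters: D₀ = 30.0 µm²/s (cytoplasm), 29.2 µm²/s (nucleus); initial
concentration 0.2 µmol/ml in the cytoplasm, 0 in the nucleus (interface
nodes take the cytoplasm value by default; `nucleus` and `mean` are
config switches, and the `mean` assignment is used when comparing against
oracles with symmetric step data since it halves the interpolation bias of
the discontinuous initial condition).  All normalized observables are
unit-free by linearity, so the concentration unit never matters.

The outer boundary is insulated (natural in the Galerkin form);
concentration and normal flux are continuous across the conforming
interface.  Time integration is implicit BDF (order 1 startup, order 2
with variable-step coefficients), with the step capped at t_f/50 during
the loading ramp — where the stiffness matrix is reassembled from the
time-interpolated J field each step — and growing geometrically to 0.25 s
afterwards, where the operator is frozen and factorizations are cached.
Because the diffusion stiffness has zero row sums, the scheme conserves
the total amount exactly up to linear-solver roundoff (< 1e-12 in
practice).  Default horizon t_end = 5 s (≈ 6 nominal diffusion times
R²/D of the nucleus).

Coupling modes: `simultaneous` starts the ramp and the diffusion clock
together (working hypothesis); `sequential` freezes the final Jacobian
field into D(J) and diffuses from the undisturbed initial condition
(deform-then-diffuse).

### Flux probe and normalization

The tracked observable is ‖φ‖ = ‖−D ∇c‖ at one material point: the
interface-adjacent quadrature point (nucleus side) with the largest flux
at the instant the spread configuration is attained (end of ramp).  Its
history is divided by the same point's history in an undeformed reference
run.  The reference run replays the deformed run's exact time-step
sequence — interpolating an exponentially decaying flux between coarse
time samples corrupts the ratio, so grid-sharing is enforced — and samples
where the reference flux falls below 1e-3 of its maximum are masked (NaN)
rather than silently divided, because the ratio of two equilibrated,
roundoff-dominated fluxes is meaningless.

A caveat the package makes explicit rather than papering over: with the
default diffusivities the slowest diffusion mode of the insulated
two-phase cell has a time constant of ~0.17 s (first root of
tan(kR) = kR at R = 10 µm), so the concentration field equilibrates
within a 1-s ramp and the D(J)-driven flux enhancement (local ceiling
D(J_max)/D₀ ≈ 1.13 at ε_V ≈ 8 %) competes against the faster depletion it
itself causes.  The computed normalized-flux peaks are therefore modest
(~1.0–1.06) and occur early in the ramp.  Peaks of ~1.4 at the end of the
ramp would require flux kinetics several times slower than these
parameters imply.  The crude 1-D estimate R²/D = 0.83 s (nucleus radius,
cytoplasm D₀) overstates the true modal time by ~5×.

## Morphometry and synthetic data

Nuclear masks are binary voxel grids on an anisotropic lattice (default
0.207 × 0.207 × 1.0 µm, emulating confocal z-stacks).  The best-fit
ellipsoid comes from the first and second central moments of the solid
foreground: for a uniform solid ellipsoid the principal second moments are
axis²/5, so semi-axes are √(5·eigenvalue) of the moment tensor, sorted
a ≥ b ≥ c, with the eigenvectors as orientation.  The voxel-center scatter
is used directly as a midpoint-rule estimate of the continuum moments
(adding the per-voxel cube self-moment double-counts and biases the short
axis on 1 µm slices).  Empty, disconnected (6-connectivity) and
rank-deficient masks are rejected with specific errors.  Surface area uses
the exact Legendre incomplete-elliptic-integral form (relative accuracy
≪ 1e-6), with an adaptive-quadrature fallback near the sphere limit;
volume is reported both as (4/3)πabc and as the raw voxel count × voxel
volume (quality control).

Shape indices: elongation b/a and flatness c/a.  Classification —
disk-like (elongation ≥ 0.9, flatness < 2/3), spherical (both ≥ 0.9),
rod-like (elongation < 0.9 and ≈ flatness within 0.1), else other; the
0.9 threshold renders "close to unity" and is configurable.  Group
summaries report mean, SD (n−1), and a 99 % interval half-width rendered
as ±2.576·SD dispersion bars by default (a per-cell dispersion reading of
"99 % quantiles as confidence intervals"); a standard-error mode is the
config alternative.  Feature ratios a/a₀, S/S₀, V/V₀ divide group means by
the roundish-group means.

The generator draws the major semi-axis from a truncated normal (a > 0)
with the measured group statistics — spread 7.89 ± 1.41 µm, half-spread
7.85 ± 1.30 µm, roundish 5.30 ± 0.73 µm — and builds b, c from elongation
and flatness indices truncated to (0, 1], which guarantees a ≥ b ≥ c by
construction.  The per-group index means (spread 0.90/0.45, half-spread
0.80/0.65, roundish 0.95/0.90, SDs 0.03–0.08) are qualitative readings of
the published scatter regions; they are configuration values, placeholders
never used as reference numbers anywhere.  Orientations are Haar-uniform
rotations.  Voxelization is by center inclusion (a voxel is foreground iff
its center lies inside the ellipsoid) — the simplest reproducible rule,
whose O(spacing²) bias the 3 % fit tolerance absorbs.  `perturb_mask`
emulates residual segmentation noise: independent voxel flips followed by
one majority vote over the 6-neighborhood plus the voxel itself, mimicking
manual artifact removal.

What the phantoms do *not* emulate: intensity images (no PSF, no staining
noise, no thresholding), partial-volume effects, nuclear surface
roughness, or cell-to-cell correlation.  Passing recovery tests therefore
demonstrates the correctness of the measurement pipeline on ideal
ellipsoidal geometry, not segmentation robustness on real stacks.

## Verification

- Octant/axisymmetric mesh measures against closed forms; conformity of
  every interface facet; positivity of isoparametric Jacobians.
- Mechanics: Lamé closed forms; homogeneous-deformation kinematics by
  hand; small-strain agreement (< 1 %) with an independent linear-elastic
  solve of the same boundary-value problem; objectivity under superposed
  rigid rotation; octant vs axisymmetric solution agreement (< 2 %) for
  the uniform program; calibration self-consistency.
- Diffusion: exact D(J) endpoint identities; mass conservation < 1e-6;
  single-phase insulated-sphere eigenfunction series; an independent 1-D
  conservative radial finite-difference oracle for the two-phase problem
  (< 1 % of the concentration scale); linearity in the initial
  concentration; approximate discrete maximum principle.
- Morphometry: generator → fit round trips within 3 % per semi-axis over
  semi-axes 3–10 µm, rotated and axis-aligned; surface area against
  quadrature and triangulation oracles; spacing invariance.
- Scenarios: bitwise determinism; the azimuthal program with equal targets
  reproduces the uniform program on the same mesh (< 2 %); the
  amplitude → 0 limit drives the normalized-flux peak to 1.

## Known limitations

- No cytoskeleton, cortical layer, substrate contact or viscoelasticity;
  the two homogeneous phases are the entire mechanical model.
- No nuclear-envelope or pore-complex permeability; the interface carries
  no resistance, so interface flux continuity is purely geometric.
- The transport equation lives on the reference configuration; advective
  and metric effects of the deformation are excluded by construction.
- SVK is meaningful for moderate strains; the solver rejects states with
  inverted elements but the material itself softens under strong
  compression, which bounds the reachable boundary amplitudes.
- The flux normalization is sensitive to late-time noise once the cell has
  equilibrated; masked samples make this explicit.
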