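# Methods

This note records the models implemented in `ffcraft`, the defaults and
why they were chosen, the numerical choices that matter, and what the
synthetic fixtures do and do not emulate.

## Molecular representation

Structures are element lists plus Cartesian coordinates in Å with an
undirected bond graph over 0-based indices (1-based only at the CLI).
Connectivity is perceived geometrically: a bond exists where the
distance is at most `tolerance × (r_cov(a) + r_cov(b))` with Cordero
covalent radii and tolerance 1.3; distances under 0.4 Å are treated as
input errors. Torsions follow the IUPAC sign convention (positive
counter-clockwise looking down j→k) with range (−180°, 180°].
`set_dihedral_in_degrees` rotates the distal fragment rigidly about the
bond axis, which requires the axis to be acyclic; ring bonds raise an
error. Rotatable-bond detection keeps acyclic bonds between
non-terminal atoms, drops pure CH₃ rotors when asked, and assigns
torsional multiplicity by a neighbor-count hybridization rule: 3 when
both ends have four neighbors (sp³–sp³), otherwise 2. This rule is a
package convention — different perception schemes give different
conformer counts, and no claim of uniqueness is made.

## MM potential

The energy is the classical fixed-charge form: harmonic bonds and
angles (`E = ½k Δx²`, GROMACS convention), the cosine torsion series
`Σᵢ Aᵢ[1 + cos(pᵢφ − φᵢ)]`, 12-6 Lennard-Jones with Lorentz–Berthelot
combining, and Coulomb with `k_e = 1389.35 kJ Å/mol`. Pairs separated
by one or two bonds are excluded; 1-4 pairs are scaled by 1/1.2
(Coulomb) and 1/2 (LJ), the AMBER convention. Internal units are Å,
kJ/mol, radians, elementary charges; GROMACS units (nm, degrees for
phases) appear only in the topology writer/reader, which uses funct 1
bonds/angles and funct 9 proper dihedrals (one line per cosine term).
Gradients are analytic throughout; the test suite checks them against
central finite differences and verifies zero net force and torque.

## Seminario constants

Bond constants follow the interatomic-block eigenanalysis:
`k_ab = Σₘ λₘ |û_ab·v̂ₘ|` over the eigenpairs of `−H[a,b]`. For angles
we keep the perpendicular-vector projections `Σₘ λₘ |û_P·v̂ₘ|` of the
two terminal-atom blocks but rescale the harmonic combination by the
geometric factor

```
C = 1/(1 − cosθ·r_ab/r_cb) + 1/(1 − cosθ·r_cb/r_ab),
k_θ = C / [ 1/(r_ab² Σ_ab) + 1/(r_cb² Σ_cb) ].
```

Rationale: for a Hessian generated by an isolated harmonic angle k, the
projected sums are exactly `k(1 − cosθ·r_ab/r_cb)/r_ab²` (and
symmetrically), so the unscaled harmonic combination returns
`k(1 − cosθ)/2` — a ~37% underestimate at tetrahedral angles. The
factor C makes the isolated-angle Hessian invert exactly and reduces to
a smooth geometric rescaling for general Hessians. Negative constants
(possible off-stationary or for noisy Hessians) are clamped to zero
with a warning path. Equilibrium values are always read from the input
geometry, so the method assumes the Hessian was evaluated at a
stationary structure.

## Generalized Born (OBC-II)

The implicit-solvent term uses HCT pairwise descreening integrals with
OBC-II rescaling (α = 1.0, β = 0.8, γ = 4.85, offset 0.09 Å) and the
standard pairwise energy with `f_GB = sqrt(r² + BᵢBⱼ exp(−r²/4BᵢBⱼ))`,
dielectric 78.5 by default and user-resettable. Radii passed in are
intrinsic (already offset) Born radii; when omitted they default to
Bondi van der Waals radii minus the offset. For a single ion the
expression reduces analytically to the Born self-energy, which the
tests exploit. The term is used only as an optional addition during
conformer minimization, where its gradient is taken by central finite
differences — acceptable because the molecules minimized here are
small; an analytic GB gradient would be the first optimization if the
module were used on larger systems.

## Torsion refitting

The fit is linear least squares over the amplitudes of all cosine terms
whose quadruple shares the scanned central bond, grouped by (p, φ₀)
with one tied amplitude per group, plus a free constant that is
discarded afterwards. The residual target is
`E_ref(φ) − E_MM,rest(φ)` with the fitted amplitudes zeroed in
`E_MM,rest`. Scan geometries are taken from the scan file when present,
otherwise generated by rigid rotation. Extrema selection uses the sign
change of finite differences on the angle grid, treated periodically
when the scan spans 360°. No weighting or regularization is applied;
rank deficiency (duplicate (p, φ₀)) and under-determined fits raise
errors rather than silently truncating. Because the problem is linear,
refitting an unchanged scan is exactly idempotent and adding basis
terms can only lower the residual — both are asserted in the tests.

Scan files are multi-frame XYZ whose comment lines read
`Scan i-j-k-l Dihedral <deg> Energy <value> [unit]` with 1-based atom
labels; the unit token defaults to hartree
(× 2625.4996 kJ/mol) since reference data usually comes from electronic
structure; `kj/mol`, `kcal/mol` and `ev` are accepted.

## Interpolation mechanics

*Internal coordinates.* All bonds, all angles, all proper torsions from
the bond graph, in a fixed deterministic order; torsion components are
flagged periodic and displacement differences are wrapped into
(−π, π]. Angles beyond 175° can be listed via `flag_linear_angles`;
they are kept in the set but make the B-matrix ill-conditioned, which
the rank check below catches.

*Derivative transformation.* `g_int = (BBᵀ)⁻¹B g_cart` via a pseudo-
inverse with relative singular-value cutoff 1e−8;
`H_int = B⁺ᵀ(H_cart − Σₘ (g_int)ₘ ∂Bₘ/∂x)B⁺` with ∂B/∂x by central
finite differences (h = 1e−5 Å) of the analytic B rows — more robust
than hand-coded second derivatives of torsions. If fewer than
min(M, 3N−6) singular values survive the cutoff, the geometry is
declared rank-collapsed and the transformation refuses to proceed.

*Weights.* Distances are all-atom best-fit Kabsch RMSDs, no mass
weighting. Default weighting is the modified Shepard form
`vₖ = [(d/rₖ)²ᵖ + (d/rₖ)²𐞥]⁻¹` with 2p = 12, 2q = 2, normalized to
Σw = 1; a one-part `d⁻²ᵖ` mode is selectable. The confidence radius
`rₖ` of every point is the RMSD to its nearest database neighbor
(0.5 Å until a neighbor exists); radii are recomputed on every
insertion. Exponents and the radius rule are package defaults, exposed
on the database object, chosen so that the high power localizes each
expansion while the low power keeps far-field weights smooth. Exact
hits (d < 1e−10) short-circuit to the stored expansion, making
interpolation-through-data exact by construction.

*Gradients.* ∇w goes through the analytic gradient of the Kabsch RMSD
(envelope theorem at the optimal superposition: `(x_c − y_fit)/(N·d)`),
so the IM gradient is fully analytic; the suite checks it against
finite differences at 1e−5 and checks rigid-motion invariance of the
energy.

*Adaptive build.* Ten seed structures equidistant over the full 360°
rotation of the key torsion, each relaxed on the oracle by projected
gradient descent (torsion component removed, dihedral re-imposed every
step, backtracking line search, convergence at max |g⊥| < 0.1
kJ/mol/Å). After each seed joins the database, Langevin sampling runs
on the *current* IM surface with a flat-bottom wall (500 kJ/mol/rad²)
outside ±18° of the seed angle; any sampled structure whose IM energy
deviates from the oracle by more than 8.4 kJ/mol is added, and a run
ends after 7.5 ps without additions. `confirm_database_quality`
repeats unrestrained test simulations, adding every above-threshold
structure, until a full pass adds nothing; an iteration cap raises an
error that carries the partial database. Thermostat: BAOAB-split
velocity Verlet with friction 5 ps⁻¹, 0.5 fs step, 300 K default. The
dynamics exists to *sample* around each seed, not to generate correct
ensembles, so the friction value is uncritical.

*Persistence.* HDF5 container with groups `/coords`
(bond/angle/torsion index tables), `/points/<k>/{q,E,g,H,x,r}` and
`/meta` (weight mode, exponents, format version); default filename
`im_database.h5`. Loading validates the layout and reports the expected
format version for foreign or truncated files.

## Conformer search

Enumeration takes each rotatable bond's minima from the dominant
(largest |A|) cosine term of the force field — minima at
`φ = (φ₀ + (2k+1)π)/p` for positive amplitude, shifted by π/p for
negative — falling back to `multiplicity` evenly spaced angles if the
bond carries no torsion term. The Cartesian product is capped at 10⁶
assignments, beyond which the error message points to MD sampling.
Minimization is SciPy L-BFGS-B on the analytic MM gradient with a
max-gradient acceptance of 0.5 kJ/mol/Å and a 2000-iteration cap;
non-converged conformers are dropped with a warning. Deduplication is a
greedy ascending-energy pass declaring two conformers identical iff
|ΔE| ≤ 0.1 kJ/mol *and* heavy-atom Kabsch RMSD ≤ 0.2 Å; symmetry
automorphisms are not considered, so symmetric molecules can overcount
(documented limitation). High-temperature sampling uses the same
Langevin integrator at 700 K by default — hot enough to cross typical
torsion barriers of tens of kJ/mol within picoseconds — taking equally
spaced snapshots that are then minimized and deduplicated.

## Solvation boxes

The cubic box edge is the solute's largest axis-aligned span plus twice
the padding (1.0 nm default). The target solvent count is
`⌊ρ·(L³ − V_solute)/m⌋` with the solute volume approximated as the sum
of van der Waals spheres without overlap correction — deliberately
crude; it biases the accessible volume slightly low for bonded atoms,
which is conservative for packing. Insertion draws batches of uniform
random positions and orientations (normalized-quaternion rotations),
accepts a candidate iff every atom stays inside the box and no atom is
within 1.8 Å of any already-placed atom (k-d tree query, brute-force
audited in the tests), and stops at the target or an attempt cap of
500 per molecule; achieving less than 90% of the target is an error.
Shipped solvents are SPC/E and TIP3P water (geometry + charges,
ρ = 0.997 g/cm³); any other solvent enters as a user template via
`SolventSpec` or `custom_solvate`, which places exact requested counts.
Counterions are Na⁺ for negative and Cl⁻ for positive solutes, placed
with the same overlap rules. The Galvani registry holds SPC/E
(φ_G = −57.7 kJ/mol per unit charge) only; corrections are
`ΔG − q·φ_G`. Writers emit .gro (nm), PDB (Å) and a .top counts
section; no equilibration is performed — a hook accepts an external
minimizer or dynamics callable.

## Toy oracles and what the tests show

The torsional oracle is a stiff harmonic frame (bond 3000 kJ/mol/Å²,
angle 500 kJ/mol/rad²) plus a cosine series on one dihedral; gradients
are analytic and the Hessian combines analytic curvature per internal
coordinate with finite-difference curvature of the internals
themselves, so energy/gradient/Hessian are mutually consistent to
better than 1e−5 (asserted by a shared consistency suite). The
harmonic oracle is a pure Cartesian quadratic. Fixture molecules
(water, ethane, butane, a twisted biphenyl, hydrogen peroxide) are
generated from internal coordinates at import time — nothing is read
from disk.

These fixtures emulate the *interfaces and failure modes* of real
reference data — smooth surfaces, consistent derivatives, torsional
multi-well structure — but not electronic effects: no conjugation
breaking, no charge transfer, no coupling between torsion and frame
beyond geometry. Passing tests therefore demonstrate that the
machinery (fitting, transformation, weighting, adaptive sampling,
packing) is correct, not that any particular chemical system is
described accurately; accuracy on real molecules is inherited from
whatever oracle or reference data the user supplies.

A known branch-cut caveat: Taylor expansions in wrapped torsion
displacements are not additive across the ±180° cut, so an oracle with
a single harmonic torsion minimum can be composed exactly from multiple
expansion points only away from the cut. The periodic cosine surfaces
the package targets do not have this problem; the test suite documents
it where it constructs quadratic-in-internals oracles.

## Problem sizes

Default test and acceptance runs use the 4-atom torsion fixture for
interpolation builds (10 seeds, 7.5 ps windows ≈ 150k dynamics steps),
butane for conformer and box tests, and ~30 Å water boxes (≈ 900
molecules) for density statistics — sizes chosen so the full pipeline,
including the adaptive build, completes in minutes on one CPU while
still exercising every code path at the protocol's stated constants.
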