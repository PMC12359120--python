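# ffcraft

Desk-scale force-field construction for small molecules: assemble a
molecular-mechanics (MM) force field, refit its torsion terms against
reference scans, extract harmonic constants from a Hessian, build an
interpolation-mechanics (IM) potential adaptively against any
energy/gradient/Hessian backend, enumerate conformers with Boltzmann
weighting, and pack solvated simulation boxes with counterion
neutralization.

The package is aimed at force-field developers and simulators who need
the *machinery* of parameterization — fitting, transformation,
enumeration, packing — decoupled from any particular quantum-chemistry
engine. Everywhere a QM code would normally supply energies, gradients
or Hessians, `ffcraft` accepts an **oracle**: any callable
`x -> (E, g, H)` in kJ/mol, kJ/mol/Å, kJ/mol/Å². Built-in analytic toy
oracles make every stage runnable and testable on a laptop.

## The models

**Torsion refitting.** Each rotatable bond carries a cosine series

```
V(φ) = Σᵢ Aᵢ [1 + cos(pᵢ φ − φᵢ)]
```

with barrier heights `Aᵢ`, integer periodicities `pᵢ` and phases `φᵢ`.
Given a reference scan `E_ref(φ)`, the amplitudes solve a linear least
squares problem on the residual `E_ref − E_MM,rest`, where `E_MM,rest`
is the force field with the fitted terms zeroed; a free constant
absorbs the arbitrary energy zero. Terms on equivalent quadruples
sharing the central bond are tied to one amplitude. `fit_extrema`
restricts the fit to interior extrema of the scan.

**Seminario constants.** Harmonic bond constants come from the
eigendecomposition of the negated 3×3 interatomic Hessian block,
`k_ab = Σₘ λₘ |û_ab·v̂ₘ|`; angle constants combine the perpendicular
in-plane projections of the two terminal-atom blocks, rescaled by the
geometric 1–3 coupling factor so an isolated harmonic-angle Hessian is
inverted exactly (see `docs/methods.md`).

**Interpolation mechanics.** The potential surface is a Shepard-weighted
sum of local second-order Taylor expansions in redundant internal
coordinates,

```
E(x) = Σₖ wₖ(x) [Eₖ + gₖᵀΔq + ½ΔqᵀHₖΔq],
```

with weights built from the best-fit (Kabsch) Cartesian RMSD between
the query and each stored reference structure, and derivatives
transformed through the Wilson B-matrix. The database is built
adaptively: ten oracle-relaxed seeds equidistant over a key torsion,
restrained sampling dynamics (±18°) on the current IM surface, a point
added whenever the IM-vs-oracle error exceeds 8.4 kJ/mol, and a
sampling run terminated after 7.5 ps without additions.

**Conformers and solvation.** Conformers come either from the Cartesian
product of per-bond torsional minima (each assignment minimized, then
deduplicated by joint energy/RMSD comparison) or from high-temperature
Langevin sampling (700 K default) with snapshot minimization.
Populations follow `pᵢ ∝ exp(−Eᵢ/k_BT)`. The solvation builder packs a
cubic box (solute extent + 2 × 1.0 nm padding by default) by random
batch insertion with a k-d tree overlap check against an
accessible-volume density target, adds Na⁺/Cl⁻ counterions to
neutrality, and applies the Galvani surface-potential correction
`−q·φ_G` (φ_G = −57.7 kJ/mol per unit charge for SPC/E water) to ionic
solvation free energies.

## Worked example

Refit the H–O–O–H torsion of hydrogen peroxide against a noisy
reference scan (generated here by the built-in fixtures; any multi-frame
XYZ scan file with `Scan i-j-k-l Dihedral <deg> Energy <value> [unit]`
comment lines works):

```python
from ffcraft.chem_core import write_xyz_file
from ffcraft.dihedral_refit import scan_geometries, write_scan_file
from ffcraft.toy_oracles import fixture_molecule, synthetic_scan

mol = fixture_molecule("peroxide")
scan = synthetic_scan((0, 1, 2, 3), [(6.5, 2, 0.0), (2.0, 1, 0.0)],
                      n_points=19, noise_sd=0.1, seed=4)
scan.geometries = scan_geometries(mol, scan)
write_xyz_file(mol, "peroxide.xyz")
write_scan_file("1-2-3-4.xyz", scan, mol, unit="kj/mol")
```

```console
$ ffcraft fit-dihedral peroxide.xyz --scan 1-2-3-4.xyz --add 1,0
fit over 19 points: RMSE 0.1132 kJ/mol, max deviation 0.2384 kJ/mol
  A =    -6.5163 kJ/mol  p = 2  phase =   180.00 deg
  A =     2.0008 kJ/mol  p = 1  phase =     0.00 deg
```

The scan was generated from amplitudes 6.5 (p=2, phase 0°) and 2.0
(p=1) with 0.1 kJ/mol of Gaussian noise. The fit recovers them — the
p=2 term is reported in the equivalent (A → −A, phase → phase+180°)
convention — and the RMSE sits at the noise floor. Other entry points:

```console
$ ffcraft mol info butane.xyz            # rotatable bonds and multiplicities
$ ffcraft conformers butane.xyz          # enumerated conformers + populations
$ ffcraft solvate butane.xyz --seed 7    # packed water box, .gro/.top output
$ ffcraft imbuild --seeds 10             # adaptive IM database demo -> im_database.h5
```

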