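# Methods

## The model

`molfrag` implements restrained structural refinement with
**non-interacting molecular fragments**. An engineered structural
constraint — a metal-ion bridge between two mutated residues
(Cys–Cd²⁺–Cys, Asp–Mg²⁺–Asp, His–Zn²⁺–His), a Lys/Glu salt bridge, or a
spin-label probed by DEER — is represented as an atomically detailed
sub-molecule overlaid on the host protein. Each fragment

* carries its own backbone atoms (N, C, O, C_α) for the patched
  residue(s), tied to the host backbone by harmonic **anchor
  restraints** E = k(d − 0)²;
* interacts normally within itself;
* never interacts with any other fragment;
* never interacts with its target host residue, and its backbone never
  interacts with the backbone of host residues i−1, i+1;
* sees the rest of the environment through interactions scaled by 1/N
  when the fragment is one of N copies of a spin-label.

Because mutually exclusive constraints (two different mutations at one
site, overlapping labels) cannot clash sterically, many independent
experiments can be imposed on a single model simultaneously; the shared
host backbone is the only medium through which they communicate, which
is exactly the quantity being refined.

### Soft-core effective distance

All pair interactions involving a fragment atom are evaluated at
r′ = √(r² + Δ), with Δ ≥ 0 (Å²) a user parameter (default 1 Å²). This
bounds energies and forces at atomic overlap — overlaps are expected by
construction, since fragments are transparent to each other and to
parts of the host. Host–host pairs use the plain distance. Δ = 0
recovers the standard interaction identically.

### Nonbonded terms

Lennard-Jones in ε/R_min form with geometric-mean ε and additive
R_min/2 combination, plus Coulomb with constant dielectric
(332.0636 kcal·Å/mol/e²). Both terms are multiplied by a C¹ switching
function that is 1 below `switch_on` (default 10 Å) and 0 beyond
`cutoff` (default 12 Å). Applying the switch to Coulomb as well as LJ
keeps the total energy once-differentiable at both boundaries, which
the force audit requires; a bare Coulomb truncation would inject force
spikes at the cutoff. There is no reciprocal-space electrostatics. For
anyone swapping in a long-range solver, the contract is: only the host
protein's charges may be accumulated on the mesh; fragments always
interact with their surroundings through the truncated real-space
terms, because fragment–fragment subtraction is intractable on a grid.

Standard 1-2/1-3 bonded exclusions apply everywhere. Pair scales are
symmetric, and the total decomposes exactly as
E = E_host–host + Σ_f E_intra(f) + Σ_f s_f·E_cross(f, host),
which the tests assert to 1e-9 kcal/mol.

### Bridge restraints

Harmonic terms use E = k(x − x₀)² with **no factor ½** (the convention
under which the shipped force constants are meaningful). Defaults:

| term | k | x₀ |
| --- | --- | --- |
| S_γ–Cd²⁺ bond | 10 kcal/mol/Å² | 2.6 Å |
| O_δ2–Mg²⁺, N_ε–Zn²⁺ bonds | 10 kcal/mol/Å² | 2.1 Å |
| S_γ–Cd–S_γ, O_δ2–Mg–O_δ2 angles | 10 kcal/mol/rad² | 180° |
| C_ε1–N_ε–Zn, C_δ2–N_ε–Zn angles | 10 kcal/mol/rad² | 127.0°, 125.5° |
| C_γ–C_δ2–N_ε–Zn dihedral | 10 kcal/mol/rad² | 180° |
| N_ε–C_δ2–C_ε1–Zn, N_ε–C_ε1–C_δ2–Zn impropers | 10 kcal/mol/rad² | 0° |
| backbone anchors (bridges / labels) | 50 / 10 kcal/mol/Å² | 0 Å |
| salt bridge N_ζ–O_ε2 | 10 kcal/mol/Å² (configurable) | 3.5 Å |
| host backbone positional (reMD) | 100 kcal/mol/Å² | — |

Zn²⁺ coordinates through N_ε only; the angle/dihedral/improper set that
keeps the ion in the imidazole plane is applied to **both** histidines
(12 terms per Zn bridge). The salt-bridge fragment mutates site 1 to
lysine and site 2 to glutamate so the restrained N_ζ/O_ε2 pair and the
neutral net charge are self-contained; a Trp stabilizer mutation can be
requested explicitly via `mutations` but then carries no restraint.
Bridge residues are deprotonated (side chain −1) so every
two-residue-plus-divalent-ion fragment is electrically neutral; label
fragments are neutral outright.

Angle terms with θ₀ = 180° operate at the angular-gradient singularity
by design. Whenever |sin θ| < 1e-8 the term's forces are taken from the
quadratic expansion about the singular geometry, whose gradient at that
point is exactly zero — never NaN.

Force constants can follow **ramp schedules**: piecewise-linear scale
factors over the dynamics step counter, clamped outside the defined
stages. Turning bridges on gradually lets the host adjust without
shocks; the same mechanism ramps secondary-structure restraints (φ/ψ
dihedral wells at −57°/−47°) downward.

### Restrained-ensemble histogram energy

Each label site carries N copies (default 25), each scaled by 1/N. For
a site pair (i, j) the N² probe–probe distances (nitroxide oxygen for
the full label, the pseudo-atom for dummy labels) are smeared onto bin
centers nΔr, n = 1..60, Δr = 1 Å:

    raw(n) = (1/N²) Σ_{s,s'} (2πσ²)^{-1/2} exp(−(nΔr − d_ss')²/2σ²)

with σ = 1.1 Å, then renormalized to unit mass over the window,
h̄(n) = raw(n)/Σ raw·Δr. The energy against a target H (normalized the
same way) is

    U_RE = (K/2) Σ_pairs Σ_n (h̄(n) − H(n))²,  K = 500 kcal/mol/Å².

Forces are the exact gradient with respect to probe coordinates,
**including the quotient-rule term from the renormalization**: the
energy that is differentiated is exactly the energy that is evaluated,
which the finite-difference audit (relative 1e-6) checks. When nearly
all Gaussian mass lies inside the window the renormalization term is
numerically tiny, so an implementation that dropped it would differ
below typical tolerances; the exact gradient is used regardless. Forces
act only on probe atoms. A coincident probe pair contributes zero force
direction (the Gaussian itself is smooth there).

### Exclusion-group packing

An engine-level cap (default 255) limits how many distinct
non-interacting groups can exist, while 34 sites × 25 copies = 850
label copies are needed. Copies whose minimum interatomic separation
exceeds the nonbonded cutoff can share a group without ever
interacting. The packer is greedy first-fit over copies in site-major
order with ties to the lowest group index — deterministic, and the
within-group separation property is assertable by brute force. Copies
of the *same* site always conflict, so the group count is at least
n_copies; with all sites mutually beyond the cutoff it is exactly
n_copies (25 ≪ 255).

## Engine

* **Minimizer**: L-BFGS (scipy) driven by the summed force providers;
  the line search makes accepted energies monotone non-increasing, and
  the convergence criterion is max |force| ≤ tol. NaN energies abort
  with the offending provider's name.
* **Integrator**: BAOAB-split Langevin. Units: Å, fs, amu, kcal/mol,
  with acceleration conversion 4.184e-4 (kcal/mol/Å/amu → Å/fs²). At
  T = 0 with zero forces one step maps v → v·exp(−γ dt); with γ = 0 it
  reduces to velocity Verlet (harmonic-oscillator energy drift < 1e-4
  relative over 1e5 steps at dt = 1 fs). Velocities are
  Maxwell-Boltzmann initialized per stage, seeded. The default timestep
  is 1 fs: the internal force field has no constrained hydrogens (no
  hydrogens at all), so no constraint solver is needed or provided.
* **Neighbor list**: KD-tree pairs at cutoff + 2 Å skin, rebuilt when
  any atom moves more than half the skin. Pair accumulation is done in
  canonical (i, j) order so per-atom forces are bitwise reproducible
  for a given configuration — this is what lets the fragment-
  independence test demand exactly zero, not approximately zero.
* **Protocols**: `run_refinement` executes ordered minimize/dynamics
  stages, samples bridge geometry (ligand–ion and C_β–C_β distances)
  over the tail of the final stage and reports mean ± SD plus the worst
  anchor deviation. `run_restrained_ensemble` equilibrates without
  U_RE, then runs production with it, discarding the first quarter of
  production as transient before time-averaging h̄ per pair and
  reporting RMS bin deviations against the targets.

## Internal force field

Deliberately minimal: harmonic bonds and angles, cosine dihedrals,
heavy atoms only, with a small template table (ideal bond lengths,
angles and z-matrix construction) covering Cys, Asp, His, Lys, Glu,
Trp, a reduced MTSSL side chain, and a single-pseudo-atom dummy label
on a soft 4.6 Å tether from C_α (about the reach of three side-chain
bonds; k = 5 kcal/mol/Å² so the probe swivels freely). The imidazole
and indole rings are regular-polygon approximations that close exactly
under their harmonic terms. Partial charges are coarse: backbone sets
sum to zero, charged side chains carry integral net charges where the
chemistry demands it. This layer exists to give the restraint and
exclusion machinery realistic degrees of freedom at desk scale; it is
not a transferable force field and no claim about real-protein
energetics rests on it.

## Synthetic fixtures

* **Four-helix bundle** — four ideal α-helices (φ = −57°, ψ = −47°,
  NeRF-built backbone + C_β) on a 10 Å square lattice, antiparallel
  around the square, residues numbered 100·h + r so indices are
  globally unique. A catalog picks seven cross-helix residue pairs with
  C_β–C_β separations in the 8–16 Å window, mirroring the
  S1/S4–S2/S4–S2/S3–S3/S4 topology of engineered bridge experiments on
  voltage-sensor domains, so bridge combinations can be exercised as
  presets. Emulated: bridgeable geometry and helix packing. Not
  emulated: membrane environment, real VSD sequence/curvature, hence no
  conclusion about real refinement accuracy follows from these tests.
* **Label host** — a single-chain backbone scaffold threaded along a
  serpentine space curve through a grid whose nodes are the label
  sites, giving any number of sites with a declared minimum pairwise
  separation (needed to exercise the 850-copy grouping bound, which no
  compact 160-residue globule can host). Bonded equilibrium values are
  set to the built geometry so the scaffold starts strain-free; in
  ensemble runs the host backbone is additionally held by positional
  restraints (k = 100 kcal/mol/Å²), as the refinement target there is
  the label ensemble, not the scaffold.
* **Free probes** — bare pseudo-atoms, two ensembles in a 40 Å box,
  for isolating the histogram restraint.
* **Targets** — Gaussian-mixture histograms on the n·Δr grid, with an
  achievability check: each mode must lie within
  [d_sites − 2·reach, d_sites + 2·reach] of the site separation given
  the probe tether reach, unless explicitly overridden.

All fixtures are bit-for-bit reproducible from (recipe, seed).

## Numerical and design choices

* Harmonic convention k(x−x₀)² throughout (bonds, angles, anchors,
  positional); equipartition for E = kx² is ⟨x²⟩ = k_BT/2k, which the
  thermostat test verifies within 5 %.
* Δ default 1 Å²; exposed in config. Soft-core applies to both LJ and
  Coulomb for any fragment-involved pair.
* Histogram bin semantics: value at bin n is a density (Å⁻¹) at center
  n·Δr; every histogram the package returns integrates to 1 within
  1e-10.
* Grouping determinism: site-major greedy first-fit, lowest group
  wins.
* Copy spreading: each copy's side-chain χ torsions are offset by
  uniform draws from a seeded generator; dummy labels spread on the
  tether cone through their single torsion.
* PDB I/O is fixed-column ATOM/HETATM with exclusion-group ids stored
  in the segment columns (`G<id>`), so any number of copies survives a
  round trip even though chain characters repeat after 62 groups.
  Charges and LJ parameters are not representable in PDB and are
  reassigned from the element table on read; likewise bonded topology
  is not representable, so the CLI reconstructs backbone + C_β terms
  from the coordinates (strain-free, with measured equilibria) when it
  loads a host structure.

### Convergence demonstrations and problem sizes

The test suite scales the refinement protocols to desk size as the
package's own study conditions: the bundle demo runs 500 minimization
steps, 12 ps of ramped restrained dynamics and a final minimization;
the paper-scale analogue of this staging is nanoseconds long, so the
demo shows mechanism, not production statistics.

For the restrained-ensemble convergence demonstrations the bath is run
cold (50 K, friction 0.01–0.05 fs⁻¹) after an initial minimization.
The reason is physical: the time-averaged smoothed histogram of a
thermal ensemble carries an irreducible entropic broadening relative
to its target that scales like √(k_BT/K). For 25 untethered copies per
site at 300 K this floor is ≈ 0.016 Å⁻¹ RMS per bin — it does not
decay with longer averaging — while at 50 K the restraint machinery
drives the time-averaged RMS deviation below 0.01 Å⁻¹ well within 1e5
steps. The choice isolates what the demonstration is about (exactness
of the histogram forces and the ability of U_RE to steer an ensemble)
from a thermodynamic property of the toy conditions. The tethered
protein case the method is used on in practice starts with an
intrinsic ensemble close to the target, where this distinction is
immaterial.

## Known limitations

* No long-range electrostatics, no periodic boundaries, no barostat,
  no solvent or membrane: desk-scale mechanism testing only.
* The internal force field is not transferable; side-chain geometry is
  idealized and hydrogens are absent.
* The greedy grouper is first-fit, not optimal packing; it can refuse
  (with the achieved count) where an optimal packer would fit.
* Minimization uses L-BFGS line searches; on the 180° angle terms the
  guarded gradient is exact only to the quadratic expansion within
  |sin θ| < 1e-8 of the singularity.
* `read_pdb` handles the fixed-column ATOM/HETATM subset only — no
  MODEL records, insertion codes, or alternate locations.
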