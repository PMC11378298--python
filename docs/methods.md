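# Methods

## Scope and model

pocketedda analyses a protein–ligand complex as a set of capped fragments:
one ligand plus one fragment per binding-pocket residue. All energies are
kcal/mol, coordinates Å, charges in elementary charge units.

### Pocket extraction

A residue joins the pocket if its minimum *any-atom* distance (hydrogens
included) to any ligand atom is ≤ the cutoff, inclusive; the default cutoff
is 5.0 Å, the shell conventionally drawn around kinase-site ligands. The
inclusive boundary and any-atom convention make selection reproducible and
monotone in the cutoff. Waters are excluded by default and can be included
as single-fragment residues; whether a bridging water belongs in the energy
model is left to the user, since its occupancy and protonation are usually
uncertain at typical resolution.

Severed peptide bonds are capped with hydrogens only (no acetyl/N-methyl
caps): the removed backbone neighbor is replaced by an H placed along the
severed bond vector at 1.01 Å (N–H) or 1.09 Å (C–H). Heavy atoms are never
moved. Alternate locations resolve to the highest-occupancy conformer, ties
keeping the first listed, giving a deterministic single-conformer model.

Fragment formal charges follow physiological defaults when the input
carries no protonation information (Lys/Arg +1, Asp/Glu −1, His neutral).
Partial charges are made consistent with the formal charge by a *uniform
additive shift* across the fragment's atoms rather than multiplicative
scaling — the common case is an input with no partial charges at all, where
scaling has no solution.

### Classical energy backend

The built-in backend is deliberately transparent (every term has a closed
form a reviewer can check by hand):

* Coulomb: k_e q_i q_j / (ε_in r), k_e = 332.0637 kcal·Å/(mol·e²),
  ε_in = 1.
* Lennard-Jones: 4ε[(σ/r)¹² − (σ/r)⁶], Lorentz–Berthelot combining; the
  attractive branch reports as dispersion, the repulsive as repulsion.
* Hydrogen bonds: no separate potential is invented. Cross-fragment
  H···acceptor pairs whose X–H···A geometry passes fixed gates
  (H···A ≤ 2.5 Å, angle ≥ 120°, A ∈ {N, O, S}) have their Coulomb + LJ
  contribution *reattributed* to an hbond component. Totals are therefore
  independent of the gates by construction. The donor heavy atom is the
  H's bonded neighbor when a topology is attached, else the nearest heavy
  atom in its fragment.
* Solvation: generalized-Born polarization with Still-type effective
  radii, ΔG_pol = −½ k_e (1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB,
  f_GB = √(r² + a_i a_j e^{−r²/4a_i a_j}), ε_out = 78.5. Born radii are
  fixed per-element defaults (H 1.2, C 1.7, N 1.55, O 1.52, S 1.8 Å),
  user-overridable through the parameter-table format.
* Bonded terms: harmonic bonds ½k(r−r₀)² when a topology is attached,
  used by the deformation machinery and toy fixtures; pairs closer than
  three bonds are then excluded from nonbonded sums.

No cutoffs or neighbor lists: pockets are small and exact double sums keep
acceptance numbers bit-stable. Pair interactions use the supermolecule
definition E(L∪R) − E(L) − E(R), which for this strictly pairwise model
equals the direct cross-fragment sums (verified in the tests both ways).

An external engine (e.g. a semiempirical xtb-style binary) can be plugged
in via a command template and a regex that captures the total energy in
hartree (converted at 627.5095 kcal/mol/Eh). Engine totals are *not*
decomposed: component maps honestly flag what the backend cannot supply.

### Hydrogen refinement

Refinement minimizes the pair supermolecule's total energy over the
Cartesian coordinates of mobile hydrogens only, by gradient descent with a
backtracking (Armijo) line search — deterministic, strictly monotone, no
randomness. Gradients are analytic for the classical backend and central
finite differences (step 1e-4 Å) for the external engine. Termination: an
accepted step lowering the energy by less than the tolerance (default 1e-6
kcal/mol) or 500 iterations. Each pair is refined independently from the
original pocket geometry, preserving the pairwise partition, and the
monomer energies keep the pair-refined hydrogen positions. Refinement
defaults off for the classical backend (whose closed-form tests assume
fixed geometry) and on for the external engine via the CLI.

### Decomposition and mode comparison

Per mode, the ledger holds the gas-phase interaction sum, the pocket-level
desolvation, the ligand deformation energy, and their sum (the score).
Desolvation is computed at pocket level — GB of the whole pocket minus all
monomers — to avoid double counting; because the GB model is pairwise this
equals the sum of fragment-pair cross terms, and each residue's approximate
share is its ligand cross term plus half of each residue–residue term it
participates in (shares sum exactly to the pocket total).

Deformation is E_intra(bound) − E_intra(reference). The reference conformer
is user-supplied where available; otherwise it is generated by full
minimization of the bound pose with the classical backend (steepest descent
with line search, tolerance 1e-6), which makes the deformation non-negative
up to convergence noise.

Two modes compare residue-by-residue and component-by-component (A − B);
deltas are antisymmetric under swapping by construction. The verdict is
"dual" when |score(A) − score(B)| is within a configurable near-degeneracy
threshold, default 0.5 kcal/mol — chosen because energy gaps of a few
tenths of a kcal/mol are well inside both the physical thermal scale
(RT ≈ 0.6 kcal/mol at 298 K) and the accuracy of any pocket-scale energy
model, so neither orientation can honestly be excluded.

### Thermodynamics

ΔG_bind = ΔE_bind + ΔE_def + ΔH_TRV + ΔG_solv − T(ΔS_TRV + ΔS_conf), with
unset terms tracked explicitly in a ledger and never silently zeroed; the
minimum viable decomposition is ΔE_bind + ΔG_solv. Entropy terms are
accepted only as user inputs (e.g. from an external conformer-ensemble
tool); the package never computes them. Boltzmann weights use
R = 1.98720425864083e-3 kcal/(mol·K) and are shifted by the minimum energy
for overflow safety. Affinity ratios convert through ΔΔG = RT ln(K_A/K_B)
at a 1 M standard state; when IC50 values stand in for binding constants
the output is labeled "relative, IC50-proxy". Default temperature 298.15 K.

## Synthetic fixtures

The generators emulate the *shape* of the problem — a ligand surrounded by
a handful of close fragments with known charges — not protein geometry:

* Toy pockets: a planar five-site ring (radius 1.2 Å) with per-site
  charges, surrounded by 1–4-atom archetypes (point ions, water-like,
  methylamine-like) at chosen radial distances. Expected cross-fragment
  Coulomb energies are computed *inside the generator* from the closed
  form and carried in the pocket's provenance.
* Flip fixture: the pentagon is mirror-symmetric as a point set, so a
  180° flip maps the site positions onto themselves and only the charge
  pattern moves. With a symmetric pattern the two modes are exactly
  degenerate; with asymmetry ε on the mirror-paired sites the inter-mode
  delta reduces to the two swapped sites' Coulomb + GB terms, recorded in
  provenance as the closed-form expectation. All placements derive from a
  single seed (default 20240819).

What passing these tests shows: the energy bookkeeping, decomposition
conservation, symmetry logic and refinement contracts are exact. What they
do not show: agreement with experiment for real pockets, which depends on
the fidelity of charges, radii and the chosen backend — for production work
the external-engine adapter exists precisely so a quantum mechanical method
can supply the totals.

## Numerical choices

* Cross-fragment atoms closer than 0.1 Å raise a geometry error (a clash
  that close is a preparation bug, not a physics question).
* Interaction-map CSV serializes floats at 17 significant digits, so
  write → read round trips are exact.
* Pair enumeration orders by ascending closest contact, ties broken by
  residue number; map sums are order-independent (verified).
* Problem sizes in the acceptance script (50-pocket oracle sweep, 20
  refinement geometries) keep the whole run under a few seconds while
  exercising every code path; deviations are reported as maxima, so larger
  sweeps could only raise, never hide, a failure.

## Known limitations

* The classical component split is a transparent stand-in, not a
  quantum-mechanical energy decomposition; per-residue desolvation shares
  are approximate by construction and labeled so.
* Fixed per-element Born radii ignore burial (no perfect-radii
  integration); adequate for bookkeeping, not for absolute solvation.
* No protonation-state optimization, rotamer repair, or symmetry
  expansion; inputs are expected to be prepared structures.
* The external adapter only reads total energies; engines that print
  component breakdowns are not yet parsed.
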