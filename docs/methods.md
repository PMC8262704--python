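# Methods

## Scope and model

The package scores the nonbonded interactions between the constituting
residues of a protein 3D structure with a molecular-mechanical pair
potential and arranges the pairwise interaction energies (IEs) in a
symmetric residue×residue matrix (IEM) with a zero diagonal.  The total
(net) IE of a residue is its row sum.  Three electrostatics models are
offered; the Lennard-Jones term is common to all of them.

Bonded terms (bonds, angles, dihedrals) are deliberately absent: the IEM
is a nonbonded decomposition.  Poisson–Boltzmann solving is likewise out
of scope — its grid solutions are slow, implementation-sensitive, and
not pairwise separable, which is what the IEM formalism needs; the
generalized Born (GB) model is the analytic, pairwise-separable
approximation used instead.

## Electrostatics

* **vacuum** — Coulomb's law in a uniform dielectric `ε_in` (default 1).
* **dddc** — the legacy distance-dependent dielectric `ε(r) = c·r`.  No
  canonical functional form exists for this heuristic; the linear form
  with slope `c = 1` is used, making the interaction decay as `1/r²`.
  The slope is configurable.
* **gb** — the generalized Born pair term with the canonical smoothing
  function `f_GB = sqrt(r² + R_i R_j exp(−r²/4R_iR_j))` and screening
  prefactor `(1/ε_in − 1/ε_out)`.  `ε_out` defaults to 78.5 (water at
  room temperature); both dielectrics are configurable.  With
  `ε_out = ε_in` the term reduces exactly to vacuum Coulomb, and at
  large separation it tends to the screened Coulomb limit
  `k q_i q_j/(ε_out r)` — both limits are asserted in the test suite.

GB *self* terms (atom i with itself, and intra-residue solvation) are
not part of pairwise IEs: the IEM contains only cross-residue screened
interactions, so the matrix diagonal is zero by convention.

## Born radii (OBC model II)

Effective Born radii come from the Onufriev–Bashford–Case tanh
rescaling of Hawkins–Cramer–Truhlar (HCT) pairwise descreening
integrals:

```
I_i  = Σ_{j≠i} HCT(ρ̃_i, ρ_j, S_j, r_ij)        ρ̃_i = ρ_i − offset
Ψ_i  = I_i ρ̃_i
R_i⁻¹ = ρ̃_i⁻¹ − ρ_i⁻¹ tanh(α Ψ_i − β Ψ_i² + γ Ψ_i³)
```

with the model-II constants α = 1.0, β = 0.8, γ = 4.85 and dielectric
offset 0.09 Å (configurable through `ObcParameters`).  The HCT term is
the closed-form value of `(1/4π)∫ r'⁻⁴ dV` over the scaled sphere
`s_j = S_j ρ_j` at distance `r`, excluding the region inside `ρ̃_i`;
the implementation covers all four piecewise regimes (separated,
partially overlapping, engulfed, atom-inside-sphere) and is verified
against both 1-D adaptive quadrature and a fixed-seed Monte-Carlo
volume integral (≤1 % relative error at 4–10 million samples).

Radii are computed **once from the full structure** — this is what
makes GB pair energies sensitive to global geometry even though the sum
remains pairwise.  The tanh form bounds radii by `ρ̃_iρ_i/(ρ_i−ρ̃_i)`,
so genuinely infinite radii cannot occur; still, radii above 100 Å
(possible only for unphysically large intrinsic radii under heavy
descreening) are clamped with a warning rather than an error so that
malformed inputs remain diagnosable.

## Parameters and assignment

Parameters are looked up by `(residue_name, atom_name)` from a
`ParameterSet` (TSV schema
`residue atom charge sigma epsilon gb_rho gb_scale`).  The shipped
built-in table is a minimal, internally consistent illustrative set for
the 20 standard amino acids: class-based LJ values of common all-atom
magnitude, mbondi2-style GB radii (1.2 Å hydrogens, 1.3 Å on amide
nitrogens) with per-element HCT screening factors, and a simplified
charge scheme in which every neutral residue sums to 0 e and ionizable
side chains to their formal charge (±1 e).  It is intended for testing
and illustration; production scoring should load a real force-field
table through the same loader.

Terminal variants are resolved by name-based patches: the presence of
`OXT` triggers the carboxylate patch (residue total −1 e) and of
`H1/H2/H3` the ammonium patch (+1 e).  Atoms with no match are recorded
as *unassigned*, never dropped; energetics refuse structures whose
selected atoms are unassigned.  Conversely, template atoms absent from
the structure (typically hydrogens) are recorded as *missing* and the
pipeline refuses to run on them — hydrogens are never added, since
automated protonation is itself a well-known source of unphysical
contacts; users are expected to supply protonated structures.

Units are fixed package-wide — Å, elementary charges, kcal/mol,
Coulomb constant k = 332.0636 kcal·Å·mol⁻¹·e⁻² — to avoid kJ/kcal
mix-ups.

## Exclusion policy

By default **all** cross-residue atom pairs are summed, matching the
plain reading of a pairwise residue decomposition.  Covalently adjacent
residues then contribute large bonded-contact terms through the peptide
linkage; the optional `ff` policy removes cross-bond 1-2/1-3 pairs and
scales 1-4 pairs by the standard factors (1/1.2 electrostatics, 1/2
LJ).  Peptide bonds are detected geometrically (C–N under 2.0 Å between
consecutive residues of a chain), and bond separations are derived from
the invariant backbone topology, which is sufficient because only
backbone atoms and CB lie within three bonds of a neighbouring residue.

## Structure handling

PDB files are parsed with gemmi.  Only model 1 of multi-model (NMR)
files is used — the matrix is otherwise ill-defined; alternate
locations resolve to the highest-occupancy conformer (ties: first
record).  HETATM residues are retained and flagged; the CLI drops
unparameterizable hetero residues with a warning, while standard
residues with missing parameters are a hard error.  Residues are
reported by author numbering (`chain:resSeq:iCode:name`); internal
indices are dense and 0-based.

The backbone subgroup is the name set {N, CA, C, O, OXT} plus the
hydrogens bonded to N/CA (H, H1–H3, HA, HA2, HA3); the side-chain
subgroup is its complement, so the two always partition the residue.
Distances use either the closest cross-atom contact or mass-weighted
centres of mass (masses from the element table), with the subgroup
applied to both residues.  The combined matrix shows pair energies
within a contact threshold (default 5.0 Å, a conventional contact
cutoff; configurable) and distances beyond it.

## Conservation

GSC weights are computed on a UPGMA guide tree over fractional-identity
distances (identity over columns where neither row is gapped; rows with
no comparable columns are maximally distant).  Cluster-merge ties are
broken by the lowest contained row index, making the tree — and hence
the weights — deterministic.  Each branch length is distributed among
the leaves below it proportionally to their accumulated weights (evenly
while all are zero), and the result is rescaled to mean one, matching
the convention of the reference `esl-weight` implementation, against
which the test suite cross-checks when the tool is installed.

Column IC uses weighted frequencies over the 20 standard amino acids;
gaps and ambiguous symbols (X, B, Z, …) are excluded and the remaining
weight mass renormalized, keeping the published 0…log₂20 range without
a background-frequency correction.  All-gap columns are undefined
(NaN).  Per-column gap fractions are reported alongside the IC so that
spuriously conserved terminal residues — positions left unmatched in
most alignment rows — can be flagged by the user.

The profile maps onto a structure chain through the alignment's query
row: the k-th non-gap query position carries its column's IC to the
k-th chain residue, with `X` acting as a wildcard on either side and a
hard error (first mismatch named) otherwise.  The optional phmmer
adapter builds query-anchored alignments from a local sequence database
by keeping match-state columns of the hit alignment; no database is
bundled and no tests depend on the adapter beyond its error contract.

## Synthetic data

The fixture generators produce: single-atom residue pairs at exact
separations (the ±1 e pair at r = 3.320636 Å makes the vacuum Coulomb
term exactly +100 kcal/mol; the ρ = 1.5 Å / S = 0.8 pair at 3.0 Å is
the Born-radius fixture), an all-atom alanine dipeptide with idealized
bond geometry, poly-alanine "helices" of configurable length (rigid
copies at 3.4 Å rise and 100° twist), and alignments with columns of
designed IC (conserved, all-20-uniform, random).  Geometries are
checked clash-free (cross-residue clearance ≥ 1.0 Å) and all output is
byte-deterministic in (spec, seed).

What these fixtures do *not* emulate: real side-chain rotamer
diversity, realistic charge distributions, solvent-exposure contrast
between core and surface, or homologous sequence families with
phylogenetic structure.  Passing tests therefore demonstrate the
correctness of the formulas, invariants and plumbing — not the
biological accuracy of the shipped illustrative parameter table.

## Numerical choices and sizes

Energies are assembled from vectorized O(N²) atom-pair matrices
(float64); no distance cutoff is applied by default (an optional cutoff
flag exists).  Test problem sizes are desk-scale — up to 17 residues
(~170 atoms) for matrix invariants and 10⁷ Monte-Carlo samples for the
descreening oracle — chosen so the whole suite completes in seconds
while still separating correct from incorrect piecewise regimes.
Rigid-motion invariance is asserted to 1e-8 relative, reflecting
float64 accumulation over squared distances.

## Known limitations

* The shipped parameter table is illustrative; no claim is made that
  its absolute energies match any published force field.
* No nonpolar/SASA solvation term; GB covers polar screening only.
* No mmCIF input, no structure fetching, no hydrogen addition, no
  missing-atom modelling or geometry optimization.
* The conservation pipeline does not reconstruct phylogenies or model
  substitution processes; GSC weighting is its only defence against
  uneven sampling of sequence space.
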