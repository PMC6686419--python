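# Methods

## The torsion model

The torsional energy of an atom quadruple *i-j-k-l* is a three-term cosine
series

    ET(φ) = ½ [ V₁(1 + cos φ) + V₂(1 − cos 2φ) + V₃(1 + cos 3φ) ]

with the dihedral φ in degrees and barrier heights V₁ (onefold), V₂
(twofold), V₃ (threefold) in kcal/mol. Useful analytic anchors, used
throughout the tests: `ET(180) = 0` for any triple, `ET(0) = V₁ + V₃`, and
`ET(90) = V₂` whenever V₁ = V₃ = 0. A positive V₂ therefore penalizes the
perpendicular conformation and enforces planarity; a negative V₁ stabilizes
the cis (φ = 0) over the trans (φ = 180) orientation, which is how the
S···O chalcogen contact of 2-amidothiophenes is mimicked within a
fixed-charge force field. The internal energy unit is kcal/mol (the MMFF
convention); kJ/mol is supported as a presentation unit with the exact
factor 4.184.

Parameter records are keyed by a torsion-type index `tt` plus the four
MMFF94 numeric atom types, stored in a canonical orientation (j < k, or
j = k and i ≤ l; the reversed quadruple denotes the same record). `tt` is
treated as an opaque integer supplied by the caller; perceiving it from
bond orders is the energy engine's job, not the table's. Lookup of a
concrete quadruple proceeds in stages after canonical orientation: exact
`tt-i-j-k-l`, then the single-end wildcards `tt-0-j-k-l` and `tt-i-j-k-0`,
then the double wildcard `tt-0-j-k-0`; the first hit wins. This order is
standard MMFF practice and makes resolution deterministic.

Two tables ship as plain-text `TT I J K L V1 V2 V3` files: the original
aryl-amide wildcard record, and the refit set covering N-aryl amides
(including the 5-ring heteroaromatic quadruples built from atom types
3, 10, 28, 37, 44, 63, 64, 65, 66) and phenylpyrroles (tt = 1). Only the
original record whose coefficients are actually documented is shipped in
the original table.

## TorsionID

A TorsionID is a canonical string naming a rotatable bond together with its
immediate environment, so that statistics ("how often does minimization get
this kind of torsion wrong?") can be accumulated over chemically equivalent
bonds across a dataset.

Assignability: a bond receives an ID iff it is a single bond, not aromatic,
not a member of a ring with ≤ 5 atoms, and a dihedral can be defined across
it (both ends have at least two neighbours, hydrogens included). The ring
cutoff deliberately admits bonds in 6- and 7-membered saturated rings even
though such torsions are coupled to the ring conformation; the rule is kept
as stated rather than silently tightened.

Perception is implemented from scratch on a light molecular graph
(explicit hydrogens, Kekulé bond orders; ring membership and Kekulé
structures are taken from RDKit when a molecule is read from SDF/SMILES):

* **Aromaticity** — per-ring Hückel counting restricted to rings of size
  ≤ 7 inside isolated (fused) ring systems. Electron contributions: ring
  atom with an endocyclic double bond 1; with only an exocyclic double bond
  (carbonyl-like) 0; N/O/S lone-pair donors 2; saturated centres break the
  count. 4n+2 flags the ring's atoms and bonds aromatic.
* **Delocalization** — bonds of 6-membered aromatic rings are flagged
  delocalized (their Kekulé orders are artefacts of an arbitrary mesomer);
  5-membered heteroaromatic rings are *not* flagged, their Kekulé structure
  being unique given the heteroatom.
* **sp2 nitrogens** — aromatic N, amide N (N–C(=O)), enamine N (N–C=C), or
  N in resonance with an aromatic ring. The resonance condition is
  suppressed when both ortho positions of the aryl neighbour carry
  non-hydrogen substituents — a topological proxy for steric twisting out
  of plane, chosen because no geometric test is available on a graph.

The fragment of a bond contains the two central atoms and every atom
directly bonded to them; if the bond sits on a consecutive chain of sp
(linear) atoms, the whole chain plus both chain-end atoms and their
substituent shells is included. The string grammar renders the chain
linearly — `ATOM(branches) bond ATOM(branches)` with the central bond
token parenthesized — where an atom descriptor is
`El[flags,n<neighbour count>]` (flags: `a` aromatic, `N2` sp2 nitrogen,
charges as `+n`/`-n`) and bond tokens are `-`, `=`, `#` and `:`
(delocalized), with `=E`/`=Z` when a double bond inside the fragment
carries stereo. Canonicalization sorts each branch list lexicographically
and takes the lexicographically smaller of the two chain directions;
`decode` parses the grammar back into a fragment and reports the position
of the first violation. The rendered glyphs are this package's own; string
equality with other implementations of the same idea is not claimed.

## End symmetry and deviation folding

Each end of a rotatable bond gets a topological symmetry label decided by
canonical rooted branch codes (Weisfeiler–Lehman label refinement on the
graph with the end atom removed; delocalized bonds get a dedicated edge
label so Kekulé artefacts cannot break ring symmetry): D3 for three
pairwise-equivalent branches, D2 for a planar-type end (aromatic, sp2-N or
double-bonded) with two equivalent branches, D1 when the pattern admits a
mirror (two-of-three equivalent branches, a non-planar equivalent pair, or
a single branch), else C1. D3 collapses to D1 for pair classification,
giving six unordered pair classes with fold periods 360° (C1C1, C1D1),
180° (C1D2, D1D1) and 90° (D1D2, D2D2).

Two deviation quantities are exposed. The *literal folded value* applies
the piecewise mapping per pair class (φ+360 for negative φ in C1C1/C1D1;
φ+180 in C1D2; |φ| in D1D1; φ+180 / 180−φ in D1D2/D2D2, with the
undocumented 0–90° branch taken as identity). The *effective deviation* is
the distance from the reference angle to the nearest symmetry image of the
predicted angle — images are s·φ + k·P with the pair's period P and the
mirror s = −1 admitted only for pairs containing a D1 end — and always
lies in [0, P/2]. Threshold tests (default 30°) use the effective
deviation: the literal mapping sends a −10° deviation in C1C1 to 350°,
which would absurdly count a near-perfect prediction as wrong. Both values
are reported in diagnostics.

## Conformer pipeline

Up to 1000 conformers per molecule are generated by assigning every
acyclic assignable bond a dihedral from the 30° grid (12 values); the full
grid is enumerated when 12ⁿ ≤ 1000, otherwise distinct assignment vectors
are sampled without replacement from a seeded generator. Driving a
dihedral rotates the smaller branch rigidly about the bond axis (tie →
lower atom index); ring internal coordinates are never altered.

Minimization is delegated to a pluggable engine receiving the protocol
constants (300 conjugate-gradient steps, then 5000 L-BFGS steps, dielectric
constant 4); per-conformer failures downgrade the conformer to a failed
status and are counted, never raised collectively. Two torsion-only
engines are provided: a Cartesian one (scipy CG + L-BFGS-B on coordinates,
convergence at gradient norms near 1e−6) and a rigid-rotor one that
minimizes over the rotatable dihedrals only, rotating branches rigidly —
the natural minimizer for a potential with no bond or angle terms, and the
engine used by the synthetic benchmark. Both guarantee the contract that
minimization never increases the energy. The dielectric constant is
accepted and ignored by both (no electrostatics).

Conformers within 10.0 kcal/mol of the ensemble minimum form the
low-energy pool. The per-molecule score is the lowest heavy-atom RMSD of
any pool member to the reference conformer after optimal rigid
superposition, minimized over graph automorphisms (RDKit's best-RMS
Kabsch machinery; the symmetry-aware choice matters for para-substituted
phenyls and is cross-checked in the tests against a brute-force
superposition oracle). Recovery tables report the cumulative fraction of
successfully processed molecules under RMSD thresholds (default 0.5, 1.0,
1.5, 2.0 Å) plus the failure rate. Torsion diagnostics compare, bond by
bond, the reference conformation against the closest low-energy conformer
with the 30° effective-deviation test and aggregate flag counts per
TorsionID, ranked descending — the discovery loop that surfaces
systematically mis-modelled torsion environments.

## Parameter fitting

The merit function is the RMSD between the force-field profile and the
reference profile on an identical angle grid, both shifted so their grid
minimum is zero (profiles are relative energies; kJ/mol references are
converted on load). By default the force-field profile is the rigid
torsion-only sum of the cosine series over the quadruples present on the
scanned bond, each with an optional constant phase offset; a relaxed-scan
profile through any energy engine can be substituted.

*Systematic mode* exhaustively scans the free components of exactly one
quadruple on a regular grid (step 0.1 kcal/mol, bounds ±15 kcal/mol —
covering every shipped magnitude, max |V| = 11.5, with margin); merit ties
break toward smaller summed |V|, then lexicographically. *GA mode* jointly
optimizes all free components across several references with the summed
per-reference RMSD as fitness; quadruples shared between references share
genes, so redundancy constrains the fit. The GA is elitist (2 elites),
with tournament selection (k = 3), uniform crossover (rate 0.7),
per-gene Gaussian mutation (σ = 0.25 kcal/mol, rate 0.3), population 60
and 300 generations by default, and requires an explicit seed; fixed seed
gives a bit-identical result. These hyperparameters are this package's own
defaults — chosen so that a two-reference shared-quadruple fit recovers
generating (V₁, V₂) within 0.05 kcal/mol in a few seconds — and are all
configurable. The choice of free components follows the established
policy: fit V₂ alone for most quadruples, and free V₁ (the
`cis_trans_gap` helper computes E(0) − E(180)) when the cis/trans energy
difference cannot otherwise be reproduced; V₃ is rarely needed for
conjugated rotors.

## Synthetic data and what the tests show

The fixture registry holds ten small molecules — N-phenylacetamide and its
pyridyl, thiophenyl, ortho-methyl, ortho-fluoro and N-methyl variants,
1-phenylpyrrole, 1-phenylpyrazole, toluene and biphenyl — chosen to
exercise every perception rule (6- vs 5-ring aromaticity, amide and
resonance sp2 nitrogens, the ortho-blocking rule, D3/D2/C1 end
symmetries) and every quadruple family of the shipped tables. Coordinates
were generated once with RDKit's ETKDG distance-geometry embedder (fixed
seed) and frozen into the shipped SDF so tests are bit-stable.

Synthetic reference profiles are exact cosine-series sums (computed by an
independent summation, asserted equal to the profile code at 1e−12) with
optional seeded Gaussian noise. They emulate the *shape* of ab initio
torsion scans but none of their physics: no coupling to bond/angle
relaxation, no non-bonded 1–4 interactions, no basis-set artefacts.
Parameter-recovery tests on such profiles therefore validate the fitting
machinery (search, fitness, determinism), not the transferability of any
fitted parameter to real molecules. Likewise the end-to-end benchmark
property — recovery at 0.5 Å reaching 1 when the engine that scores
conformers is the engine that generated the references — validates the
pipeline plumbing (enumeration coverage, minimization, windowing, RMSD),
not force-field accuracy against experimental bioactive conformations,
which requires external crystal-structure datasets and a full force field
and is out of scope here. Benchmark problem sizes in the test suite are
kept small (one- to three-rotor molecules, ≤ 1000 conformers, rigid-rotor
engines) as the package's own desk-scale defaults.

## Numerical choices and limitations

* Angles are handled in degrees at the API surface; wrapping is to
  (−180, 180].
* The enumeration cap samples assignment vectors, not 3D coordinates;
  distinctness is decided on the vectors.
* The energy-window filter uses ≤ (a conformer exactly at the window edge
  is kept) and is invariant to constant energy offsets.
* Branch equivalence via WL refinement is a hash-based proxy for rooted
  subgraph isomorphism; collisions are theoretically possible but not
  observed on molecular graphs of this size.
* The D1 (mirror) assignment is topological; ends whose mirror symmetry is
  broken only geometrically (e.g. frozen exocyclic conformations) are
  still labelled D1.
* The mini atom-typer covers only the numeric types used by the shipped
  tables; full MMFF94 atom typing, non-torsion force-field terms and
  quantum-chemistry drivers are deliberately out of scope.
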