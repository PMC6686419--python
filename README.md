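# torsionforge

Torsion-parameter machinery for MMFF94s-style force fields: a toolkit for
cheminformaticians and force-field developers who need to evaluate, diagnose
and refit the torsional term of a small-molecule force field.

Force-field minimization is the workhorse of conformer generation in
computer-aided drug design, and the quality of the generated geometries is
often limited by a handful of badly parameterized torsion potentials —
N-aryl amides and N-phenylpyrroles being notorious offenders, where overly
large twofold barriers force biaryl and aryl-amide systems flat.
`torsionforge` packages the machinery needed to find and fix such problems:

* **`param_model`** — the torsional energy of an atom quadruple *i-j-k-l*,

  ```
  ET(φ) = ½ [ V₁(1 + cos φ) + V₂(1 − cos 2φ) + V₃(1 + cos 3φ) ]
  ```

  with barrier heights V₁/V₂/V₃ in kcal/mol, plus parameter tables keyed by
  MMFF94 numeric atom types with staged wildcard fallback (exact →
  single-end wildcard → double wildcard, atom type 0 matching anything).
  Two tables ship with the package: the original aryl-amide wildcard record
  (V₂ = 6.0) and the refit set for N-aryl amides and phenylpyrroles
  (e.g. the new wildcard V₂ = 2.7).
* **`torsion_id`** — canonical **TorsionID** strings identifying a rotatable
  bond by its local chemical environment (element, aromaticity, neighbour
  count, sp2-nitrogen flags, bond orders, delocalization), with its own
  Hückel aromaticity, delocalization and sp2-nitrogen perception.
* **`symmetry`** — topological symmetry labels (C1/D1/D2/D3) for the two
  ends of a rotatable bond and symmetry-corrected dihedral deviations
  (fold periods 360°/180°/90° per pair class).
* **`conformer_pipeline`** — random-dihedral conformer enumeration on a 30°
  grid (up to 1000 per molecule), pluggable minimization engines, the
  10 kcal/mol low-energy window, automorphism-aware heavy-atom best-RMSD,
  recovery tables and per-TorsionID error aggregation.
* **`param_fit`** — refitting (V₁, V₂, V₃) against reference
  potential-energy profiles by exhaustive grid search (step 0.1) or by an
  elitist genetic algorithm with summed-RMSD fitness.
* **`fixtures_io`** — SDF/SMILES/CSV I/O, a registry of ten small fixture
  molecules with frozen 3D coordinates, and a synthetic PES generator.

## Worked example

```python
from torsionforge import lookup, new_table, original_table, torsion_energy

# rotation about the aryl-N bond of an N-phenyl amide:
# quadruple C(arom)-C(arom)-N(amide)-C(carbonyl) = 37-37-10-3
old = lookup(original_table(), 0, 3, 10, 37, 37)   # wildcard 0-10-37-0
new = lookup(new_table(), 0, 3, 10, 37, 37)
print(old.triple, torsion_energy(*old.triple, 90.0))
print(new.triple, torsion_energy(*new.triple, 90.0))
```

prints

```
(0.0, 6.0, 0.0) 6.0
(0.0, 2.7, 0.0) 2.7
```

i.e. the original parameters put a 6.0 kcal/mol barrier at the
perpendicular aryl-amide conformation, and the refit lowers it to
2.7 kcal/mol — the difference that lets ortho-substituted aryl amides twist
out of plane instead of being forced flat.

TorsionIDs from the command line:

```sh
$ torsionforge torsion-id --smiles "CC(=O)Nc1ccccc1"
C[n3](-N[N2,n3],=O[n1])(-)C[n4](-H[n1],-H[n1],-H[n1])
C[n3](-C[n4],=O[n1])(-)N[N2,n3](-C[a,n3],-H[n1])
C[a,n3](:C[a,n3],:C[a,n3])(-)N[N2,n3](-C[n3],-H[n1])
```

one line per assignable bond of N-phenylacetamide (acetyl C–C, amide C–N,
aryl–N); `[N2,…]` marks the planar amide nitrogen, `:` a delocalized bond,
`(-)` the central rotatable bond.

Refit a twofold barrier from a reference scan:

```sh
torsionforge scan --triple 0,2.6,0 --grid 0:180:15 > ref.csv
torsionforge fit --mode systematic --ref ref.csv --free V2
```

recovers `V2 = 2.6` with zero merit (RMSD between force-field and reference
profile).

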