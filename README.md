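# motif3d

Define, generate and search for **3D structural motifs** in protein
structures.

A structural motif here is a small — typically 3 to 6 residue — arrangement
of amino acids that recurs across proteins (a catalytic triad, a
calcium-binding loop, a buried packing cluster), usually **discontinuous in
sequence**. Instead of scoring candidate sites by a similarity cutoff,
`motif3d` specifies a motif as a *constraint set* and returns exactly the
residue combinations that satisfy it:

* **residue type** — each motif position allows a disjunction of amino-acid
  types (`DN` = Asp or Asn);
* **secondary structure** — each position may be restricted to helix (`h`),
  strand (`s`), coil (`c`), or any combination (`*` = unrestricted);
* **inter-atomic distances** — for selected atom pairs, the observed
  distance `d` must satisfy `d_min ≤ d ≤ d_max` (Å, inclusive bounds);
* **sequence separation** — bounds on the (signed) difference in chain
  position between two motif residues.

Searching a structure of *m* residues for a *k*-residue motif naively means
examining all `C(m, k)` residue subsets (and their `k!` orderings) — for
example `C(250, 4) = 158 882 750`. The search engine prunes this space by
prefiltering each motif position's candidates on type and secondary
structure, expanding the most constrained position first, and rejecting a
partial assignment at the first violated constraint; an exhaustive
enumeration oracle in the test suite verifies that pruning never changes
the result.

Matched sites are scored by **backbone rmsd** after optimal rigid
superposition (SVD-based least-squares fit restricted to proper rotations,
so mirror images never superpose):

```
rmsd(A, B) = sqrt( (1/n) * sum_i || a_i - b_i ||^2 )
```

Motif specifications are plain text and can be edited freely — e.g. relax a
strict Asp position to `DN`, widen one distance bound, or delete a
separation constraint:

```
GROUP 1 H *
GROUP 2 D *
GROUP 3 S *
DIST 1 CA 2 CA 5.999 6.999 7.999     # d_min, d_measured, d_max (Å)
DELTA 1 2 7 7                        # signed ordinal separation bounds
```

Because specifications are always generated from measured geometry, the
source structure is guaranteed to match its own motif.

## Worked example

No input data is needed: the `fixtures` subcommand generates synthetic
PDB-format structures with a planted His/Asp/Ser arrangement (recorded in
`ground_truth.json`).

```sh
cat > recipe.json <<'EOF'
{"structures": [
  {"structure_id": "demo1", "n_residues": 60, "seed": 3,
   "planted": [{"template": "triad", "copies": 1}]},
  {"structure_id": "demo2", "n_residues": 80, "seed": 4}
]}
EOF
motif3d fixtures --recipe recipe.json --out-dir fx
motif3d build --pdb fx/demo1.pdb --residues A43,A50,A58 \
        --tol 1.0A --ss wildcard --delta strict -o triad_motif.txt
cat triad_motif.txt
```

```
# motif generated from demo1: A43 A50 A58
GROUP 1 H *
GROUP 2 D *
GROUP 3 S *
DIST 1 CA 2 CA 5.999 6.999 7.999
DIST 1 CA 3 CA 5.500 6.500 7.500
DIST 2 CA 3 CA 8.552 9.552 10.552
DELTA 1 2 7 7
DELTA 2 3 8 8
```

One GROUP line per selected residue (His43, Asp50, Ser58), one DIST line
per Cα–Cα pair with bounds at the measured distance ± 1.0 Å, and chained
DELTA lines pinning the observed sequence separations (7 and 8 residues).
Searching both structures:

```sh
motif3d search --motif triad_motif.txt --pdb-dir fx
```

```
# motif3d 0.1.0
# config d53493c0ae48: {"abs_delta": false, "dedupe_sets": false, "motif": "triad_motif.txt", "structures": 2}
structure_id	group_1	group_2	group_3	dist_0	dist_1	dist_2
demo1	A:43	A:50	A:58	6.999	6.500	9.552
# structures_searched=2 structures_with_hits=1 matches=1
```

Exactly one hit — the planted site in `demo1`, with each measured distance
inside its bounds; `demo2` contains no satisfying combination. Superposing
a hit onto the query site reports the backbone rmsd (0 here, same site):

```sh
motif3d superpose --pdb-a fx/demo1.pdb --sel-a A:43,A:50,A:58 \
                  --pdb-b fx/demo1.pdb --sel-b A:43,A:50,A:58
# backbone_rmsd_A	0.000
```

The same operations are available as a library
(`motif3d.build_motif`, `motif3d.find_matches`, `motif3d.backbone_rmsd`,
…); see `docs/methods.md` for the model and its assumptions.

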