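# Methods

## The matching model

A motif of *k* residues is a constraint set over an assignment of structure
residues to numbered groups. An assignment is a match iff

1. it is injective (no residue fills two groups);
2. each residue's one-letter type is in its group's allowed set, and its
   secondary-structure label is in the group's allowed subset of {h, s, c};
3. every distance constraint holds **inclusively**:
   `d_min ≤ ‖x_a − x_b‖ ≤ d_max` for the named atoms of the assigned
   residues. A residue lacking a named atom (truncated side chain,
   partially modelled loop) fails the constraint — it does not raise, so
   one incomplete structure cannot abort a batch search;
4. every sequence-separation constraint holds on the **signed ordinal
   separation**: `ordinal(res_b) − ordinal(res_a)`, where the ordinal is a
   residue's 0-based position within its chain after parsing. Ordinals —
   not author-assigned residue numbers — make separations robust to
   numbering gaps and insertion codes. Two groups assigned to different
   chains fail any finite separation constraint. `abs_delta=True` switches
   to unsigned semantics; the signed default preserves the N→C
   directionality of the source motif.

Matching is exact constraint satisfaction rather than a similarity score:
thresholded rmsd or summed distance-matrix differences compress a site
into one number whose meaning shifts with motif size and composition,
whereas per-distance bounds can be individually tightened or relaxed in a
text editor. Both scores remain available (`geometry.rmsd`,
`geometry.dm_similarity`) for ranking hits after the search.

### Specification format and limits

Text lines keyed `GROUP` / `DIST` / `DELTA`; any other line is preserved as
provenance. Limits: 32 groups, 150 distance constraints, 31 per group
pair. The writer renders distances with three decimals, and the builder
measures on the same milli-Å grid, so write → parse round-trips are exact.
Parsing is whitespace-delimited and keyword-case-insensitive; residue-type
letters outside the 20 standard codes plus X are rejected rather than
ignored. Negative separation minima are legal (a slack of ±25 around a
separation of 11 gives [−14, 36]).

## Search algorithm

Per-group candidate lists are prefiltered by type and secondary structure.
Groups are expanded most-constrained-first (fewest candidates, then most
incident constraints, label as tie-break), and each partial assignment is
checked against every constraint whose endpoints are both assigned,
rejecting at the first violation. With `prune=False` constraints are
evaluated only on complete assignments; the test suite asserts the match
set is identical either way (pruning soundness), and a brute-force oracle
(`fixtures.brute_force_search`) that enumerates all injective assignments
and applies the public predicate is compared against the engine on
randomized cases. Matches are emitted in a deterministic order (sorted by
assigned residue keys in group-label order). Permuted assignments of one
residue set — possible when groups share constraints — are distinct
matches by default; `dedupe_sets=True` collapses them.

No spatial index is used: at the intended scale (motifs ≤ 6 groups, a few
dozen constraints, structures of 10²–10³ residues) candidate prefiltering
plus first-violation rejection leaves the distance checks far from the
bottleneck, and a 5-group/10-constraint search of a 500-residue chain
runs in milliseconds.

## Structure reading and normalisation

PDB coordinate files are parsed with gemmi; the package then applies its
normalisation: first model only, alternate locations resolved to the
highest-occupancy conformer (ties to the first in file), HETATM dropped
except selenomethionine (typed `M`), waters and hydrogens excluded.
Residue identity is (chain, author number, insertion code); ordinals are
assigned per chain after filtering. A pre-scan validates the fixed-column
coordinate fields and reports the offending line number, since gemmi
itself is permissive about malformed numbers.

### Secondary structure

Assignment is by backbone torsion windows, chosen for determinism and
independence from any external program: a residue is a helix candidate
when φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°], a strand candidate when
φ ∈ [−180°, −40°] and ψ ∈ [90°, 180°] ∪ [−180°, −170°]; candidates become
`h`/`s` only in runs of ≥ 4 / ≥ 3 consecutive residues, everything else —
including residues whose φ or ψ cannot be computed (chain termini, chain
breaks detected by a C–N distance > 2.0 Å, missing backbone atoms) — is
coil. The windows and run lengths are module-level constants so a
DSSP-style backend could be substituted. Any torsion-window scheme
disagrees with hydrogen-bond-based assignors near helix caps and strand
edges; motifs intended to transfer across structures should use `*`
(wildcard) secondary-structure constraints, which is also the generator's
recommendation for specs meant for searching rather than documentation.

## Motif generation

`build_motif` emits one group per selected residue (observed type; observed
secondary structure or wildcard), distance constraints per the pair
selection — default all Cα–Cα pairs, `C(k,2)` of them, which keeps even a
17-residue selection under the 150-constraint cap — with bounds at the
measured distance ± x Å or ± x %, floored at 0, and chained separation
constraints between consecutive selected residues (`strict` pins the
observed signed separation; `slack` widens it by ± k, default 25; `none`
omits them). Cross-chain selections require `delta_policy="none"` since
separation is undefined across chains. Because all values are measured
from the source structure, the source selection satisfies its own spec —
the self-recovery guarantee the tests enforce for tolerances down to the
milli-Å rounding grid (in practice, any tolerance ≥ 0.01 Å).

`widen_spec` relaxes every distance bound by an extra tolerance without
touching groups or separations; the match set can only grow (monotonicity
is tested).

## Superposition and scoring

`superpose` solves the orthogonal Procrustes problem with the SVD,
sign-correcting the determinant so only proper rotations are returned;
mirror-image configurations therefore retain a positive residual.
`backbone_rmsd` pairs residues in the given order, collects {N, CA, C, O}
per pair (configurable; pairs missing an atom on either side are dropped
and counted), fits, and reports the residual rmsd. `rmsd` itself never
fits — callers superpose first. `dm_similarity` is the sum of absolute
entry-wise differences of two all-internal-distance matrices; the
absolute-value form is used because a signed sum cancels to nothing.

## Synthetic test structures

`fixtures.make_chain` builds single-chain polypeptides from ideal peptide
internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, τ(N-CA-C)
111.2°, ω = 180°) with per-residue φ/ψ drawn from helix (−57°, −47°),
strand (−120°, +120°) or coil segments of random length 4–12, residue
types sampled from a configurable alphabet, side chains through Cβ only.
Generated chains are right-handed; torsions measured from the coordinates
agree with the requested values (cross-checked against an independent
structure library in development).

Motif copies are *planted* by overwriting the types and coordinates of
slotted chain positions with a rigidly transformed copy of a template
(types, atom sets, and ordinal gaps captured from a donor structure), each
copy displaced to its own region of space, with optional isotropic
Gaussian coordinate noise of stated σ. Every planted copy is recorded as
ground truth. Copies reuse the template's ordinal gaps, so separation
constraints derived from one copy hold for all.

What this emulates: the combinatorial search problem — type/ss/distance/
separation filtering over realistic residue alphabets and chain lengths —
with analytically known ground truth. What it does not: real side-chain
rotamers, crystallographic disorder, alternate conformations in the wild,
or homology structure between decoys and motif. Passing tests therefore
demonstrate the correctness of parsing, generation, search and scoring
machinery, not biological recall/precision on curated PDB subsets, which
depends on the user's structure collection and tolerances.

Sizes used in tests and in `scripts/acceptance.py` keep the exhaustive
oracle within its 10⁷-assignment guard: 3-group motifs in chains up to ~45
residues, 4-group up to ~22, 5-group up to ~15, with 60–100 randomized
cases per run; the timing check uses a 500-residue chain, desk scale for
the pruned engine.

## Numerical choices and degenerate inputs

* Distance bounds and comparisons are inclusive at both ends.
* All distances are stored on a 0.001-Å grid (format fidelity); search
  comparisons use full double precision on measured coordinates.
* Superposition requires ≥ 3 point pairs; backbone rmsd requires ≥ 3
  usable atom pairs after dropping incomplete ones.
* `count_candidate_subsets(m, k)` is the exact binomial coefficient, 0 for
  k > m.
* Empty structures, empty match sets and empty input collections are
  normal values, not errors; unreadable files in a batch are logged,
  skipped, and still counted as searched.

## Known limitations

* Secondary-structure labels are torsion-window approximations (above).
* No nucleic acids, ligand geometry or symmetry-mate expansion.
* No automatic selection of structurally important residues; the residue
  list is the caller's.
* The brute-force oracle is intentionally naive and unusable beyond its
  guard; it exists to certify the engine, not to search with.
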