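# Methods

## Model and procedure

`orthoswap` treats variant design as a constrained nearest-neighbor search
over extant sequences. The premise: a substitution observed at the
homologous position of a close ortholog is far more likely to be tolerated
than one chosen a priori, because it has been selected for function in a
similar sequence background. The assumption breaks down when the target
residue is catalytic or part of an obligate motif — a position that is 100%
conserved across the database has, by construction, no extant alternative,
and the tool reports such clusters as unresolved rather than guessing.

The pipeline has three stages:

1. **Ranking.** Every database sequence is aligned to the query by optimal
   local alignment (Smith-Waterman with affine gaps, Gotoh recurrences) and
   the database is sorted by percent identity, descending, with ties kept in
   database input order (a stable sort, so output is reproducible for a
   given input file). Sequences whose optimal local score is 0 get an empty
   alignment and identity 0, and sort last.
2. **Cluster-coincident donor search.** For each cluster of coupled
   positions the ranked list is scanned top-down; a homolog qualifies iff
   the alignment maps *every* cluster position to a canonical residue
   different from the forbidden type. Gaps, positions outside the aligned
   span and ambiguity letters (X/B/Z/U) disqualify — none of them can be
   written as a point mutation. Clusters are searched independently, so one
   variant may combine donors of very different identity.
3. **Variant construction.** The winning donors' residues are applied as
   point substitutions; unresolved clusters leave their positions unchanged
   and flag the design incomplete (CLI exit status 3) instead of aborting,
   since a partial design is still actionable.

Requiring coincident replacement is the scientifically load-bearing rule:
for residues in steric contact, a lone substitution in an otherwise
cysteine-bearing ortholog likely depends on the remaining contacts, whereas
a donor that replaced the whole cluster demonstrates a self-consistent set.
The test suite constructs exactly this situation (a 90%-identical homolog
replacing one of three coupled positions vs an 85.8%-identical homolog
replacing all three) and asserts the coupled search falls through to the
more distant donor.

## Alignment conventions and parameters

- **Matrix / gaps:** BLOSUM62 with gap open 10.0 and gap extend 0.5 — the
  defaults of EMBOSS Water, the de-facto standard for this kind of pairwise
  scan. A gap of length L costs `open + (L-1)·extend`. Both penalties and
  the matrix (NCBI/EMBOSS text format) are configurable and recorded in the
  run manifest, because identity percentages are only comparable across runs
  made with the same scoring model.
- **Identity/similarity:** computed over all alignment columns *including*
  gap columns (Water's report convention); similarity counts columns whose
  pair scores strictly positively. Under BLOSUM62 every identity scores
  positively, so identity ≤ similarity holds and is asserted; for an
  arbitrary user matrix with non-positive diagonal this would not be
  guaranteed, which is why such matrices are rejected on load.
- **Ambiguity letters** are accepted in input sequences; pairs missing from
  the matrix (e.g. anything involving U) score 0, so they neither help nor
  hurt, and they are never proposed as replacements.
- **Engine:** the dynamic programming is delegated to Biopython's
  `PairwiseAligner` (C implementation). Correctness is established against
  an exhaustive enumeration oracle written independently in the test suite:
  every start pair, every interleaving of match/gap moves, every stopping
  point, memoized; the oracle itself is validated against a literal
  move-string enumeration on tiny inputs. 500 random peptide pairs per run
  are checked for exact score equality.
- **Ties:** among co-optimal alignments the engine's first traceback is
  taken; the enumeration order is deterministic, so identical inputs give
  byte-identical outputs (asserted in tests). Scores are kept as floats
  throughout (gap extend 0.5); nothing is rounded before presentation.
- **Coordinates** are 1-based inclusive at every interface, matching
  C140M-style mutation naming.

## Contact clustering

Two residues are in steric contact when the minimum over all heavy-atom
pairs of Euclidean distance is below the cutoff; clusters are connected
components (single linkage), so contact chains merge transitively. Defaults:

- **cutoff 4.5 Å** — a conventional heavy-atom contact threshold lying
  between van der Waals touching (~3.5-4 Å) and the onset of
  water-mediated separation; "steric contact" has no single published
  number, so the cutoff is a flagged parameter echoed in logs, not a claim.
- **all heavy atoms count** (backbone and side chain), the simplest
  defensible reading of steric contact; hydrogens are excluded because
  crystallographic models usually lack them.
- **single chain only**; inter-subunit contacts in an assembly are out of
  scope.

Alternate conformations are reduced to one atom per name (highest occupancy,
ties toward altloc A); missing requested residues are reported, never
fabricated. Clustering is invariant to input order and rigid-body motion,
and increasing the cutoff can only merge clusters — all property-tested.

## The synthetic-ortholog generator

The generator exists so the whole pipeline can be exercised, with known
ground truth, without any sequence download. A homolog at target identity t
of an L-residue query changes exactly `round((1-t)·L)` positions; planted
residues (the mechanism for constructing known donors) count toward that
budget when they differ from the query. Mutated positions draw their new
residue from the 19 alternatives weighted by `exp(BLOSUM62 score)`, so
substitutions are conservative and similarity exceeds identity, as in real
ortholog families. Optional short indels (length 1-3, default rate 0) never
touch planted positions, and a ground-truth manifest records where each
planted residue ended up. A single integer seed makes every output
reproducible, and each FASTA header embeds it.

What the generator does *not* emulate: phylogenetic correlation between
homologs (each is drawn independently from the query), site-rate
heterogeneity, domain-level conservation structure, and long indels.
Passing tests therefore demonstrate the engine's contracts — ranking,
mapping, qualification, recovery of the constructed donor — not performance
on any particular real protein family.

### Standard study family

`example_cysteine_family(seed)` is the package's reference scenario, built
to the shape of the archaeal group II chaperonin problem that motivated this
approach: a 543-residue query with cysteines at exactly
140/237/286/359/393/470/484; clusters 140+470+484 (equatorial), 237+286
(apical), 359 and 393 singletons; and a 12-homolog database in which

- the intended donors sit at 85.8% (equatorial: M/Y/T), 66.3% (apical:
  E/V), 59.2% (359: V) — the donor identities of the original design — and
  88% for 393 (S), a "closely related" level chosen once for this package;
- closer decoys (95, 92, 90, 80, 75, 70, 60, 45%) retain cysteine at the
  relevant positions, including a 90% decoy replacing only position 140 of
  the equatorial trio, which makes cluster coupling decisive.

Every target position is explicitly pinned in every homolog, so donor
qualification is known by construction and tests can verify the engine
against a brute-force scan of the whole database.

## Problem sizes and numerical choices

The default test run aligns the 543-residue family (12 homologs), checks
500 + 200 oracle pairs at lengths ≤ 8 over a 4-letter alphabet, 1000 random
identity≤similarity alignments, and ~10 synthetic coordinate sets of ~10
residues; the whole suite completes in a few seconds, and
`scripts/acceptance.py` in about one. Degenerate inputs have defined
behavior rather than errors where a result is meaningful: an all-negative
sequence pair yields an empty alignment (identity and similarity 0), a
cluster with no qualifying donor yields an explicit unresolved marker, and a
position mapped to a gap is distinguished from one outside the aligned span.

## Design choices where the design was open

- **Replacement residue = the top donor's residue.** When several close
  homologs offer different replacements (as at position 393), the engine
  takes the highest-ranked qualifying donor's residue and does not attempt
  chemical reasoning (e.g. preferring isosteric serine). That judgment is
  left to the user via `--override pos=RES`, which is validated (canonical,
  not the forbidden type, a target position) and flagged `user` in the
  report. The `profile` subcommand exists precisely to expose the extant
  options for such a call.
- **Gap tolerance near clusters.** Donors are required to be gap-free *at*
  the cluster positions only; a nearby indel does not disqualify. A stricter
  window would need a defensible width, and none presents itself.
- **Duplicate FASTA ids are a hard error** (ids join reports to inputs);
  silent renaming would corrupt the join.
- **Retrieval is file-based.** The tool consumes a pre-fetched multi-FASTA
  of homologs; no live BLAST call is made or planned here. This keeps runs
  reproducible and the tool usable offline.

## Known limitations

- No stability/energy scoring of candidate replacements; identity rank is
  the only preference order.
- No compensatory-mutation search beyond cluster coincidence.
- Single-chain contact analysis; inter-subunit couplings are invisible.
- The identity between construction target and measured alignment identity
  degrades slightly at low identity (end trimming by local alignment); the
  generator's contract is exact only in query coordinates without indels.
- Positions 100% conserved across the database are unresolvable by design;
  the tool reports them rather than inventing a replacement.
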