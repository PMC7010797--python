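# orthoswap

Evolution-guided design of residue replacements from extant ortholog
sequences.

## The problem

Site-specific protein labeling usually starts by removing every reactive
cysteine except the one to be labeled. Replacing cysteines by serine or
alanine through trial and error often yields poorly expressed or inactive
protein. A more reliable source of replacements is natural variation: if a
closely related ortholog already carries a non-cysteine residue at the
homologous position, that residue has been vetted by evolution in an
otherwise similar sequence context.

`orthoswap` automates this search. Given a query protein, a database of
homolog sequences (e.g. BLAST hits saved as multi-FASTA) and a set of target
positions, it:

1. aligns every homolog to the query with affine-gap Smith-Waterman local
   alignment (BLOSUM62, gap open 10.0, gap extend 0.5 — EMBOSS Water
   defaults) and rank-orders the database by percent identity, where
   identity and similarity are computed over *all* alignment columns
   including gaps (the Water report convention);
2. for each **cluster** of structurally coupled positions (residues in
   steric contact, which plausibly require compensatory changes together),
   scans homologs in rank order for the first one carrying an acceptable
   non-target residue at **every** clustered position simultaneously — a
   position mapped to a gap, outside the aligned span, or to an ambiguity
   letter (X/B/Z/U) disqualifies a donor;
3. applies the winning donors' residues as point substitutions (different
   clusters may draw on different donors) and writes the engineered variant,
   a substitution report and a run manifest.

Clusters can be supplied by hand or derived from a structure: two residues
are in contact when their minimum heavy-atom distance is below a cutoff
(default 4.5 Å), and clusters are the connected components of the contact
graph. The tool is residue-agnostic — it designs cysteine-less variants as
readily as single-tryptophan or single-lysine ones.

Formally, for forbidden residue type f, cluster C of query positions and
homologs h ranked by identity pct(q,h), the chosen donor is

    argmax_{h : ∀p∈C, map_h(p) ∈ A₂₀ \ {f}}  pct(q, h)

where map_h(p) is the homolog residue aligned to query position p, and the
suggested substitutions are f→map_h(p) for p ∈ C.

## Worked example

The package ships a synthetic-ortholog generator whose standard family
emulates the archaeal chaperonin case: a 543-residue query with seven
cysteines, of which 140/470/484 form an equatorial contact cluster and
237/286 an apical pair, plus a 12-homolog database with donors planted at
known identities.

```python
from orthoswap import example_cysteine_family, write_fasta
fam = example_cysteine_family(11)
write_fasta([fam.query], "query.fasta")
write_fasta(fam.database, "db.fasta")
```

```
$ orthoswap design --query query.fasta --db db.fasta --residue C \
      --clusters "140,470,484;237,286;359;393" --out design_out
INFO cluster 140,470,484 resolved: C140M,C470Y,C484T
INFO cluster 237,286 resolved: C237E,C286V
INFO cluster 359 resolved: C359V
INFO cluster 393 resolved: C393S

$ cat design_out/report.tsv
# orthoswap substitution report v1
position  from  to  donor_id   donor_identity_pct  donor_similarity_pct  donor_rank  override  status
140       C     M   ortho_eq   85.8                94.7                  5           no        OK
470       C     Y   ortho_eq   85.8                94.7                  5           no        OK
484       C     T   ortho_eq   85.8                94.7                  5           no        OK
237       C     E   ortho_ap   66.5                86.8                  9           no        OK
286       C     V   ortho_ap   66.5                86.8                  9           no        OK
359       C     V   ortho_359  59.1                82.3                  11          no        OK
393       C     S   ortho_393  88.0                95.6                  4           no        OK
```

Reading the report: each row is one point mutation (e.g. C140M), the donor
ortholog it came from, and that donor's identity/similarity to the query.
The three equatorial cysteines are replaced together from a single
85.8%-identical donor even though a 90%-identical homolog replaces position
140 alone — the closer homolog keeps cysteine at 470 and 484, so the
coupled search rejects it. The variant FASTA records the design in its
header:

```
>query_cpn_variant variant: C140M,C237E,C286V,C359V,C393S,C470Y,C484T
```

Exit status is 0 when every cluster resolves, 3 when some cluster has no
qualifying donor (its positions are left unchanged and marked UNRESOLVED in
the report), and 1/2 for errors. Intermediate stages are exposed as
`orthoswap rank` (the identity ranking) and `orthoswap profile` (residues
observed at chosen positions across the ranked homologs, with a tally —
useful for spotting 100%-conserved positions, for which no replacement can
exist). `orthoswap contacts --structure file.cif --chain A --residue C`
prints clusters in the same syntax `--clusters` accepts, and
`orthoswap gen-fixtures` builds synthetic families from a JSON/YAML plan.
A replacement can be forced manually (e.g. the isosteric choice
`--override 393=S`); it is validated and flagged `user` in the report.

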