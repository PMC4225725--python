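# plantreg

Identify and categorize plant **transcription factor (TF)**,
**transcriptional regulator (TR)** and **chromatin regulator (CR)** genes
from genome-scale protein or nucleotide sequences, by evaluating curated
boolean domain-signature rules against each protein's set of
InterPro / member-database accessions.

Plant genomes encode thousands of regulatory proteins whose families are
defined by their conserved domain architecture rather than by overall
sequence similarity: a BLAST hit cannot tell a B3-domain protein from a RAV
protein that carries *both* a B3 and an AP2 DNA-binding domain. `plantreg`
is aimed at genome-annotation and regulatory-genomics groups who have (or
can produce) InterProScan results for their sequences and want family
calls with explicit, auditable logic.

## The method

Each family *F* has a prediction logic consisting of

- a **must-have pattern** `M_F`: a boolean expression over domain
  accessions, e.g. for the ARF family
  `(IPR010525 | IPR011525) & IPR003340` — either of two Aux/IAA-related
  dimerisation entries *and* the B3 DNA-binding domain; and
- an optional **prohibited pattern** `P_F` in the same language, whose
  satisfaction vetoes the assignment.

For a protein with observed accession set *S* (the union of all InterPro
entries and member-database signatures reported for it):

```
assign F  ⇔  M_F(S) = true  ∧  (P_F absent ∨ P_F(S) = false)
```

Atoms are satisfied by case-insensitive set membership; `&` binds tighter
than `|`. Prohibited patterns split superfamilies that share a core domain:
the K-box accession IPR002487 in the prohibited pattern of MADS type1 keeps
MIKC-type MADS proteins (MADS box *and* K-box) out of the type1 family.

Nucleotide input is translated conceptually in all six reading frames;
stop-free segments of at least 50 aa (configurable) are classified and the
calls re-attributed to the parent sequence with the source frame recorded.
A benchmark module compares a prediction table against a reference
gene→family assignment, reporting **matches** (family sets intersect),
**conflicts** (disjoint), **missed** (reference only) and **newly
predicted** (prediction only) — the four categories partition the gene
universe, so matches + conflicts + missed always equals the reference size.

## Worked example

```python
from plantreg import builtin_rule_table, classify_protein
from plantreg.annotations import ProteinAnnotation, DomainHit

table = builtin_rule_table()
protein = ProteinAnnotation("At3g25730-like")
for acc in ("IPR003340", "IPR001471"):      # B3 domain + AP2 domain
    protein.add_hit(DomainHit("At3g25730-like", acc))

for p in classify_protein(protein, table):
    print(p.sequence_id, p.family_name, p.category, sorted(p.satisfied_atoms))
```

prints

```
At3g25730-like RAV TF ['IPR001471', 'IPR003340']
```

one line, because the protein carries both DNA-binding domains: the RAV
rule (`IPR003340 & IPR001471`) is satisfied, while the single-domain B3 and
AP2-EREBP rules are vetoed by their prohibited patterns and ARF's
must-have is unmet. A MADS-box-only protein (`IPR002100`) would print
`MADS type1`, and adding the K-box (`IPR002487`) switches the call to
`MADS-MICK`.

The same pipeline runs from the shell:

```sh
plantreg classify --input proteins.fasta --annotations interproscan.tsv \
    --rules builtin --out-dir out/
plantreg compare out/assignments.tsv reference.tsv --synonyms syn.tsv
plantreg rules list builtin
plantreg fixtures --out-dir demo/ --n-families 6 --seed 4
```

`classify` writes `predictions.tsv` (one row per sequence × family, with
the satisfying accessions and, for nucleotide input, the source frame and
coordinate), `assignments.tsv` (the two-column gene→family form `compare`
reads), `summary.tsv`/`summary.json` (per-family and per-category counts)
and a `run.log` recording the rule-table provenance and checksum.

The shipped starter table contains the families whose logics are fully
published (ARF, MADS type1, MADS-MICK) plus scaffold rules for the
B3/AP2-EREBP/RAV and BTB-POZ superfamily splits; see
`src/plantreg/data/builtin_rules.tsv` for curation status, and load your
own curated table with `--rules my_rules.tsv`.

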