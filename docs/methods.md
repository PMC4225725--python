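# Methods

## Model

`plantreg` assigns plant regulatory-gene families from protein domain
architecture. The unit of evidence is a protein's **accession set** *S*:
the union of every member-database signature (PFAM, PROSITE, SMART, …) and
every integrated InterPro entry reported for the protein by an external
domain scanner. Each family *F* carries a prediction logic

- must-have pattern `M_F` — a boolean expression over accessions with
  `&` (AND) and `|` (OR), no negation;
- optional prohibited pattern `P_F` — same language, same semantics;
  its satisfaction vetoes the family.

A protein is assigned to *F* iff `M_F(S)` is true and `P_F(S)` is false or
absent. All qualifying families are reported in rule-table order; the
package deliberately has no ranking or single-best-family heuristic,
because ambiguity between families sharing a core domain is a property of
the rule table and should be resolved there (with prohibitions) or
surfaced, not hidden. Coordinates and scores of domain hits are retained
for reporting but never used in the decision: the model is presence /
absence of signatures, and any score thresholding is the scanner's
responsibility.

### Rule language

Grammar: `expr := term ('|' term)*`, `term := factor ('&' factor)*`,
`factor := ACCESSION | '(' expr ')'`; `&` binds tighter than `|`,
whitespace is ignored, accessions match `[A-Za-z]{2,4}[0-9]{4,7}` and are
compared case-insensitively. The published examples are always fully
parenthesized and do not pin down precedence; AND-over-OR is the
conventional choice, and curated tables are encouraged to parenthesize
anyway. The prohibited pattern is given the full expression language
(published examples show only single accessions; a bare list `A|B` is the
common case, and sharing the grammar costs nothing). Since the language
has no negation, satisfaction is monotone: growing an accession set can
only add families before prohibitions are applied — prohibitions are the
sole mechanism that makes a larger domain complement *remove* a family,
which is exactly how the MADS and B3/AP2-EREBP/RAV/ARF superfamilies are
split.

### Six-frame translation

Nucleotide input is translated in all six frames with the standard genetic
code (table 1). Segments are stop-to-stop: no initiator ATG is required,
because domain scans operate on fragments. The minimum segment length
defaults to **50 aa** — shorter segments cannot carry a conserved domain —
and `min_len=1` recovers scan-everything behaviour. Codons containing N
translate to `X`, which never matches a stop and counts toward segment
length. Coordinates are 1-based and forward-strand anchored; frames are
`+1..+3` and `-1..-3`, where frame `-k` reads the reverse complement with
offset `k-1` and a segment's `nt_start` is the forward-strand position of
the 5′ base of its first codon on its own strand. Sequence-type detection
calls a record nucleic when ≥ 95% of its non-gap characters are in
`{A,C,G,T,U,N}`; an explicit declared type always overrides.

When several ORF segments of one nucleotide record qualify for the same
family, one prediction is emitted for the segment with the most satisfied
must-have atoms (ties: smallest `nt_start`), so a single gene never counts
twice in family totals.

### Benchmarking

`compare_assignments` classifies every gene in reference ∪ prediction into
exactly one of four categories: match (both tables, family sets
intersect), conflict (both tables, disjoint), missed (reference only),
newly predicted (prediction only). Intersection rather than equality
defines a match because predictions may legitimately carry several
families; this is conservative toward "match" and avoids artificial
conflicts from multi-assignment. The identity
`matches + conflicts + missed = |reference|` is structural and is verified
property-style on random tables. Family names fold through an optional
synonym map (case-insensitive); gene ids are compared exactly unless the
caller opts into stripping a trailing `.N` transcript suffix.

## Synthetic data

The fixture generator emulates the pipeline's four inputs with planted
ground truth; all generators are pure functions of their arguments
including the seed.

- **Rule tables**: each family gets 1–`max_atoms` fresh accessions from
  the reserved `ZZ` namespace and a random AND/OR tree in which every
  atom appears exactly once; ~30% of families (default) get a prohibited
  pattern drawn from a sibling family's atoms. Because atom sets are
  disjoint across families, subset-overlap lint warnings occur exactly at
  the (base, super) pairs the generator optionally plants.
- **Annotations**: positives receive a minimal satisfying set of their
  family's must-have expression (AND → all children, OR → one child);
  since every atom occurs once per expression, removing any atom
  falsifies it, which is what `missing_atom` decoys do. `prohibited_extra`
  decoys additionally carry atoms satisfying the prohibited pattern, so
  the must-have holds and only the veto excludes them. Noise accessions
  come from a disjoint `ZZ9` namespace and appear in no rule, so planted
  truth is recovered with precision = recall = 1 in the absence of decoys.
- **DNA encodings**: peptides are reverse-translated with uniformly random
  synonymous codons (no codon-usage bias) and embedded at a requested
  frame between in-frame stop codons; the construction is re-sampled until
  six-frame translation recovers the peptide in exactly the planted frame,
  so recovery tests are exact rather than probabilistic.

What the generator does **not** emulate: real domain-architecture
evolution, homology between family members, scanner false positives /
false negatives, overlapping hit coordinates, or biased codon usage.
Passing the planted-truth suite therefore demonstrates that the rule
engine, translation and bookkeeping are correct — not that any particular
curated rule table is biologically complete or that scanner output on real
proteomes is error-free.

## Shipped rule table

The builtin table contains the three fully published logics (ARF
`(IPR010525|IPR011525)&IPR003340`; MADS type1 `IPR002100` with K-box
`IPR002487` prohibited; MADS-MICK `IPR002100&IPR002487`) plus scaffold
rows splitting the B3 / AP2-EREBP / RAV / ARF group and the
BTB-POZ-MATH / ABTB pair. The BTB/POZ core uses PROSITE `PS50097` or SMART
`SM00225`; the AP2 (`IPR001471`), MATH (`IPR002083`) and ankyrin
(`IPR002110`) companions are the standard InterPro entries but are marked
in the table as requiring curation against a complete published family
list, which is not redistributable here. Production use should load a
fully curated table via `load_rule_table`; the loader and validator are
size-independent (tested on generated tables of comparable scale to the
full 108-family set).

## Numerical and design choices

- Accession comparison is case-insensitive and version-less; user files
  mix cases, while the identifiers themselves are case-stable.
- Parse errors report a 0-based character offset; table errors report
  family and line number.
- `classify_batch` output order is deterministic (input order, then rule
  order) and reruns are byte-identical; the CLI logs the rule-table
  SHA-256 so results are traceable to a curation state.
- A record with no available annotation is a warned no-hit, not an error:
  genome-scale scans routinely omit proteins with no detectable domains.
- Empty accession sets satisfy no expression (no negation ⇒ no vacuous
  truth).
- Acceptance-style checks run at desk scale by design: 200 random
  expressions × all 2^k subsets (k ≤ 6), ~120 (peptide, frame) round
  trips, 20 families × 5 positives, 100 random benchmark table pairs.
  These sizes exercise every code path while keeping the whole suite in
  seconds.

## Known limitations

- Only the standard genetic code is supported; plastid/mitochondrial
  codes are out of scope, as are splice-aware translation and gene
  prediction.
- The engine never runs domain scanning itself; result quality is bounded
  by the scanner's sensitivity and the rule table's curation. The
  published genome-scale benchmark numbers depend on specific genome
  releases, a reference database snapshot and full InterProScan runs, and
  are not reproducible from this repository.
- Multi-assignment is possible under under-curated tables (the validator
  flags the structural cases); the benchmark's intersection semantics are
  tolerant of it.
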