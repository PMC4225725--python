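"""Synthetic test-data generators with planted ground truth.

Every generator is a pure function of its arguments including the seed,
so fixtures are reproducible and the whole pipeline — rule loading,
six-frame translation, annotation lookup, classification, benchmarking —
is testable without an external domain scanner or any downloaded data.

Synthetic domain accessions live in a reserved ``ZZ`` namespace
(``ZZ0xxxx``–``ZZ8xxxx`` for rule atoms, ``ZZ9xxxx`` for noise) so they
can never collide with real InterPro / PFAM / PROSITE / SMART
identifiers, and noise accessions can never collide with rule atoms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from Bio.Data import CodonTable

from plantreg.annotations import AnnotationMap, DomainHit, ProteinAnnotation
from plantreg.rules import (
    And,
    Atom,
    Expr,
    FamilyRule,
    Or,
    RuleTable,
    atoms,
    write_rule_table,
)
from plantreg.seqio import FRAMES, SequenceRecord, reverse_complement, six_frame_translate

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOP_CODONS = tuple(_CODON_TABLE.stop_codons)
_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _CODON_TABLE.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, [])  # type: ignore[arg-type]
    _CODONS_BY_AA[_aa].append(_codon)  # type: ignore[index]
_CODONS_BY_AA = {aa: tuple(sorted(cs)) for aa, cs in _CODONS_BY_AA.items()}


# --------------------------------------------------------------------------
# Rule-table generation
# --------------------------------------------------------------------------

@dataclass
class GeneratedRules:
    """A generated rule table plus its construction log."""

    table: RuleTable
    atom_inventory: list[str]
    planted_overlaps: list[tuple[str, str]] = field(default_factory=list)


class _AtomFactory:
    """Sequential accessions in the reserved synthetic namespace."""

    def __init__(self):
        self._rule_counter = 0
        self._noise_counter = 0

    def rule_atom(self) -> str:
        self._rule_counter += 1
        if self._rule_counter >= 90000:
            raise ValueError("synthetic rule-atom namespace exhausted")
        return f"ZZ{self._rule_counter:05d}"

    def noise_atom(self) -> str:
        self._noise_counter += 1
        if self._noise_counter >= 10000:
            raise ValueError("synthetic noise-atom namespace exhausted")
        return f"ZZ9{self._noise_counter:04d}"


def _random_expr(atom_tokens: list[str], rng: random.Random) -> Expr:
    """Random AND/OR tree whose leaves are exactly *atom_tokens*, each once."""
    if len(atom_tokens) == 1:
        return Atom(atom_tokens[0])
    n = len(atom_tokens)
    n_children = rng.randint(2, n)
    # split tokens into n_children non-empty contiguous parts of a shuffle
    tokens = atom_tokens[:]
    rng.shuffle(tokens)
    cut_points = sorted(rng.sample(range(1, n), n_children - 1))
    parts = []
    prev = 0
    for cut in cut_points + [n]:
        parts.append(tokens[prev:cut])
        prev = cut
    children = tuple(_random_expr(part, rng) for part in parts)
    kind = rng.choice((And, Or))
    return kind(children)


def generate_rule_table(
    n_families: int,
    max_atoms: int,
    seed: int,
    prohibited_fraction: float = 0.3,
    n_overlap_pairs: int = 0,
) -> GeneratedRules:
    """Generate a random rule table over the synthetic accession namespace.

    Each family receives its own fresh atoms (so families are mutually
    satisfiable in isolation); about *prohibited_fraction* of families get a
    prohibited pattern drawn from a sibling family's atoms.  When
    *n_overlap_pairs* > 0, the first ``2*n_overlap_pairs`` families are
    constructed as (base, super) pairs in which the base's must-have atoms
    are a strict subset of the super's and the base carries no
    distinguishing prohibition — exactly the situation
    :func:`plantreg.rules.validate_rule_table` warns about — and those
    pairs are recorded in ``planted_overlaps``.
    """
    if n_families < 1 or max_atoms < 1:
        raise ValueError("n_families and max_atoms must be >= 1")
    if n_families < 2 * n_overlap_pairs:
        raise ValueError("n_families must be >= 2 * n_overlap_pairs")
    rng = random.Random(seed)
    factory = _AtomFactory()
    categories = ("TF", "TR", "CR")
    rules: list[FamilyRule] = []
    family_atoms: dict[str, list[str]] = {}
    planted: list[tuple[str, str]] = []

    idx = 0
    for _pair in range(n_overlap_pairs):
        base_name = f"FAM{idx:03d}"
        idx += 1
        super_name = f"FAM{idx:03d}"
        idx += 1
        base_atoms = [factory.rule_atom() for _ in range(rng.randint(1, max_atoms))]
        extra = [factory.rule_atom() for _ in range(rng.randint(1, max(1, max_atoms - 1)))]
        # base: pure conjunction so every base atom is required -> subset holds
        base_expr: Expr = (
            Atom(base_atoms[0]) if len(base_atoms) == 1
            else And(tuple(Atom(a) for a in base_atoms))
        )
        super_expr: Expr = And(tuple(Atom(a) for a in base_atoms + extra))
        rules.append(FamilyRule(base_name, categories[idx % 3], base_expr, None))
        rules.append(FamilyRule(super_name, categories[(idx + 1) % 3], super_expr, None))
        family_atoms[base_name] = base_atoms
        family_atoms[super_name] = base_atoms + extra
        planted.append((base_name, super_name))

    while idx < n_families:
        name = f"FAM{idx:03d}"
        own = [factory.rule_atom() for _ in range(rng.randint(1, max_atoms))]
        expr = _random_expr(own, rng)
        rules.append(FamilyRule(name, categories[idx % 3], expr, None))
        family_atoms[name] = own
        idx += 1

    # prohibitions referencing sibling atoms, added after all families exist;
    # overlap-pair bases are left clean so the planted warnings survive
    overlap_bases = {b for b, _ in planted}
    final_rules: list[FamilyRule] = []
    for rule in rules:
        prohibited: Optional[Expr] = None
        if (
            rule.family_name not in overlap_bases
            and len(rules) > 1
            and rng.random() < prohibited_fraction
        ):
            donor = rng.choice([r for r in rules if r.family_name != rule.family_name])
            donor_atoms = family_atoms[donor.family_name]
            k = min(len(donor_atoms), rng.randint(1, 2))
            chosen = rng.sample(donor_atoms, k)
            prohibited = (
                Atom(chosen[0]) if k == 1 else Or(tuple(Atom(a) for a in chosen))
            )
        final_rules.append(
            FamilyRule(rule.family_name, rule.category, rule.must_have, prohibited)
        )

    inventory = [a for atoms_ in family_atoms.values() for a in atoms_]
    return GeneratedRules(
        table=RuleTable(rules=final_rules, provenance=f"generated(seed={seed})"),
        atom_inventory=inventory,
        planted_overlaps=planted,
    )


# --------------------------------------------------------------------------
# Annotation generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoyInfo:
    """Which family a decoy was aimed at and how it violates the rule."""

    family: str
    kind: str  # "missing_atom" or "prohibited_extra"


@dataclass
class PlantedTruth:
    """Ground truth for a generated annotation set."""

    seed: int
    truth: dict[str, Optional[str]] = field(default_factory=dict)
    accessions: dict[str, frozenset[str]] = field(default_factory=dict)
    decoys: dict[str, DecoyInfo] = field(default_factory=dict)

    @property
    def positives(self) -> dict[str, str]:
        return {s: f for s, f in self.truth.items() if f is not None}


def minimal_satisfying_set(expr: Expr, rng: random.Random) -> set[str]:
    """One satisfying accession set: AND takes all children, OR picks one."""
    if isinstance(expr, Atom):
        return {expr.token}
    if isinstance(expr, And):
        out: set[str] = set()
        for child in expr.children:
            out |= minimal_satisfying_set(child, rng)
        return out
    return minimal_satisfying_set(rng.choice(expr.children), rng)


def _positive_set(rule: FamilyRule, rng: random.Random, attempts: int = 50) -> set[str]:
    """A satisfying set for the rule that does not trip its own prohibition."""
    for _ in range(attempts):
        accs = minimal_satisfying_set(rule.must_have, rng)
        if rule.accepts(accs):
            return accs
    raise ValueError(
        f"family {rule.family_name!r}: could not construct a positive; "
        "its prohibited pattern may subsume every satisfying assignment"
    )


def generate_annotations(
    rules: RuleTable,
    n_pos_per_family: int,
    n_decoys: int,
    noise_accessions: int,
    seed: int,
) -> tuple[AnnotationMap, PlantedTruth]:
    """Planted positives, decoys and noise for a rule table.

    Positives get a minimal satisfying accession set for their family (plus
    noise); *n_decoys* decoys per family either drop one required atom
    (``missing_atom``) or additionally carry an atom satisfying the family's
    prohibited pattern (``prohibited_extra``).  Noise accessions come from
    the reserved noise namespace and never occur in any rule, so they can
    change no rule's verdict.
    """
    if len(rules) == 0:
        raise ValueError("rule table must be non-empty")
    rng = random.Random(seed)
    factory = _AtomFactory()
    noise_pool = [factory.noise_atom() for _ in range(max(50, 4 * noise_accessions))]
    rule_atoms_upper = {
        a.upper()
        for r in rules
        for a in (
            atoms(r.must_have) | (atoms(r.prohibited) if r.prohibited else frozenset())
        )
    }
    noise_pool = [a for a in noise_pool if a.upper() not in rule_atoms_upper]

    annotations: AnnotationMap = {}
    planted = PlantedTruth(seed=seed)

    def _register(seq_id: str, accs: set[str], family: Optional[str]) -> None:
        if noise_accessions:
            accs = accs | set(rng.sample(noise_pool, min(noise_accessions, len(noise_pool))))
        ann = ProteinAnnotation(seq_id)
        for acc in sorted(accs):
            ann.add_hit(DomainHit(seq_id, acc))
        annotations[seq_id] = ann
        planted.truth[seq_id] = family
        planted.accessions[seq_id] = frozenset(accs)

    for rule in rules:
        safe = rule.family_name.replace(" ", "_")
        for i in range(n_pos_per_family):
            accs = _positive_set(rule, rng)
            _register(f"POS_{safe}_{i:03d}", accs, rule.family_name)
        for i in range(n_decoys):
            base = _positive_set(rule, rng)
            if rule.prohibited is not None and i % 2 == 0:
                kind = "prohibited_extra"
                accs = base | minimal_satisfying_set(rule.prohibited, rng)
            else:
                kind = "missing_atom"
                accs = set(base)
                accs.discard(rng.choice(sorted(base)))
            seq_id = f"DECOY_{safe}_{i:03d}"
            _register(seq_id, accs, None)
            planted.decoys[seq_id] = DecoyInfo(rule.family_name, kind)

    return annotations, planted


def write_domain_table(annotations: AnnotationMap, path: Union[str, Path]) -> None:
    """Write annotations in the simplified two-column TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein_id\taccession\n")
        for protein_id in sorted(annotations):
            for acc in sorted(annotations[protein_id].accession_set):
                fh.write(f"{protein_id}\t{acc}\n")


# --------------------------------------------------------------------------
# Reverse translation
# --------------------------------------------------------------------------

def random_peptide(length: int, rng: random.Random) -> str:
    """Uniform random peptide over the 20 standard amino acids."""
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _random_codon(rng: random.Random) -> str:
    """A random non-stop codon."""
    while True:
        codon = "".join(rng.choice("ACGT") for _ in range(3))
        if codon not in _STOP_CODONS:
            return codon


def encode_protein_to_dna(
    peptide: str, frame: str, flank: int, seed: int
) -> str:
    """Reverse-translate *peptide* and embed it at the requested reading frame.

    Synonymous codons are chosen uniformly at random.  The planted segment is
    delimited by in-frame stop codons (or the sequence end when *flank* is 0,
    where *flank* counts padding codons on each side), so six-frame
    translation with ``min_len <= len(peptide)`` recovers the peptide as a
    complete segment in exactly the requested frame; the construction is
    re-sampled until that uniqueness holds.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    bad = set(peptide) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(
            f"peptide must be stop-free over the 20 standard amino acids; "
            f"illegal symbols: {sorted(bad)}"
        )
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame!r}")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    rng = random.Random(seed)
    k = int(frame[1])
    for _attempt in range(100):
        coding = "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in peptide)
        prefix = "".join(rng.choice("ACGT") for _ in range(k - 1))
        left = prefix
        right = ""
        if flank > 0:
            left += "".join(_random_codon(rng) for _ in range(flank))
            left += rng.choice(_STOP_CODONS)
            right += rng.choice(_STOP_CODONS)
            right += "".join(_random_codon(rng) for _ in range(flank))
        else:
            right += rng.choice(_STOP_CODONS)
        s_plus = left + coding + right
        s = s_plus if frame[0] == "+" else reverse_complement(s_plus)
        if _planted_uniquely(s, peptide, frame):
            return s
    raise RuntimeError(
        f"could not embed peptide uniquely in frame {frame} after 100 attempts"
    )


def _planted_uniquely(s: str, peptide: str, frame: str) -> bool:
    record = SequenceRecord("probe", s, declared_type="nucleic")
    segments = six_frame_translate(record, min_len=len(peptide))
    hit_frames = {seg.frame for seg in segments if peptide in seg.peptide}
    exact = [
        seg for seg in segments if seg.frame == frame and seg.peptide == peptide
    ]
    return hit_frames == {frame} and len(exact) == 1


def find_planted_segment(dna: str, peptide: str, frame: str, parent_id: str):
    """The :class:`TranslatedSegment` of *dna* whose peptide equals *peptide*."""
    record = SequenceRecord(parent_id, dna, declared_type="nucleic")
    for seg in six_frame_translate(record, min_len=len(peptide)):
        if seg.frame == frame and seg.peptide == peptide:
            return seg
    raise ValueError("planted peptide not found in the stated frame")


# --------------------------------------------------------------------------
# Fixture bundles
# --------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Paths of a written fixture bundle plus its ground truth."""

    rules_path: Path
    domains_path: Path
    protein_fasta_path: Path
    dna_fasta_path: Path
    reference_path: Path
    truth: PlantedTruth
    dna_truth: dict[str, str] = field(default_factory=dict)


def write_fixture_bundle(
    outdir: Union[str, Path],
    rules: RuleTable,
    seed: int,
    n_pos_per_family: int = 3,
    n_decoys: int = 0,
    noise_accessions: int = 0,
    n_dna_per_family: int = 1,
    peptide_length: int = 60,
) -> FixtureBundle:
    """Write a complete on-disk fixture set exercising the whole pipeline.

    Emits the rule table, a two-column domain table covering both protein ids
    and the segment ids of planted DNA encodings, protein and DNA FASTA
    files, and a gene→family reference table of the planted truth.  DNA
    records re-encode the first *n_dna_per_family* positives of each family:
    a random peptide is reverse-translated into a random frame and the
    positive's accession set is attached to the planted segment's id, so
    nucleotide-mode classification must reproduce protein-mode results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    annotations, truth = generate_annotations(
        rules, n_pos_per_family, n_decoys, noise_accessions, seed
    )

    rules_path = outdir / "rules.tsv"
    write_rule_table(rules, rules_path)

    # protein FASTA: sequence content is irrelevant to classification
    protein_fasta_path = outdir / "proteins.fasta"
    with open(protein_fasta_path, "w", encoding="utf-8") as fh:
        for seq_id in sorted(annotations):
            fh.write(f">{seq_id}\n{random_peptide(peptide_length, rng)}\n")

    # DNA encodings of the first n_dna_per_family positives per family
    dna_truth: dict[str, str] = {}
    dna_records: list[tuple[str, str]] = []
    segment_annotations: AnnotationMap = {}
    by_family: dict[str, list[str]] = {}
    for seq_id, fam in sorted(truth.positives.items()):
        by_family.setdefault(fam, []).append(seq_id)
    for fam, ids in sorted(by_family.items()):
        for seq_id in ids[:n_dna_per_family]:
            peptide = random_peptide(peptide_length, rng)
            frame = rng.choice(FRAMES)
            dna = encode_protein_to_dna(
                peptide, frame, flank=4, seed=rng.randrange(2**31)
            )
            dna_id = f"DNA_{seq_id}"
            seg = find_planted_segment(dna, peptide, frame, dna_id)
            ann = ProteinAnnotation(seg.segment_id)
            for acc in sorted(truth.accessions[seq_id]):
                ann.add_hit(DomainHit(seg.segment_id, acc))
            segment_annotations[seg.segment_id] = ann
            dna_records.append((dna_id, dna))
            dna_truth[dna_id] = fam

    dna_fasta_path = outdir / "dna.fasta"
    with open(dna_fasta_path, "w", encoding="utf-8") as fh:
        for dna_id, dna in dna_records:
            fh.write(f">{dna_id}\n{dna}\n")

    domains_path = outdir / "domains.tsv"
    combined: AnnotationMap = {**annotations, **segment_annotations}
    write_domain_table(combined, domains_path)

    reference_path = outdir / "reference.tsv"
    with open(reference_path, "w", encoding="utf-8") as fh:
        fh.write("# gene_id\tfamily\n")
        for seq_id, fam in sorted(truth.positives.items()):
            fh.write(f"{seq_id}\t{fam}\n")
        for dna_id, fam in sorted(dna_truth.items()):
            fh.write(f"{dna_id}\t{fam}\n")

    return FixtureBundle(
        rules_path=rules_path,
        domains_path=domains_path,
        protein_fasta_path=protein_fasta_path,
        dna_fasta_path=dna_fasta_path,
        reference_path=reference_path,
        truth=truth,
        dna_truth=dna_truth,
    )
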