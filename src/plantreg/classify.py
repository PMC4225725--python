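"""Family assignment: evaluate every rule against each protein's accession set.

A protein is assigned to every family whose must-have expression its
accession set satisfies and whose prohibited expression (if any) it does
not — all qualifying families are reported, in rule-table order; a curated
table disambiguates superfamilies through prohibitions rather than through
any ranking heuristic.  Nucleotide records are routed through six-frame
translation, their segments classified, and predictions re-attributed to
the parent sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

from plantreg.annotations import AnnotationMap, ProteinAnnotation
from plantreg.rules import FamilyRule, RuleTable, atoms, evaluate
from plantreg.seqio import SequenceRecord, detect_sequence_type, six_frame_translate

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = (
    "sequence_id", "family", "category", "satisfied_atoms",
    "all_accessions", "frame", "nt_start",
)


@dataclass(frozen=True)
class FamilyPrediction:
    """One (sequence, family) assignment.

    ``satisfied_atoms`` are the must-have atoms actually present on the
    protein; ``frame``/``nt_start`` locate the source ORF segment for
    nucleotide input and are ``None`` for protein input.
    """

    sequence_id: str
    family_name: str
    category: str
    satisfied_atoms: frozenset[str]
    all_accessions: frozenset[str]
    frame: Optional[str] = None
    nt_start: Optional[int] = None


@dataclass(frozen=True)
class Explanation:
    """Audit record for one (protein, rule) evaluation."""

    protein_id: str
    family_name: str
    must_have_satisfied: bool
    matched_atoms: frozenset[str]
    missing_atoms: frozenset[str]
    prohibited_fired: bool
    fired_prohibited_atoms: frozenset[str]
    included: bool

    def render(self) -> str:
        verdict = "included" if self.included else "excluded"
        lines = [f"{self.protein_id} vs {self.family_name}: {verdict}"]
        lines.append(
            f"  must-have {'satisfied' if self.must_have_satisfied else 'NOT satisfied'}; "
            f"matched atoms: {', '.join(sorted(self.matched_atoms)) or '(none)'}; "
            f"missing atoms: {', '.join(sorted(self.missing_atoms)) or '(none)'}"
        )
        if self.prohibited_fired:
            lines.append(
                "  prohibited pattern fired on: "
                + ", ".join(sorted(self.fired_prohibited_atoms))
            )
        return "\n".join(lines)


@dataclass
class BatchResult:
    """Predictions for a batch plus bookkeeping for the run summary."""

    predictions: list[FamilyPrediction] = field(default_factory=list)
    n_records: int = 0
    no_annotation_ids: list[str] = field(default_factory=list)
    no_hit_ids: list[str] = field(default_factory=list)

    def family_counts(self) -> dict[str, int]:
        """Distinct sequences assigned per family."""
        out: dict[str, set[str]] = {}
        for p in self.predictions:
            out.setdefault(p.family_name, set()).add(p.sequence_id)
        return {fam: len(ids) for fam, ids in out.items()}

    def category_counts(self) -> dict[str, int]:
        """Distinct sequences assigned per regulator category (TF/TR/CR/Other)."""
        out: dict[str, set[str]] = {}
        for p in self.predictions:
            out.setdefault(p.category, set()).add(p.sequence_id)
        return {cat: len(ids) for cat, ids in out.items()}


def _matched_atoms(expr, accession_set: frozenset[str]) -> frozenset[str]:
    upper = {a.upper() for a in accession_set}
    return frozenset(t for t in atoms(expr) if t.upper() in upper)


def classify_protein(
    annotation: ProteinAnnotation, rules: RuleTable
) -> list[FamilyPrediction]:
    """All families whose rule accepts the protein, in rule-table order.

    An empty list means the protein is not predicted to be a TF/TR/CR.
    """
    accession_set = annotation.accession_set
    predictions: list[FamilyPrediction] = []
    for rule in rules:
        if rule.accepts(accession_set):
            predictions.append(
                FamilyPrediction(
                    sequence_id=annotation.protein_id,
                    family_name=rule.family_name,
                    category=rule.category,
                    satisfied_atoms=_matched_atoms(rule.must_have, accession_set),
                    all_accessions=accession_set,
                )
            )
    return predictions


def explain(annotation: ProteinAnnotation, rule: FamilyRule) -> Explanation:
    """Why a protein is, or is not, assigned to a family."""
    accession_set = annotation.accession_set
    must_ok = evaluate(rule.must_have, accession_set)
    matched = _matched_atoms(rule.must_have, accession_set)
    missing = atoms(rule.must_have) - matched
    prohibited_fired = rule.prohibited is not None and evaluate(
        rule.prohibited, accession_set
    )
    fired = (
        _matched_atoms(rule.prohibited, accession_set)
        if rule.prohibited is not None
        else frozenset()
    )
    return Explanation(
        protein_id=annotation.protein_id,
        family_name=rule.family_name,
        must_have_satisfied=must_ok,
        matched_atoms=matched,
        missing_atoms=missing,
        prohibited_fired=prohibited_fired,
        fired_prohibited_atoms=fired,
        included=must_ok and not prohibited_fired,
    )


def classify_batch(
    records: Sequence[SequenceRecord],
    annotations: AnnotationMap,
    rules: RuleTable,
    min_orf_len: int = 50,
) -> BatchResult:
    """Run the full pipeline over a batch of FASTA records.

    Protein records are looked up in *annotations* by their id.  Nucleic
    records are six-frame translated; each segment is looked up by its
    ``parent|frame|nt_start`` segment id and predictions are re-attributed
    to the parent with the frame recorded.  When several segments of one
    record hit the same family only the best-supported segment is kept
    (most satisfied atoms, then smallest nt_start) so one gene never counts
    twice.  Output order is deterministic: input order, then rule order.
    """
    result = BatchResult(n_records=len(records))
    for record in records:
        seq_type = detect_sequence_type(record)
        if seq_type == "protein":
            ann = annotations.get(record.seq_id)
            if ann is None:
                logger.warning("no annotation for record %s; classified as no-hit", record.seq_id)
                result.no_annotation_ids.append(record.seq_id)
                continue
            preds = classify_protein(ann, rules)
        else:
            segments = six_frame_translate(record, min_len=min_orf_len)
            found_any_annotation = False
            candidates: list[FamilyPrediction] = []
            for seg in segments:
                ann = annotations.get(seg.segment_id)
                if ann is None:
                    continue
                found_any_annotation = True
                for p in classify_protein(ann, rules):
                    candidates.append(
                        FamilyPrediction(
                            sequence_id=record.seq_id,
                            family_name=p.family_name,
                            category=p.category,
                            satisfied_atoms=p.satisfied_atoms,
                            all_accessions=p.all_accessions,
                            frame=seg.frame,
                            nt_start=seg.nt_start,
                        )
                    )
            if not found_any_annotation:
                logger.warning("no annotation for record %s; classified as no-hit", record.seq_id)
                result.no_annotation_ids.append(record.seq_id)
                continue
            preds = _dedupe_by_family(candidates, rules)
        if not preds:
            result.no_hit_ids.append(record.seq_id)
        result.predictions.extend(preds)
    return result


def _dedupe_by_family(
    candidates: list[FamilyPrediction], rules: RuleTable
) -> list[FamilyPrediction]:
    """One prediction per family per parent: best segment wins."""
    best: dict[str, FamilyPrediction] = {}
    for p in candidates:
        cur = best.get(p.family_name)
        if cur is None:
            best[p.family_name] = p
            continue
        key_new = (-len(p.satisfied_atoms), p.nt_start)
        key_cur = (-len(cur.satisfied_atoms), cur.nt_start)
        if key_new < key_cur:
            best[p.family_name] = p
    order = {name: i for i, name in enumerate(rules.family_names)}
    return sorted(best.values(), key=lambda p: order.get(p.family_name, len(order)))


def write_prediction_table(
    predictions: Sequence[FamilyPrediction], out: Union[str, Path, TextIO]
) -> None:
    """Write predictions as TSV; absent fields are rendered ``-``."""
    own = isinstance(out, (str, Path))
    fh = open(out, "w", encoding="utf-8") if own else out
    try:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for p in predictions:
            fh.write(
                "\t".join(
                    (
                        p.sequence_id,
                        p.family_name,
                        p.category,
                        ",".join(sorted(p.satisfied_atoms)) or "-",
                        ",".join(sorted(p.all_accessions)) or "-",
                        p.frame if p.frame is not None else "-",
                        str(p.nt_start) if p.nt_start is not None else "-",
                    )
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()
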