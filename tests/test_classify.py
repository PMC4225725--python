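"""Family assignment: superfamily splitting, batch pipeline, explanations."""

import io
import random

import pytest

from plantreg.annotations import DomainHit, ProteinAnnotation
from plantreg.classify import (
    classify_batch,
    classify_protein,
    explain,
    write_prediction_table,
)
from plantreg.fixtures import (
    encode_protein_to_dna,
    find_planted_segment,
    generate_annotations,
    generate_rule_table,
    random_peptide,
)
from plantreg.rules import evaluate
from plantreg.seqio import FRAMES, SequenceRecord

from conftest import oracle_eval


def annotation(protein_id, *accessions):
    ann = ProteinAnnotation(protein_id)
    for acc in accessions:
        ann.add_hit(DomainHit(protein_id, acc))
    return ann


class TestClassifyProtein:
    def test_mads_box_only_is_type1(self, builtin_rules):
        """MADS box alone -> type1; the K-box prohibition keeps MIKC out."""
        preds = classify_protein(annotation("p", "IPR002100"), builtin_rules)
        assert [p.family_name for p in preds] == ["MADS type1"]

    def test_mads_box_plus_kbox_is_mick_only(self, builtin_rules):
        preds = classify_protein(
            annotation("p", "IPR002100", "IPR002487"), builtin_rules
        )
        assert [p.family_name for p in preds] == ["MADS-MICK"]

    def test_empty_accession_set_yields_nothing(self, builtin_rules):
        assert classify_protein(annotation("p"), builtin_rules) == []

    def test_dual_b3_ap2_protein_is_rav_only(self, builtin_rules):
        """A protein carrying both the B3 and AP2 DNA-binding domains belongs
        to RAV, not to B3, AP2-EREBP or ARF."""
        preds = classify_protein(
            annotation("p", "IPR003340", "IPR001471"), builtin_rules
        )
        assert [p.family_name for p in preds] == ["RAV"]

    def test_arf_requires_dimerisation_domain(self, builtin_rules):
        b3_only = classify_protein(annotation("p", "IPR003340"), builtin_rules)
        assert [p.family_name for p in b3_only] == ["B3"]
        arf = classify_protein(
            annotation("p", "IPR011525", "IPR003340"), builtin_rules
        )
        assert [p.family_name for p in arf] == ["ARF"]

    def test_satisfied_atoms_subset_of_accessions(self, builtin_rules):
        preds = classify_protein(
            annotation("p", "IPR002100", "IPR002487", "PF99999"), builtin_rules
        )
        for p in preds:
            assert p.satisfied_atoms <= p.all_accessions

    def test_soundness_against_independent_reevaluation(self):
        """Every emitted prediction re-verifies under the oracle evaluator:
        must-have true and prohibited false on the protein's accession set."""
        gen = generate_rule_table(15, 5, seed=41, prohibited_fraction=0.5)
        anns, _ = generate_annotations(gen.table, 4, 3, 2, seed=42)
        n_checked = 0
        for ann in anns.values():
            for pred in classify_protein(ann, gen.table):
                rule = gen.table.get(pred.family_name)
                assert oracle_eval(rule.must_have, ann.accession_set)
                if rule.prohibited is not None:
                    assert not oracle_eval(rule.prohibited, ann.accession_set)
                n_checked += 1
        assert n_checked > 0

    def test_mads_families_mutually_exclusive(self, builtin_rules):
        rng = random.Random(7)
        pool = ["IPR002100", "IPR002487", "IPR003340", "PF00001", "ZZ00001"]
        for _ in range(100):
            accs = rng.sample(pool, rng.randint(0, len(pool)))
            fams = {p.family_name for p in classify_protein(annotation("p", *accs), builtin_rules)}
            assert not {"MADS type1", "MADS-MICK"} <= fams
            assert not {"B3", "RAV"} <= fams
            assert not {"AP2-EREBP", "RAV"} <= fams


class TestExplain:
    def test_prohibition_fires(self, builtin_rules):
        exp = explain(
            annotation("p", "IPR002100", "IPR002487"),
            builtin_rules.get("MADS type1"),
        )
        assert exp.must_have_satisfied
        assert exp.prohibited_fired
        assert exp.fired_prohibited_atoms == {"IPR002487"}
        assert not exp.included
        assert "excluded" in exp.render()

    def test_missing_or_group_reported(self, builtin_rules):
        exp = explain(annotation("p", "IPR003340"), builtin_rules.get("ARF"))
        assert not exp.must_have_satisfied
        assert exp.missing_atoms == {"IPR010525", "IPR011525"}
        assert not exp.included

    def test_all_clauses_satisfied(self, builtin_rules):
        exp = explain(
            annotation("p", "IPR010525", "IPR003340"), builtin_rules.get("ARF")
        )
        assert exp.included
        assert exp.matched_atoms == {"IPR010525", "IPR003340"}


class TestClassifyBatch:
    def test_protein_mode(self, builtin_rules):
        records = [SequenceRecord("p1", "MKVLWEQF")]
        anns = {"p1": annotation("p1", "IPR002100")}
        result = classify_batch(records, anns, builtin_rules)
        assert [(p.sequence_id, p.family_name, p.frame) for p in result.predictions] == [
            ("p1", "MADS type1", None)
        ]

    @pytest.mark.parametrize("frame", FRAMES)
    def test_mode_equivalence_per_frame(self, builtin_rules, frame):
        """Nucleotide encoding of a protein classifies identically to the
        protein itself, modulo the frame field, in every frame."""
        rng = random.Random(sum(ord(c) for c in frame))
        peptide = random_peptide(60, rng)
        dna = encode_protein_to_dna(peptide, frame, flank=4, seed=99)
        seg = find_planted_segment(dna, peptide, frame, "g1")
        accs = ("IPR002100", "IPR002487")

        protein_result = classify_batch(
            [SequenceRecord("g1", peptide)],
            {"g1": annotation("g1", *accs)},
            builtin_rules,
        )
        dna_result = classify_batch(
            [SequenceRecord("g1", dna, declared_type="nucleic")],
            {seg.segment_id: annotation(seg.segment_id, *accs)},
            builtin_rules,
            min_orf_len=50,
        )
        strip = lambda preds: [
            (p.sequence_id, p.family_name, p.category, p.satisfied_atoms)
            for p in preds
        ]
        assert strip(dna_result.predictions) == strip(protein_result.predictions)
        assert dna_result.predictions[0].frame == frame
        assert dna_result.predictions[0].nt_start == seg.nt_start

    def test_segments_deduplicated_per_family(self, builtin_rules):
        """Two ORF segments of one record hitting the same family produce a
        single prediction, attributed to the better-supported segment."""
        rng = random.Random(3)
        pep_a, pep_b = random_peptide(55, rng), random_peptide(55, rng)
        # both peptides in frame +1, separated by a stop codon
        from plantreg.fixtures import _CODONS_BY_AA  # synthetic-codon table
        enc = lambda pep: "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in pep)
        dna = enc(pep_a) + "TAA" + enc(pep_b)
        record = SequenceRecord("g1", dna, declared_type="nucleic")
        seg_a = find_planted_segment(dna, pep_a, "+1", "g1")
        seg_b = find_planted_segment(dna, pep_b, "+1", "g1")
        anns = {
            seg_a.segment_id: annotation(seg_a.segment_id, "IPR002100"),
            seg_b.segment_id: annotation(seg_b.segment_id, "IPR002100", "IPR002487"),
        }
        result = classify_batch([record], anns, builtin_rules, min_orf_len=50)
        fams = [(p.family_name, p.nt_start) for p in result.predictions]
        # type1 only from segment A, MICK only from segment B; one row each
        assert fams == [("MADS type1", seg_a.nt_start), ("MADS-MICK", seg_b.nt_start)]

        # same family from both segments: one row, earliest segment wins the tie
        anns_same = {
            seg_a.segment_id: annotation(seg_a.segment_id, "IPR002100"),
            seg_b.segment_id: annotation(seg_b.segment_id, "IPR002100"),
        }
        result2 = classify_batch([record], anns_same, builtin_rules, min_orf_len=50)
        assert [(p.family_name, p.nt_start) for p in result2.predictions] == [
            ("MADS type1", min(seg_a.nt_start, seg_b.nt_start))
        ]

    def test_missing_annotation_is_warned_no_hit(self, builtin_rules, caplog):
        records = [SequenceRecord("p1", "MKVLWEQF")]
        with caplog.at_level("WARNING"):
            result = classify_batch(records, {}, builtin_rules)
        assert result.predictions == []
        assert result.no_annotation_ids == ["p1"]
        assert "p1" in caplog.text

    def test_output_deterministic_and_ordered(self, builtin_rules):
        records = [
            SequenceRecord("b", "MKVLWEQF"),
            SequenceRecord("a", "MKVLWEQF"),
        ]
        anns = {
            "a": annotation("a", "IPR002100"),
            "b": annotation("b", "IPR003340", "IPR001471"),
        }

        def run():
            result = classify_batch(records, anns, builtin_rules)
            buf = io.StringIO()
            write_prediction_table(result.predictions, buf)
            return buf.getvalue()

        first, second = run(), run()
        assert first == second  # byte-identical
        # input order preserved: record 'b' precedes 'a'
        lines = first.splitlines()
        assert lines[1].startswith("b\tRAV")
        assert lines[2].startswith("a\tMADS type1")

    def test_summary_counts_match_predictions(self, builtin_rules):
        records = [SequenceRecord(f"p{i}", "MKVLWEQF") for i in range(4)]
        anns = {
            "p0": annotation("p0", "IPR002100"),
            "p1": annotation("p1", "IPR002100"),
            "p2": annotation("p2", "IPR002100", "IPR002487"),
            "p3": annotation("p3", "PF99999"),
        }
        result = classify_batch(records, anns, builtin_rules)
        assert result.family_counts() == {"MADS type1": 2, "MADS-MICK": 1}
        assert result.category_counts() == {"TF": 3}
        assert result.no_hit_ids == ["p3"]
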