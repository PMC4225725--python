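"""Prediction-vs-reference comparison: matches, conflicts, missed, newly predicted.

Given a prediction table and a reference gene→family assignment, each
reference gene falls into exactly one of *matches* (predicted, family sets
intersect), *conflicts* (predicted, family sets disjoint) or *missed* (not
predicted); genes predicted but absent from the reference are *newly
predicted*.  The four gene lists partition the union of both gene sets,
so matches + conflicts + missed always equals the reference size.
A gene counts as a match when the family sets intersect rather than being
equal, because predictions may legitimately carry several families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

from plantreg.errors import AnnotationError

AssignmentTable = dict[str, set[str]]

_TRANSCRIPT_SUFFIX = re.compile(r"\.\d+$")


@dataclass(frozen=True)
class ComparisonResult:
    """Counts and sorted gene lists for the four comparison categories."""

    matches: tuple[str, ...]
    conflicts: tuple[str, ...]
    missed: tuple[str, ...]
    newly_predicted: tuple[str, ...]

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    @property
    def n_conflicts(self) -> int:
        return len(self.conflicts)

    @property
    def n_missed(self) -> int:
        return len(self.missed)

    @property
    def n_newly_predicted(self) -> int:
        return len(self.newly_predicted)

    def as_dict(self) -> dict:
        return {
            "matches": {"count": self.n_matches, "genes": list(self.matches)},
            "conflicts": {"count": self.n_conflicts, "genes": list(self.conflicts)},
            "missed": {"count": self.n_missed, "genes": list(self.missed)},
            "newly_predicted": {
                "count": self.n_newly_predicted,
                "genes": list(self.newly_predicted),
            },
        }


def load_assignment_table(
    path: Union[str, Path], strip_transcript_suffix: bool = False
) -> AssignmentTable:
    """Load a two-column ``gene_id <TAB> family`` TSV into gene→family-set form.

    Repeated gene rows accumulate into family sets.  With
    *strip_transcript_suffix*, a trailing ``.N`` is removed from gene ids
    (gene models vs transcript models); off by default because silent id
    munging is dangerous.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"assignment table not found: {path}")
    table: AssignmentTable = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2 or not cells[0].strip() or not cells[1].strip():
                raise AnnotationError(
                    f"{path}, line {lineno}: expected 'gene_id<TAB>family'"
                )
            gene = cells[0].strip()
            if strip_transcript_suffix:
                gene = _TRANSCRIPT_SUFFIX.sub("", gene)
            table.setdefault(gene, set()).add(cells[1].strip())
    return table


def load_synonym_map(path: Union[str, Path]) -> dict[str, str]:
    """Load a two-column ``alias <TAB> canonical`` family-synonym map."""
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"synonym map not found: {path}")
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2 or not cells[0].strip() or not cells[1].strip():
                raise AnnotationError(
                    f"{path}, line {lineno}: expected 'alias<TAB>canonical'"
                )
            out[cells[0].strip().lower()] = cells[1].strip()
    return out


def _canonicalize(families: set[str], name_map: Optional[Mapping[str, str]]) -> set[str]:
    if not name_map:
        return {f.lower() for f in families}
    lowered = {k.lower(): v for k, v in name_map.items()}
    return {lowered.get(f.lower(), f).lower() for f in families}


def compare_assignments(
    predictions: AssignmentTable,
    reference: AssignmentTable,
    name_map: Optional[Mapping[str, str]] = None,
) -> ComparisonResult:
    """Compare a prediction table against a reference assignment.

    Family names are compared case-insensitively after folding through the
    optional synonym map.  Returns sorted gene lists for the four pairwise
    disjoint categories.
    """
    if not predictions or not reference:
        raise ValueError("both prediction and reference tables must be non-empty")
    matches, conflicts, missed = [], [], []
    for gene, ref_fams in reference.items():
        if gene not in predictions:
            missed.append(gene)
            continue
        pred_fams = _canonicalize(predictions[gene], name_map)
        if pred_fams & _canonicalize(ref_fams, name_map):
            matches.append(gene)
        else:
            conflicts.append(gene)
    newly = [g for g in predictions if g not in reference]
    return ComparisonResult(
        matches=tuple(sorted(matches)),
        conflicts=tuple(sorted(conflicts)),
        missed=tuple(sorted(missed)),
        newly_predicted=tuple(sorted(newly)),
    )


VENN_REGIONS = ("A_only", "B_only", "C_only", "AB_only", "AC_only", "BC_only", "ABC")


def compare_three_way(
    set_a: set[str], set_b: set[str], set_c: set[str]
) -> dict[str, int]:
    """Counts of the seven regions of a three-set Venn diagram.

    Region counts sum to ``|A ∪ B ∪ C|``.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    ab = (a & b) - c
    ac = (a & c) - b
    bc = (b & c) - a
    return {
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB_only": len(ab),
        "AC_only": len(ac),
        "BC_only": len(bc),
        "ABC": len(abc),
    }
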