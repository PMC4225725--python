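"""FASTA input, sequence-type detection and six-frame translation.

Nucleotide submissions are translated conceptually in all six reading
frames; each frame translation is split at stop codons and stop-free
segments at least ``min_len`` residues long are kept as candidate
proteins for domain annotation.  No start codon is required — domain
scans work on fragments — and the default minimum of 50 aa reflects
that shorter segments cannot carry a conserved domain.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from Bio import SeqIO
from Bio.Seq import Seq

from plantreg.errors import FastaError

logger = logging.getLogger(__name__)

NUCLEOTIDE_CHARS = frozenset("ACGTUN")
GAP_CHARS = frozenset("-.")
NUCLEIC_FRACTION_THRESHOLD = 0.95

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record; ``declared_type`` overrides auto-detection."""

    seq_id: str
    residues: str
    declared_type: str = "auto"

    def __post_init__(self):
        if not self.seq_id or any(c.isspace() for c in self.seq_id):
            raise ValueError(f"seq_id must be non-empty without whitespace: {self.seq_id!r}")
        if not self.residues:
            raise ValueError(f"record {self.seq_id!r} has an empty sequence")
        if self.declared_type not in ("auto", "nucleic", "protein"):
            raise ValueError(f"declared_type must be auto/nucleic/protein, got {self.declared_type!r}")


@dataclass(frozen=True)
class TranslatedSegment:
    """A stop-free peptide from one reading frame of a nucleotide record.

    ``nt_start`` is the 1-based forward-strand position of the first base of
    the segment's first codon (for negative frames, the first base as read
    5'→3' on the reverse strand, mapped onto forward coordinates).
    """

    parent_id: str
    frame: str
    nt_start: int
    peptide: str

    def __post_init__(self):
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}, got {self.frame!r}")
        if self.nt_start < 1:
            raise ValueError("nt_start is 1-based and must be >= 1")
        if not self.peptide or "*" in self.peptide:
            raise ValueError("peptide must be non-empty and stop-free")

    @property
    def segment_id(self) -> str:
        """Identifier used when a segment is sent to a domain scanner."""
        return f"{self.parent_id}|{self.frame}|{self.nt_start}"


def read_fasta(path: Union[str, Path], declared_type: str = "auto") -> list[SequenceRecord]:
    """Read a (possibly gzip-compressed) FASTA file into records.

    The record id is the first whitespace-delimited header token; residues
    are uppercased and terminal ``*`` stop symbols stripped.  Raises
    :class:`FastaError` for an empty file, duplicate ids or empty sequences.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"FASTA file not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            residues = str(rec.seq).upper().strip("*")
            if not residues:
                raise FastaError(f"{path}: record {rec.id!r} has an empty sequence")
            records.append(SequenceRecord(rec.id, residues, declared_type))
    if not records:
        raise FastaError(f"{path}: no sequences found")
    return records


def detect_sequence_type(record: SequenceRecord) -> str:
    """Classify a record as ``nucleic`` or ``protein``.

    A record is nucleic when at least 95% of its non-gap characters are in
    ``{A,C,G,T,U,N}`` — protein sequences contain enough of the other amino
    acid letters to fall below that.  A non-``auto`` ``declared_type``
    overrides detection.
    """
    if record.declared_type != "auto":
        return record.declared_type
    chars = [c for c in record.residues if c not in GAP_CHARS]
    if not chars:
        return "protein"
    frac = sum(1 for c in chars if c in NUCLEOTIDE_CHARS) / len(chars)
    return "nucleic" if frac >= NUCLEIC_FRACTION_THRESHOLD else "protein"


def reverse_complement(residues: str) -> str:
    """Watson–Crick reverse complement; U is treated as T, N maps to N."""
    bad = set(residues.upper()) - NUCLEOTIDE_CHARS
    if bad:
        raise ValueError(f"non-nucleotide character(s) in sequence: {sorted(bad)}")
    return residues.upper().translate(_COMPLEMENT)[::-1]


def _translate_frame(nt: str) -> str:
    """Translate one frame with the standard code; N-containing codons -> X."""
    usable = len(nt) - len(nt) % 3
    if usable < 3:
        return ""
    clean = nt[:usable].replace("U", "T")
    if "N" in clean:
        out = []
        for i in range(0, usable, 3):
            codon = clean[i : i + 3]
            out.append("X" if "N" in codon else str(Seq(codon).translate(table=1)))
        return "".join(out)
    return str(Seq(clean).translate(table=1))


def six_frame_translate(record: SequenceRecord, min_len: int = 50) -> list[TranslatedSegment]:
    """Conceptually translate a nucleotide record in all six reading frames.

    Each frame translation (standard genetic code, table 1; codons containing
    N become ``X``) is split at stop codons; stop-free segments with at least
    *min_len* residues are returned with their frame and the forward-strand
    coordinate of their first codon base.  A record shorter than one codon
    yields an empty list with a logged warning.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = record.residues.upper()
    if len(seq) < 3:
        logger.warning(
            "record %s is shorter than one codon (%d nt); no translation",
            record.seq_id, len(seq),
        )
        return []
    L = len(seq)
    rc = reverse_complement(seq)
    segments: list[TranslatedSegment] = []
    for frame in FRAMES:
        strand, k = frame[0], int(frame[1])
        template = seq if strand == "+" else rc
        offset = k - 1
        peptide_full = _translate_frame(template[offset:])
        # split at stops, tracking codon index within the frame
        codon_idx = 0
        for chunk in peptide_full.split("*"):
            if len(chunk) >= min_len:
                # position (0-based, on the translated strand) of first codon base
                strand_pos = offset + 3 * codon_idx
                if strand == "+":
                    nt_start = strand_pos + 1
                else:
                    nt_start = L - strand_pos  # forward 1-based coord of that base
                segments.append(
                    TranslatedSegment(record.seq_id, frame, nt_start, chunk)
                )
            codon_idx += len(chunk) + 1  # +1 for the stop codon
    return segments
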