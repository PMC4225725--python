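"""Per-protein domain-accession sets from external scanner output.

Domain scanning itself is always external (InterProScan or any tool that
emits the same tab-separated dialect); this module only parses results
into :class:`ProteinAnnotation` objects — a protein id plus the union of
every member-database signature accession and InterPro accession seen on
it.  Classification is presence/absence: coordinates and scores are kept
for reporting but never thresholded here.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from plantreg.errors import AnnotationError, ScannerError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DomainHit:
    """One scanner match: a signature on a protein interval."""

    protein_id: str
    signature_acc: str
    interpro_acc: Optional[str] = None
    start: Optional[int] = None
    stop: Optional[int] = None
    score: Optional[float] = None

    def __post_init__(self):
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if self.start is not None and self.stop is not None:
            if not (1 <= self.start <= self.stop):
                raise ValueError(
                    f"require 1 <= start <= stop, got {self.start}..{self.stop}"
                )

    @property
    def accessions(self) -> frozenset[str]:
        accs = {self.signature_acc}
        if self.interpro_acc:
            accs.add(self.interpro_acc)
        return frozenset(accs)


@dataclass
class ProteinAnnotation:
    """A protein's hits and the accession set the rules are evaluated against."""

    protein_id: str
    hits: list[DomainHit] = field(default_factory=list)

    @property
    def accession_set(self) -> frozenset[str]:
        out: set[str] = set()
        for hit in self.hits:
            out |= hit.accessions
        return frozenset(out)

    def add_hit(self, hit: DomainHit) -> None:
        if hit.protein_id != self.protein_id:
            raise ValueError("hit belongs to a different protein")
        self.hits.append(hit)


AnnotationMap = dict[str, ProteinAnnotation]


def _add(annotations: AnnotationMap, hit: DomainHit) -> None:
    ann = annotations.get(hit.protein_id)
    if ann is None:
        ann = ProteinAnnotation(hit.protein_id)
        annotations[hit.protein_id] = ann
    ann.add_hit(hit)


def parse_interproscan_tsv(path: Union[str, Path]) -> AnnotationMap:
    """Parse InterProScan 5 tab-separated output into per-protein annotations.

    Expected columns (1-based): 1 protein id, 2 md5, 3 length, 4 analysis,
    5 signature accession, 6 signature description, 7 start, 8 stop,
    9 score, 10 status, 11 date, then optionally 12 InterPro accession,
    13 InterPro description, 14 GO, 15 pathways.  ``-`` marks absence.
    Column 5 always enters the accession set; column 12 when present.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    annotations: AnnotationMap = {}
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 11:
                raise AnnotationError(
                    f"{path}, line {lineno}: expected >= 11 tab-separated "
                    f"columns, got {len(cells)}"
                )
            protein_id = cells[0].strip()
            signature_acc = cells[4].strip()
            try:
                start = int(cells[6])
                stop = int(cells[7])
            except ValueError:
                raise AnnotationError(
                    f"{path}, line {lineno}: non-numeric start/stop "
                    f"{cells[6]!r}/{cells[7]!r}"
                ) from None
            score_cell = cells[8].strip()
            score = None
            if score_cell and score_cell != "-":
                try:
                    score = float(score_cell)
                except ValueError:
                    score = None  # some analyses emit non-numeric status here
            interpro_acc = None
            if len(cells) >= 12:
                cell = cells[11].strip()
                if cell and cell != "-":
                    interpro_acc = cell
            try:
                hit = DomainHit(protein_id, signature_acc, interpro_acc, start, stop, score)
            except ValueError as exc:
                raise AnnotationError(f"{path}, line {lineno}: {exc}") from exc
            _add(annotations, hit)
            n_rows += 1
    if n_rows == 0:
        raise AnnotationError(f"{path}: empty annotation file")
    return annotations


def parse_domain_table(path: Union[str, Path]) -> AnnotationMap:
    """Parse the simplified two-column ``protein_id <TAB> accession`` table.

    ``#`` comment lines are allowed; duplicate rows are idempotent (set
    semantics).  An empty file yields an empty map with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    annotations: AnnotationMap = {}
    seen: set[tuple[str, str]] = set()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2 or not cells[0].strip() or not cells[1].strip():
                raise AnnotationError(
                    f"{path}, line {lineno}: expected 'protein_id<TAB>accession'"
                )
            protein_id, accession = cells[0].strip(), cells[1].strip()
            n_rows += 1
            key = (protein_id, accession.upper())
            if key in seen:
                continue
            seen.add(key)
            _add(annotations, DomainHit(protein_id, accession))
    if n_rows == 0:
        logger.warning("%s: empty domain table", path)
    return annotations


def run_external_scanner(
    fasta_path: Union[str, Path],
    command_template: str,
    workdir: Union[str, Path],
    timeout: Optional[float] = None,
) -> Path:
    """Run a configured external domain scanner and return its TSV output path.

    *command_template* must contain ``{input}`` and ``{output}`` placeholders;
    the produced file must be in the InterProScan TSV dialect.  Nonzero exit,
    a missing output file or a timeout raise :class:`ScannerError` (captured
    stderr is attached).
    """
    if "{input}" not in command_template or "{output}" not in command_template:
        raise ScannerError(
            "command template must contain {input} and {output} placeholders"
        )
    fasta_path = Path(fasta_path)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    output_path = workdir / (fasta_path.stem + ".domains.tsv")
    command = command_template.format(input=str(fasta_path), output=str(output_path))
    argv = shlex.split(command)
    try:
        proc = subprocess.run(
            argv, capture_output=True, text=True, timeout=timeout, check=False
        )
    except FileNotFoundError as exc:
        raise ScannerError(f"scanner executable not found: {argv[0]!r}") from exc
    except subprocess.TimeoutExpired as exc:
        raise ScannerError(
            f"scanner timed out after {timeout}s", stderr=str(exc.stderr or "")
        ) from exc
    if proc.returncode != 0:
        raise ScannerError(
            f"scanner exited with status {proc.returncode}", stderr=proc.stderr
        )
    if not output_path.exists():
        raise ScannerError(
            f"scanner exited 0 but produced no output file {output_path}",
            stderr=proc.stderr,
        )
    return output_path
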