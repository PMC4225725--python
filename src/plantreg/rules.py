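"""Family prediction logics: the must-have / prohibited rule language.

Each TF/TR/CR family is described by a boolean *must-have* expression over
domain accessions (InterPro ``IPRxxxxxx`` entries or member-database
signatures such as PFAM ``PFxxxxx``, PROSITE ``PSxxxxx``, SMART ``SMxxxxx``)
and an optional *prohibited* expression in the same language.  A protein is
a candidate for a family when its observed accession set satisfies the
must-have expression; satisfaction of the prohibited expression vetoes the
assignment.  Prohibitions are what split superfamilies that share a core
domain: the K-box accession in the prohibited pattern of MADS type1 keeps
MIKC-type MADS proteins out of the type1 family.

Grammar (``&`` binds tighter than ``|``; whitespace ignored)::

    expr   := term ('|' term)*
    term   := factor ('&' factor)*
    factor := ACCESSION | '(' expr ')'
    ACCESSION := [A-Za-z]{2,4}[0-9]{4,7}

Accessions are compared case-insensitively.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from plantreg.errors import RuleSyntaxError, RuleTableError

ACCESSION_RE = re.compile(r"[A-Za-z]{2,4}[0-9]{4,7}\Z")

CATEGORIES = ("TF", "TR", "CR", "Other")

RULE_TABLE_COLUMNS = ("family", "category", "must_have", "prohibited")


def is_accession(token: str) -> bool:
    """True if *token* is a well-formed domain accession (e.g. IPR003340, PS50097)."""
    return bool(ACCESSION_RE.match(token))


# --------------------------------------------------------------------------
# Expression AST
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single domain accession; satisfied by set membership (case-insensitive)."""

    token: str

    def __post_init__(self):
        if not is_accession(self.token):
            raise ValueError(f"illegal accession token: {self.token!r}")


@dataclass(frozen=True)
class And:
    """Conjunction: all children must be satisfied."""

    children: tuple["Expr", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND node requires >= 2 children")


@dataclass(frozen=True)
class Or:
    """Disjunction: at least one child must be satisfied."""

    children: tuple["Expr", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR node requires >= 2 children")


Expr = Union[Atom, And, Or]


def atoms(expr: Expr) -> frozenset[str]:
    """The set of accession tokens appearing in *expr* (original case)."""
    if isinstance(expr, Atom):
        return frozenset((expr.token,))
    out: set[str] = set()
    for child in expr.children:
        out |= atoms(child)
    return frozenset(out)


def evaluate(expr: Expr, accessions: Iterable[str]) -> bool:
    """Evaluate *expr* against a protein's accession set.

    Atoms test membership case-insensitively; AND requires all children,
    OR any child.  Pure function of its arguments; an empty accession set
    never satisfies any expression (there is no negation in the language).
    """
    if not isinstance(accessions, (set, frozenset)):
        accessions = set(accessions)
    normalized = {a.upper() for a in accessions}
    return _eval(expr, normalized)


def _eval(expr: Expr, upper: set[str]) -> bool:
    if isinstance(expr, Atom):
        return expr.token.upper() in upper
    if isinstance(expr, And):
        return all(_eval(c, upper) for c in expr.children)
    return any(_eval(c, upper) for c in expr.children)


def serialize(expr: Expr) -> str:
    """Render *expr* in the rule language, fully parenthesized below the root."""
    return _ser(expr, top=True)


def _ser(expr: Expr, top: bool = False) -> str:
    if isinstance(expr, Atom):
        return expr.token
    op = "&" if isinstance(expr, And) else "|"
    body = op.join(_ser(c) for c in expr.children)
    return body if top else f"({body})"


# --------------------------------------------------------------------------
# Parser (recursive descent over a token stream with offsets)
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[&|()]|\S")


class _Tokens:
    def __init__(self, text: str):
        self.items: list[tuple[str, int]] = []  # (lexeme, offset)
        for m in _TOKEN_RE.finditer(text):
            self.items.append((m.group(), m.start()))
        self.pos = 0
        self.end_offset = len(text)

    def peek(self) -> Optional[tuple[str, int]]:
        return self.items[self.pos] if self.pos < len(self.items) else None

    def next(self) -> Optional[tuple[str, int]]:
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok


def parse_expression(text: str) -> Expr:
    """Parse a rule-language string into an expression AST.

    Raises :class:`RuleSyntaxError` with the character offset of the fault
    for unbalanced parentheses, dangling operators, empty parentheses and
    illegal accession tokens.

    >>> serialize(parse_expression("(IPR010525|IPR011525)&IPR003340"))
    '(IPR010525|IPR011525)&IPR003340'
    """
    if text is None or not text.strip():
        raise RuleSyntaxError("empty expression", 0)
    toks = _Tokens(text)
    expr = _parse_or(toks)
    trailing = toks.peek()
    if trailing is not None:
        raise RuleSyntaxError(f"unexpected token {trailing[0]!r}", trailing[1])
    return expr


def _parse_or(toks: _Tokens) -> Expr:
    terms = [_parse_and(toks)]
    while True:
        tok = toks.peek()
        if tok is not None and tok[0] == "|":
            toks.next()
            terms.append(_parse_and(toks))
        else:
            break
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


def _parse_and(toks: _Tokens) -> Expr:
    factors = [_parse_factor(toks)]
    while True:
        tok = toks.peek()
        if tok is not None and tok[0] == "&":
            toks.next()
            factors.append(_parse_factor(toks))
        else:
            break
    return factors[0] if len(factors) == 1 else And(tuple(factors))


def _parse_factor(toks: _Tokens) -> Expr:
    tok = toks.next()
    if tok is None:
        raise RuleSyntaxError("dangling operator or empty expression", toks.end_offset)
    lexeme, offset = tok
    if lexeme == "(":
        inner = toks.peek()
        if inner is not None and inner[0] == ")":
            raise RuleSyntaxError("empty parentheses", inner[1])
        expr = _parse_or(toks)
        closing = toks.next()
        if closing is None or closing[0] != ")":
            raise RuleSyntaxError(
                "unbalanced parentheses",
                closing[1] if closing else toks.end_offset,
            )
        return expr
    if lexeme in ")&|":
        raise RuleSyntaxError(f"unexpected token {lexeme!r}", offset)
    if not is_accession(lexeme):
        raise RuleSyntaxError(f"illegal accession token {lexeme!r}", offset)
    return Atom(lexeme)


# --------------------------------------------------------------------------
# Rule tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyRule:
    """One family's prediction logic."""

    family_name: str
    category: str
    must_have: Expr
    prohibited: Optional[Expr] = None

    def __post_init__(self):
        if not self.family_name or not self.family_name.strip():
            raise ValueError("family_name must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )

    def accepts(self, accessions: Iterable[str]) -> bool:
        """must-have satisfied and prohibited (if any) not satisfied."""
        if not isinstance(accessions, (set, frozenset)):
            accessions = set(accessions)
        if not evaluate(self.must_have, accessions):
            return False
        return self.prohibited is None or not evaluate(self.prohibited, accessions)


@dataclass
class RuleTable:
    """Ordered collection of family rules; family names unique (case-insensitive)."""

    rules: list[FamilyRule] = field(default_factory=list)
    provenance: str = "builtin"

    def __post_init__(self):
        seen: set[str] = set()
        for rule in self.rules:
            key = rule.family_name.lower()
            if key in seen:
                raise RuleTableError(f"duplicate family name: {rule.family_name!r}")
            seen.add(key)

    def __iter__(self) -> Iterator[FamilyRule]:
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def get(self, family_name: str) -> Optional[FamilyRule]:
        key = family_name.lower()
        for rule in self.rules:
            if rule.family_name.lower() == key:
                return rule
        return None

    @property
    def family_names(self) -> list[str]:
        return [r.family_name for r in self.rules]


def _parse_rule_lines(lines: Iterable[str], provenance: str) -> RuleTable:
    rules: list[FamilyRule] = []
    seen: set[str] = set()
    header: Optional[list[str]] = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip().lower() for c in cells]
            missing = [c for c in RULE_TABLE_COLUMNS if c not in header]
            if missing:
                raise RuleTableError(
                    f"{provenance}: missing column(s) {missing} in header {header}"
                )
            continue
        row = dict(zip(header, cells + [""] * (len(header) - len(cells))))
        family = row["family"].strip()
        if not family:
            raise RuleTableError(f"{provenance}, line {lineno}: empty family name")
        if family.lower() in seen:
            raise RuleTableError(
                f"{provenance}, line {lineno}: duplicate family {family!r}"
            )
        category = row["category"].strip()
        try:
            must = parse_expression(row["must_have"])
        except RuleSyntaxError as exc:
            raise RuleTableError(
                f"{provenance}, line {lineno}, family {family!r}: "
                f"bad must_have expression: {exc}"
            ) from exc
        prohibited_cell = row.get("prohibited", "").strip()
        prohibited: Optional[Expr] = None
        if prohibited_cell and prohibited_cell != "-":
            try:
                prohibited = parse_expression(prohibited_cell)
            except RuleSyntaxError as exc:
                raise RuleTableError(
                    f"{provenance}, line {lineno}, family {family!r}: "
                    f"bad prohibited expression: {exc}"
                ) from exc
        try:
            rule = FamilyRule(family, category, must, prohibited)
        except ValueError as exc:
            raise RuleTableError(
                f"{provenance}, line {lineno}, family {family!r}: {exc}"
            ) from exc
        rules.append(rule)
        seen.add(family.lower())
    if header is None:
        raise RuleTableError(f"{provenance}: empty rule table")
    return RuleTable(rules=rules, provenance=provenance)


def load_rule_table(path: Union[str, Path]) -> RuleTable:
    """Load a 4-column TSV rule table (header: family/category/must_have/prohibited).

    ``#`` comment lines are ignored; an empty or ``-`` prohibited cell means
    the family has no prohibition.  Raises :class:`RuleTableError` naming the
    family and line for any unparseable expression or duplicate family.
    """
    path = Path(path)
    if not path.exists():
        raise RuleTableError(f"rule table not found: {path}")
    with open(path, encoding="utf-8") as fh:
        return _parse_rule_lines(fh, provenance=str(path))


def builtin_rule_table() -> RuleTable:
    """The starter rule table shipped with the package.

    Contains the MADS type1 / MADS-MICK pair, the ARF logic, the
    B3 / AP2-EREBP / RAV superfamily split and BTB-POZ scaffold rules.
    See the table file's comments for curation status of each row.
    """
    text = resources.files("plantreg.data").joinpath("builtin_rules.tsv").read_text(
        encoding="utf-8"
    )
    return _parse_rule_lines(text.splitlines(), provenance="builtin")


def write_rule_table(table: RuleTable, path: Union[str, Path]) -> None:
    """Serialize a rule table to the 4-column TSV format ``load_rule_table`` reads."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RULE_TABLE_COLUMNS) + "\n")
        for rule in table:
            prohibited = serialize(rule.prohibited) if rule.prohibited is not None else "-"
            fh.write(
                f"{rule.family_name}\t{rule.category}\t"
                f"{serialize(rule.must_have)}\t{prohibited}\n"
            )


# --------------------------------------------------------------------------
# Validation diagnostics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    """A validation finding; ``kind`` is ``subset_overlap`` or ``orphan_prohibition``."""

    kind: str
    message: str
    families: tuple[str, ...] = ()


def validate_rule_table(table: RuleTable) -> list[Diagnostic]:
    """Lint a rule table for patterns that cause systematic mis-assignment.

    Warns when (a) one family's must-have atom set is a subset of another's
    and no prohibited atom of the first intersects the second's atoms — any
    protein of the second family then also satisfies the first (the
    superfamily-splitting situation the prohibited pattern exists to fix);
    and (b) an accession occurs in a prohibited pattern but in no must-have
    pattern of any family, which usually indicates a typo.
    """
    diags: list[Diagnostic] = []
    atom_sets = {
        r.family_name: frozenset(a.upper() for a in atoms(r.must_have))
        for r in table
    }
    for a in table:
        a_atoms = atom_sets[a.family_name]
        a_prohib = (
            frozenset(x.upper() for x in atoms(a.prohibited))
            if a.prohibited is not None
            else frozenset()
        )
        for b in table:
            if a.family_name == b.family_name:
                continue
            b_atoms = atom_sets[b.family_name]
            if a_atoms <= b_atoms and not (a_prohib & b_atoms):
                diags.append(
                    Diagnostic(
                        kind="subset_overlap",
                        message=(
                            f"must-have atoms of {a.family_name!r} are a subset of "
                            f"{b.family_name!r}'s with no distinguishing prohibited "
                            f"pattern; proteins of {b.family_name!r} may be "
                            f"double-assigned to {a.family_name!r}"
                        ),
                        families=(a.family_name, b.family_name),
                    )
                )
    all_must = frozenset().union(*atom_sets.values()) if atom_sets else frozenset()
    for r in table:
        if r.prohibited is None:
            continue
        for tok in sorted(atoms(r.prohibited)):
            if tok.upper() not in all_must:
                diags.append(
                    Diagnostic(
                        kind="orphan_prohibition",
                        message=(
                            f"accession {tok} appears in the prohibited pattern of "
                            f"{r.family_name!r} but in no family's must-have pattern"
                        ),
                        families=(r.family_name,),
                    )
                )
    return diags
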