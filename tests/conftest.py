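"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random
from itertools import chain, combinations

import pytest

from plantreg.rules import And, Atom, Or, builtin_rule_table


# ---------------------------------------------------------------------------
# Independent brute-force oracle for the rule language
# ---------------------------------------------------------------------------

def oracle_eval(expr, accession_set):
    """Reference evaluator, written from the recursive definition only.

    Deliberately independent of plantreg.rules.evaluate: different
    normalisation path, explicit recursion, no shared helpers.
    """
    normalized = frozenset(a.lower() for a in accession_set)
    if isinstance(expr, Atom):
        return expr.token.lower() in normalized
    if isinstance(expr, And):
        for child in expr.children:
            if not oracle_eval(child, accession_set):
                return False
        return True
    if isinstance(expr, Or):
        for child in expr.children:
            if oracle_eval(child, accession_set):
                return True
        return False
    raise TypeError(f"unknown node {expr!r}")


def all_subsets(items):
    items = sorted(items)
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def random_test_expr(rng: random.Random, n_atoms: int):
    """Random expression with *n_atoms* distinct atoms (test-local generator)."""
    tokens = [f"QQ{1000 + i:05d}" for i in range(n_atoms)]
    rng.shuffle(tokens)

    def build(leaves):
        if len(leaves) == 1:
            return Atom(leaves[0])
        split = rng.randint(1, len(leaves) - 1)
        left, right = leaves[:split], leaves[split:]
        node = rng.choice((And, Or))
        return node((build(left), build(right)))

    return build(tokens)


@pytest.fixture(scope="session")
def builtin_rules():
    return builtin_rule_table()
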