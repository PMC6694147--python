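"""Boolean gene-protein-reaction (GPR) rules.

A GPR expression links a reaction to the genes whose products catalyse it:
AND nodes represent enzyme complexes (every subunit required), OR nodes
represent isoenzymes (any one suffices).  A reaction with no rule
(``None``) is spontaneous and never affected by gene knockouts.  A rule
that can no longer be satisfied after genes have been removed from the
model is represented by the :data:`UNSATISFIABLE` sentinel.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "And",
    "Or",
    "GprExpression",
    "GprError",
    "UNSATISFIABLE",
    "parse_gpr",
    "gpr_genes",
    "evaluate_gpr",
    "remove_genes",
    "gpr_to_string",
]


class GprError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


class _Unsatisfiable:
    """Sentinel for a rule falsified by gene removal (always evaluates False)."""

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return "UNSATISFIABLE"


UNSATISFIABLE = _Unsatisfiable()

#: A GPR is a tree of Gene/And/Or nodes, ``None`` (spontaneous) or UNSATISFIABLE.
GprExpression = Union[Gene, And, Or, _Unsatisfiable, None]

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: Optional[str], *, known_genes: Optional[set] = None) -> GprExpression:
    """Parse a rule string such as ``"(g1 and g2) or g3"`` into a tree.

    ``and``/``or`` are case-insensitive.  Any other token is taken to be a
    gene identifier; tokens not in ``known_genes`` (when given) are accepted
    with a warning, mirroring the tolerant behaviour needed for real
    genome-scale models whose gene lists are not always complete.
    """
    if text is None:
        return None
    tokens = _TOKEN.findall(text)
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprExpression:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            advance()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> GprExpression:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            advance()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def parse_atom() -> GprExpression:
        tok = peek()
        if tok is None:
            raise GprError(f"unexpected end of GPR string: {text!r}")
        if tok == "(":
            advance()
            inner = parse_or()
            if peek() != ")":
                raise GprError(f"unbalanced parenthesis in GPR string: {text!r}")
            advance()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprError(f"malformed GPR string near {tok!r}: {text!r}")
        advance()
        if known_genes is not None and tok not in known_genes:
            logger.warning("GPR token %r not in model gene list; treating as a gene id", tok)
        return Gene(tok)

    expr = parse_or()
    if pos != len(tokens):
        raise GprError(f"trailing tokens in GPR string: {text!r}")
    return expr


def gpr_genes(expr: GprExpression) -> frozenset:
    """All gene ids appearing in the rule."""
    if expr is None or expr is UNSATISFIABLE:
        return frozenset()
    if isinstance(expr, Gene):
        return frozenset({expr.name})
    out = set()
    for child in expr.children:
        out |= gpr_genes(child)
    return frozenset(out)


def evaluate_gpr(expr: GprExpression, absent: Iterable[str] = ()) -> bool:
    """Evaluate the rule with the given genes knocked out (absent).

    A spontaneous reaction (``None``) always evaluates True; an
    unsatisfiable rule always evaluates False.
    """
    absent = set(absent)
    if expr is None:
        return True
    if expr is UNSATISFIABLE:
        return False
    if isinstance(expr, Gene):
        return expr.name not in absent
    if isinstance(expr, And):
        return all(evaluate_gpr(c, absent) for c in expr.children)
    if isinstance(expr, Or):
        return any(evaluate_gpr(c, absent) for c in expr.children)
    raise TypeError(f"not a GPR node: {expr!r}")


def remove_genes(expr: GprExpression, genes: Iterable[str]) -> GprExpression:
    """Partially evaluate the rule with ``genes`` absent and simplify.

    Returns the simplified tree, or :data:`UNSATISFIABLE` if no gene
    assignment over the remaining genes can satisfy the rule.
    """
    genes = set(genes)
    if expr is None:
        return None
    if expr is UNSATISFIABLE:
        return UNSATISFIABLE
    if isinstance(expr, Gene):
        return UNSATISFIABLE if expr.name in genes else expr
    simplified = [remove_genes(c, genes) for c in expr.children]
    if isinstance(expr, And):
        if any(c is UNSATISFIABLE for c in simplified):
            return UNSATISFIABLE
        kept = tuple(simplified)
        return kept[0] if len(kept) == 1 else And(kept)
    kept = tuple(c for c in simplified if c is not UNSATISFIABLE)
    if not kept:
        return UNSATISFIABLE
    return kept[0] if len(kept) == 1 else Or(kept)


def gpr_to_string(expr: GprExpression) -> str:
    """Render a tree back to ``and``/``or`` notation (empty string if spontaneous)."""
    if expr is None:
        return ""
    if expr is UNSATISFIABLE:
        raise ValueError("an unsatisfiable GPR has no string form")
    if isinstance(expr, Gene):
        return expr.name

    def render(node: GprExpression, parent_is_and: bool) -> str:
        if isinstance(node, Gene):
            return node.name
        op = " and " if isinstance(node, And) else " or "
        inner = op.join(render(c, isinstance(node, And)) for c in node.children)
        if isinstance(node, Or) and parent_is_and:
            return f"({inner})"
        return inner

    return render(expr, False)
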