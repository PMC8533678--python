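"""Gene-protein-reaction (GPR) rule handling.

A GPR rule is a boolean combination of gene identifiers, e.g.
``(b0001 and b0002) or b0003``, where AND conventionally denotes an enzyme
complex (all subunits required) and OR denotes isozymes (any one suffices).
Parsing is delegated to cobrapy's grammar; the resulting tree is converted to
a minimal immutable AST so that rules can be *evaluated numerically* with
configurable semantics: a real value per gene (here: an expression ratio) is
propagated through the tree, AND nodes combined with ``and_rule`` and OR
nodes with ``or_rule`` (``min``, ``max`` or ``mean``).
"""

from __future__ import annotations

import ast as _pyast
from dataclasses import dataclass
from statistics import fmean
from typing import Mapping

from cobra.core.gene import GPR as _CobraGPR

from .errors import FormatError

__all__ = ["GprNode", "GeneRef", "BoolOp", "parse_gpr", "evaluate_gpr", "gpr_genes"]

_RULES = {"min": min, "max": max, "mean": fmean}


@dataclass(frozen=True)
class GeneRef:
    """Leaf node: a single gene identifier."""

    gene: str


@dataclass(frozen=True)
class BoolOp:
    """Internal node: ``op`` is ``"and"`` or ``"or"``; two or more children."""

    op: str
    children: tuple["GprNode", ...]


GprNode = GeneRef | BoolOp


def parse_gpr(rule: str) -> GprNode | None:
    """Parse a GPR rule string into an AST; empty/blank rules give ``None``."""
    if rule is None or not rule.strip():
        return None
    try:
        body = _CobraGPR.from_string(rule).body
    except (SyntaxError, TypeError) as exc:  # pragma: no cover - cobra raises variously
        raise FormatError(f"malformed GPR rule {rule!r}: {exc}") from exc
    if body is None:
        raise FormatError(f"malformed GPR rule {rule!r}")
    return _convert(body)


def _convert(node: _pyast.AST) -> GprNode:
    if isinstance(node, _pyast.Name):
        return GeneRef(node.id)
    if isinstance(node, _pyast.BoolOp):
        op = "and" if isinstance(node.op, _pyast.And) else "or"
        return BoolOp(op, tuple(_convert(v) for v in node.values))
    raise FormatError(f"unsupported GPR syntax node: {type(node).__name__}")


def gpr_genes(node: GprNode | None) -> frozenset[str]:
    """All gene identifiers referenced by the rule."""
    if node is None:
        return frozenset()
    if isinstance(node, GeneRef):
        return frozenset([node.gene])
    return frozenset().union(*(gpr_genes(c) for c in node.children))


def evaluate_gpr(
    node: GprNode | None,
    gene_values: Mapping[str, float],
    and_rule: str = "min",
    or_rule: str = "max",
    neutral: float = 1.0,
) -> float | None:
    """Combine per-gene values through the GPR tree.

    Genes absent from ``gene_values`` contribute the ``neutral`` value (by
    default 1, i.e. "unchanged expression"). An empty rule is undefined and
    returns ``None``.
    """
    for name, rule in (("and_rule", and_rule), ("or_rule", or_rule)):
        if rule not in _RULES:
            raise FormatError(f"{name} must be one of {sorted(_RULES)}, got {rule!r}")
    if node is None:
        return None
    return _eval(node, gene_values, _RULES[and_rule], _RULES[or_rule], neutral)


def _eval(node, values, and_fn, or_fn, neutral):
    if isinstance(node, GeneRef):
        return float(values.get(node.gene, neutral))
    if isinstance(node, BoolOp):
        vals = [_eval(c, values, and_fn, or_fn, neutral) for c in node.children]
        return float((and_fn if node.op == "and" else or_fn)(vals))
    raise FormatError(f"malformed GPR AST node: {node!r}")


def unparse_gpr(node: GprNode | None) -> str:
    """Render the AST back to a rule string (parenthesized, canonical)."""
    if node is None:
        return ""
    if isinstance(node, GeneRef):
        return node.gene
    sep = f" {node.op} "
    parts = []
    for child in node.children:
        text = unparse_gpr(child)
        if isinstance(child, BoolOp):
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)
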