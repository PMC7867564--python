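"""Gene–protein–reaction (GPR) boolean rules.

A GPR rule states which gene products a reaction needs: ``and`` means a
complex (all subunits required), ``or`` means isozymes (any suffices).
The grammar is deliberately small: identifiers, ``and``, ``or`` and
parentheses, with ``or`` binding looser than ``and``.  An empty rule
denotes a spontaneous (gene-independent) reaction.

Rules are parsed into immutable nested tuples::

    ("lit", "gA")
    ("and", (("lit", "gA"), ("lit", "gB")))
    ("or",  (("lit", "gA"), ("and", (("lit", "gB"), ("lit", "gC")))))
"""

from __future__ import annotations

import re
from typing import FrozenSet, Optional, Tuple

GprNode = Tuple  # ("lit", gene) | ("and", (nodes...)) | ("or", (nodes...))

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class GprError(ValueError):
    """Raised for a malformed GPR expression or rule tree."""


def parse_gpr(text: Optional[str]) -> Optional[GprNode]:
    """Parse a GPR string into a rule tree; empty/None means spontaneous."""
    if text is None or not text.strip():
        return None
    tokens = _TOKEN.findall(text)
    node, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise GprError(f"trailing tokens in GPR {text!r}: {tokens[pos:]}")
    return node


def _parse_or(tokens, pos):
    node, pos = _parse_and(tokens, pos)
    terms = [node]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        node, pos = _parse_and(tokens, pos + 1)
        terms.append(node)
    return (terms[0] if len(terms) == 1 else ("or", tuple(terms))), pos


def _parse_and(tokens, pos):
    node, pos = _parse_atom(tokens, pos)
    terms = [node]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        node, pos = _parse_atom(tokens, pos + 1)
        terms.append(node)
    return (terms[0] if len(terms) == 1 else ("and", tuple(terms))), pos


def _parse_atom(tokens, pos):
    if pos >= len(tokens):
        raise GprError("unexpected end of GPR expression")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GprError("unbalanced parentheses in GPR expression")
        return node, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GprError(f"unexpected token {tok!r} in GPR expression")
    return ("lit", tok), pos + 1


def evaluate_gpr(rule: Optional[GprNode], present: FrozenSet[str]) -> bool:
    """Evaluate a rule tree against a set of available genes.

    A literal is true iff its gene is present; ``and``/``or`` follow
    boolean semantics; an empty (``None``) rule is always true.
    """
    if rule is None:
        return True
    op = rule[0] if isinstance(rule, tuple) and len(rule) == 2 else None
    if op == "lit":
        return rule[1] in present
    if op == "and":
        return all(evaluate_gpr(c, present) for c in rule[1])
    if op == "or":
        return any(evaluate_gpr(c, present) for c in rule[1])
    raise GprError(f"malformed GPR node: {rule!r}")


def gpr_genes(rule: Optional[GprNode]) -> FrozenSet[str]:
    """All gene identifiers mentioned by a rule."""
    if rule is None:
        return frozenset()
    op = rule[0] if isinstance(rule, tuple) and len(rule) == 2 else None
    if op == "lit":
        return frozenset((rule[1],))
    if op in ("and", "or"):
        out = frozenset()
        for c in rule[1]:
            out |= gpr_genes(c)
        return out
    raise GprError(f"malformed GPR node: {rule!r}")


def format_gpr(rule: Optional[GprNode]) -> str:
    """Render a rule tree back to the string grammar."""
    if rule is None:
        return ""
    op = rule[0]
    if op == "lit":
        return rule[1]
    joiner = f" {op} "
    parts = []
    for c in rule[1]:
        s = format_gpr(c)
        if c[0] != "lit" and c[0] != op:
            s = f"({s})"
        parts.append(s)
    return joiner.join(parts)
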