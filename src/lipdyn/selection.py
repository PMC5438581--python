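"""A small atom-selection expression language.

Grammar (whitespace-insensitive, case-insensitive keywords)::

    expr    := or_expr
    or_expr := and_expr ("or" and_expr)*
    and_expr:= not_expr ("and" not_expr)*
    not_expr:= "not" not_expr | "(" expr ")" | term
    term    := "resid" N[:M] | "resname" X | "name" X | "element" X
             | "category" X | "chain" X

Examples: ``resid 175:230 and name CA``, ``category protein and not name CA``.
"""

from __future__ import annotations

import re

import numpy as np

from .core import Selection, Structure
from .errors import SelectionSyntaxError

_TOKEN_RE = re.compile(r"\s*([()]|[^\s()]+)")

_FIELDS = {"resid", "resname", "name", "element", "category", "chain"}


class _Tokenizer:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m:
                break
            self.tokens.append((m.group(1), m.start(1)))
            pos = m.end()
        self.i = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok


def _parse_term(tz: _Tokenizer):
    tok, pos = tz.next()
    low = tok.lower()
    if low == "(":
        node = _parse_or(tz)
        closing = tz.peek()
        if closing is None or closing[0] != ")":
            raise SelectionSyntaxError("expected ')'", pos)
        tz.next()
        return node
    if low == "not":
        inner = _parse_term(tz)
        return ("not", inner)
    if low in _FIELDS:
        val_tok = tz.peek()
        if val_tok is None or val_tok[0].lower() in _FIELDS | {"and", "or", "not", "(", ")"}:
            raise SelectionSyntaxError(f"field {tok!r} needs a value", pos)
        value, vpos = tz.next()
        if low == "resid":
            m = re.fullmatch(r"(-?\d+)(?::(-?\d+))?", value)
            if not m:
                raise SelectionSyntaxError(f"bad resid value {value!r}", vpos)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            return ("resid", lo, hi)
        return (low, value.upper())
    raise SelectionSyntaxError(f"unexpected token {tok!r}", pos)


def _parse_and(tz: _Tokenizer):
    node = _parse_term(tz)
    while True:
        tok = tz.peek()
        if tok is None or tok[0].lower() != "and":
            return node
        tz.next()
        node = ("and", node, _parse_term(tz))


def _parse_or(tz: _Tokenizer):
    node = _parse_and(tz)
    while True:
        tok = tz.peek()
        if tok is None or tok[0].lower() != "or":
            return node
        tz.next()
        node = ("or", node, _parse_and(tz))


def _parse(expr: str):
    tz = _Tokenizer(expr)
    if tz.peek() is None:
        raise SelectionSyntaxError("empty expression", 0)
    node = _parse_or(tz)
    trailing = tz.peek()
    if trailing is not None:
        raise SelectionSyntaxError(f"unexpected token {trailing[0]!r}", trailing[1])
    return node


def _evaluate(node, structure: Structure) -> np.ndarray:
    op = node[0]
    atoms = structure.atoms
    if op == "and":
        return _evaluate(node[1], structure) & _evaluate(node[2], structure)
    if op == "or":
        return _evaluate(node[1], structure) | _evaluate(node[2], structure)
    if op == "not":
        return ~_evaluate(node[1], structure)
    if op == "resid":
        lo, hi = node[1], node[2]
        return np.array([lo <= a.resid <= hi for a in atoms])
    field = op
    value = node[1]
    if field == "resname":
        return np.array([a.resname.upper() == value for a in atoms])
    if field == "name":
        return np.array([a.name.upper() == value for a in atoms])
    if field == "element":
        return np.array([a.element.upper() == value for a in atoms])
    if field == "category":
        return np.array([a.category.upper() == value for a in atoms])
    if field == "chain":
        return np.array([a.chain.upper() == value for a in atoms])
    raise AssertionError(f"unknown node {node!r}")


def select(structure: Structure, expr: str) -> Selection:
    """Evaluate a selection expression; returns ordered atom indices.

    Empty selections are legal and returned as an empty Selection.
    """
    mask = _evaluate(_parse(expr), structure)
    return Selection.from_indices(np.flatnonzero(mask), n_atoms=len(structure.atoms))
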