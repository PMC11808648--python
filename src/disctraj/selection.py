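"""Atom-selection mini-language.

Grammar (lowest to highest precedence)::

    expr     := and_expr ("or" and_expr)*
    and_expr := not_expr ("and" not_expr)*
    not_expr := "not" not_expr | primary
    primary  := "(" expr ")" | keyword

Keywords: ``resid <id|a-b> ...``, ``resname <NAME> ...``, ``name <NAME> ...``,
``chain <ID> ...``, ``element <SYM> ...``, ``segment <class>``, plus the
bare words ``protein``, ``lipid``, ``scaffold``, ``solvent``, ``ion``,
``water``, ``backbone``, ``hydrogen``, ``all``, ``none``.

Selections evaluate to sorted, duplicate-free 0-based index arrays; named
groups from the literature (e.g. the C1 domain, ``resid 2021-2170 and
protein``) are expressed directly.
"""

from __future__ import annotations

import re
from typing import List, Tuple

import numpy as np

from .model import SelectionSyntaxError, Topology

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")

_KEYWORDS = {"and", "or", "not", "resid", "resname", "name", "chain",
             "element", "segment", "protein", "lipid", "scaffold", "solvent",
             "ion", "water", "backbone", "hydrogen", "all", "none", "(", ")"}

BACKBONE_NAMES = ("N", "CA", "C", "O")


def _tokenize(expr: str) -> List[Tuple[str, int]]:
    tokens = []
    for m in _TOKEN_RE.finditer(expr):
        tokens.append((m.group(0), m.start()))
    if not tokens:
        raise SelectionSyntaxError("empty selection expression", 0)
    return tokens


class _Parser:
    def __init__(self, expr: str, topology: Topology):
        self.expr = expr
        self.topo = topology
        self.tokens = _tokenize(expr)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def advance(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionSyntaxError(f"unexpected token {tok!r}", at)
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek()[0] == "or":
            self.advance()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek()[0] == "and":
            self.advance()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        tok, _ = self.peek()
        if tok == "not":
            self.advance()
            return ~self.parse_not()
        return self.parse_primary()

    def _value_list(self) -> List[str]:
        """Greedily collect value tokens until a keyword/paren/end."""
        values = []
        while True:
            tok, at = self.peek()
            if tok is None or tok.lower() in _KEYWORDS:
                break
            values.append(self.advance()[0])
        return values

    def parse_primary(self) -> np.ndarray:
        tok, at = self.advance()
        t = self.topo
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", at)
        low = tok.lower()
        if tok == "(":
            mask = self.parse_or()
            closer, cat = self.advance()
            if closer != ")":
                raise SelectionSyntaxError("expected ')'", cat)
            return mask
        if low == "all":
            return np.ones(t.n_atoms, dtype=bool)
        if low == "none":
            return np.zeros(t.n_atoms, dtype=bool)
        if low in ("protein", "lipid", "scaffold", "solvent", "ion"):
            return t.segment_classes == low
        if low == "water":
            return t.segment_classes == "solvent"
        if low == "backbone":
            return (t.segment_classes == "protein") & np.isin(t.names, BACKBONE_NAMES)
        if low == "hydrogen":
            return t.elements == "H"
        if low == "resid":
            values = self._value_list()
            if not values:
                raise SelectionSyntaxError("'resid' needs at least one id or range", at)
            mask = np.zeros(t.n_atoms, dtype=bool)
            for v in values:
                m = _RANGE_RE.match(v)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    mask |= (t.residue_ids >= lo) & (t.residue_ids <= hi)
                elif v.isdigit():
                    mask |= t.residue_ids == int(v)
                else:
                    raise SelectionSyntaxError(f"bad residue id {v!r}", at)
            return mask
        if low in ("resname", "name", "chain", "element", "segment"):
            values = self._value_list()
            if not values:
                raise SelectionSyntaxError(f"{low!r} needs at least one value", at)
            field = {
                "resname": t.residue_names,
                "name": t.names,
                "chain": t.chain_ids,
                "element": t.elements,
                "segment": t.segment_classes,
            }[low]
            return np.isin(field, values)
        raise SelectionSyntaxError(f"unknown token {tok!r}", at)


def select(topology: Topology, expr: str) -> np.ndarray:
    """Evaluate a selection expression to a sorted unique index array."""
    mask = _Parser(expr, topology).parse()
    return np.flatnonzero(mask)
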