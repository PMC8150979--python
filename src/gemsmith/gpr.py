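"""Boolean gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers in which ``and`` denotes
subunits of an enzyme complex (all required) and ``or`` denotes isozymes or
alternative complexes (any suffices).  The grammar is the de-facto community
convention: case-insensitive ``and``/``or`` keywords, parentheses, ``and``
binding tighter than ``or``.  Gene identifiers are opaque, case-sensitive
strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = ["Gpr", "GprParseError", "parse_gpr"]


class GprParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class Gpr:
    """Node of a GPR boolean tree.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``.  Leaves carry the gene
    id in ``gene``; internal nodes carry >= 2 ``children``.
    """

    op: str
    gene: str | None = None
    children: tuple["Gpr", ...] = ()

    # -- constructors -------------------------------------------------
    @staticmethod
    def leaf(gene: str) -> "Gpr":
        return Gpr("gene", gene=gene)

    @staticmethod
    def and_(children: Iterable["Gpr"]) -> "Gpr":
        return _nary("and", children)

    @staticmethod
    def or_(children: Iterable["Gpr"]) -> "Gpr":
        return _nary("or", children)

    # -- queries ------------------------------------------------------
    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.gene])
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        """Truth value with genes in ``deleted`` set to FALSE, others TRUE."""
        if self.op == "gene":
            return self.gene not in deleted
        if self.op == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def substitute(self, mapping: dict[str, "Gpr | None"]) -> "Gpr | None":
        """Replace every leaf per ``mapping`` (missing keys keep the leaf).

        A ``None`` value means FALSE.  Returns the simplified tree, or
        ``None`` when the whole expression simplifies to FALSE.
        """
        if self.op == "gene":
            if self.gene in mapping:
                return mapping[self.gene]
            return self
        parts = [c.substitute(mapping) for c in self.children]
        if self.op == "and":
            if any(p is None for p in parts):
                return None
            return Gpr.and_([p for p in parts if p is not None])
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        return Gpr.or_(parts)

    def dnf(self, max_terms: int = 1024) -> list[frozenset[str]] | None:
        """Disjunctive normal form as a list of minimal gene sets.

        Returns ``None`` if expansion would exceed ``max_terms`` (guards
        pathological rules).  Absorbed (superset) terms are dropped.
        """
        terms = self._dnf_raw(max_terms)
        if terms is None:
            return None
        # drop terms that are supersets of another term
        terms = sorted(set(terms), key=lambda t: (len(t), sorted(t)))
        kept: list[frozenset[str]] = []
        for t in terms:
            if not any(k <= t for k in kept):
                kept.append(t)
        return kept

    def _dnf_raw(self, max_terms: int) -> list[frozenset[str]] | None:
        if self.op == "gene":
            return [frozenset([self.gene])]
        parts = [c._dnf_raw(max_terms) for c in self.children]
        if any(p is None for p in parts):
            return None
        if self.op == "or":
            out = [t for p in parts for t in p]
            return None if len(out) > max_terms else out
        # and: cartesian product of child terms
        out = [frozenset()]
        for p in parts:
            out = [a | b for a in out for b in p]
            if len(out) > max_terms:
                return None
        return out

    def has_alternatives(self, max_terms: int = 1024) -> bool:
        """True if >= 2 alternative gene sets can activate the reaction.

        Falls back to "any OR node exists" when DNF expansion is capped.
        """
        terms = self.dnf(max_terms)
        if terms is None:
            return self._has_or()
        return len(terms) >= 2

    def _has_or(self) -> bool:
        if self.op == "or":
            return True
        return any(c._has_or() for c in self.children)

    # -- rendering ----------------------------------------------------
    def to_string(self) -> str:
        return self._render(top=True)

    def _render(self, top: bool = False) -> str:
        if self.op == "gene":
            return self.gene
        joiner = f" {self.op} "
        inner = []
        for c in self.children:
            s = c._render()
            # parenthesize a looser-binding child ("or" under "and")
            if c.op == "or" and self.op == "and":
                s = f"({s})"
            inner.append(s)
        s = joiner.join(inner)
        return s if top else (f"({s})" if self.op == "or" else s)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _nary(op: str, children: Iterable[Gpr]) -> Gpr:
    """Flatten nested same-op nodes; collapse singletons."""
    flat: list[Gpr] = []
    for c in children:
        if c.op == op:
            flat.extend(c.children)
        else:
            flat.append(c)
    if not flat:
        raise GprParseError(f"empty {op!r} expression")
    if len(flat) == 1:
        return flat[0]
    return Gpr(op, children=tuple(flat))


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> Gpr | None:
    """Parse a GPR string; returns ``None`` for empty/whitespace input.

    ``and`` binds tighter than ``or``; both keywords are case-insensitive.
    """
    tokens = _TOKEN.findall(text)
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Gpr:
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            parts.append(parse_and())
        return Gpr.or_(parts)

    def parse_and() -> Gpr:
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            parts.append(parse_atom())
        return Gpr.and_(parts)

    def parse_atom() -> Gpr:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parenthesis in GPR: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return Gpr.leaf(take())

    node = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR: {text!r}")
    return node
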