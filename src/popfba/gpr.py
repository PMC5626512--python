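"""Gene-protein-reaction (GPR) boolean expressions.

A GPR rule links a reaction to the genes whose products catalyze it:
``AND`` joins subunits of one complex, ``OR`` joins isozymes. Under
enzyme-capacity constraints the rule maps per-gene capacities
(``v_max = N_copy * k_cat * c``) to a reaction capacity: minimum over
subunits, sum over isozymes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator, Mapping

__all__ = ["GPRExpr", "Gene", "And", "Or", "parse_gpr", "GPRParseError"]


class GPRParseError(ValueError):
    pass


@dataclass(frozen=True)
class GPRExpr:
    """Base class for nodes of a GPR expression tree."""

    def genes(self) -> list[str]:
        """All gene ids referenced, in left-to-right order, deduplicated."""
        seen: dict[str, None] = {}
        for g in self._iter_genes():
            seen.setdefault(g)
        return list(seen)

    def _iter_genes(self) -> Iterator[str]:
        raise NotImplementedError

    def evaluate_bool(self, active: Callable[[str], bool]) -> bool:
        """Truth value of the rule given per-gene presence."""
        raise NotImplementedError

    def evaluate_vmax(
        self, vmax_by_gene: Mapping[str, float], default_bound: float
    ) -> float | None:
        """Reaction capacity from per-gene capacities.

        Returns ``None`` when no gene in the subtree is measured. An OR
        with any unmeasured branch falls back to ``default_bound`` (an
        unmeasured isozyme may carry arbitrary flux, so the sum rule
        cannot cap the reaction); an AND uses the minimum over the
        measured subunits only, since a measured subunit is still a valid
        capacity ceiling.
        """
        raise NotImplementedError

    def combine_counts(self, counts: Mapping[str, float]) -> float | None:
        """GPR-effective copy number: sum over OR, min over AND.

        Genes absent from ``counts`` are ignored; returns ``None`` when
        nothing in the subtree is measured.
        """
        raise NotImplementedError


@dataclass(frozen=True)
class Gene(GPRExpr):
    name: str

    def _iter_genes(self):
        yield self.name

    def evaluate_bool(self, active):
        return bool(active(self.name))

    def evaluate_vmax(self, vmax_by_gene, default_bound):
        return vmax_by_gene.get(self.name)

    def combine_counts(self, counts):
        return counts.get(self.name)

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class And(GPRExpr):
    children: tuple[GPRExpr, ...]

    def __post_init__(self):
        if not self.children:
            raise GPRParseError("empty AND node")

    def _iter_genes(self):
        for c in self.children:
            yield from c._iter_genes()

    def evaluate_bool(self, active):
        return all(c.evaluate_bool(active) for c in self.children)

    def evaluate_vmax(self, vmax_by_gene, default_bound):
        vals = [c.evaluate_vmax(vmax_by_gene, default_bound)
                for c in self.children]
        measured = [v for v in vals if v is not None]
        return min(measured) if measured else None

    def combine_counts(self, counts):
        vals = [c.combine_counts(counts) for c in self.children]
        measured = [v for v in vals if v is not None]
        return min(measured) if measured else None

    def __str__(self) -> str:
        return "(" + " and ".join(str(c) for c in self.children) + ")"


@dataclass(frozen=True)
class Or(GPRExpr):
    children: tuple[GPRExpr, ...]

    def __post_init__(self):
        if not self.children:
            raise GPRParseError("empty OR node")

    def _iter_genes(self):
        for c in self.children:
            yield from c._iter_genes()

    def evaluate_bool(self, active):
        return any(c.evaluate_bool(active) for c in self.children)

    def evaluate_vmax(self, vmax_by_gene, default_bound):
        vals = [c.evaluate_vmax(vmax_by_gene, default_bound)
                for c in self.children]
        if any(v is None for v in vals):
            # an unmeasured isozyme leaves the reaction effectively uncapped
            return default_bound if any(v is not None for v in vals) else None
        return sum(vals)

    def combine_counts(self, counts):
        vals = [c.combine_counts(counts) for c in self.children]
        measured = [v for v in vals if v is not None]
        return sum(measured) if measured else None

    def __str__(self) -> str:
        return "(" + " or ".join(str(c) for c in self.children) + ")"


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[str]:
    pos, tokens = 0, []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GPRExpr:
    """Parse a GPR string like ``"(G1 and G2) or G3"`` into a tree.

    ``and`` binds tighter than ``or``; keywords are case-insensitive.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRParseError("empty GPR string")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def parse_or() -> GPRExpr:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> GPRExpr:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_atom() -> GPRExpr:
        tok = take()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR string: {text!r}")
        if tok == "(":
            node = parse_or()
            if take() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR: {text!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"malformed GPR string: {text!r}")
        return Gene(tok)

    expr = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR string: {text!r}")
    return expr
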