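"""Gene-protein-reaction (GPR) boolean rules.

A GPR is a boolean tree over gene identifiers with AND/OR internal nodes.
A reaction with an empty GPR is constitutive: it stays active under every
knockout. Rules are written in the usual infix dialect, e.g.::

    (HK1 or HK2) and GPI

Evaluation is pure: a reaction is active iff its rule evaluates true when
every gene not in the knockout set is present.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Set, Tuple, Union

__all__ = ["GPRExpression", "parse_gpr", "GPRParseError"]


class GPRParseError(ValueError):
    """Raised when a GPR rule string cannot be parsed."""


# A node is either a gene id (str) or ("and"|"or", (children...)).
Node = Union[str, Tuple[str, Tuple["Node", ...]]]

_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(rule: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    if rule[pos:].strip():
        raise GPRParseError(f"unparsable trailing text in GPR: {rule[pos:]!r}")
    return tokens


class _Parser:
    # grammar: or_expr := and_expr ("or" and_expr)*
    #          and_expr := atom ("and" atom)*
    #          atom := gene | "(" or_expr ")"
    def __init__(self, tokens: list[str], rule: str):
        self.tokens = tokens
        self.pos = 0
        self.rule = rule

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR rule: {self.rule!r}")
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.or_expr()
        if self.peek() is not None:
            raise GPRParseError(
                f"unexpected token {self.peek()!r} in GPR rule: {self.rule!r}"
            )
        return node

    def or_expr(self) -> Node:
        children = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            children.append(self.and_expr())
        if len(children) == 1:
            return children[0]
        return ("or", tuple(children))

    def and_expr(self) -> Node:
        children = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            children.append(self.atom())
        if len(children) == 1:
            return children[0]
        return ("and", tuple(children))

    def atom(self) -> Node:
        tok = self.take()
        if tok == "(":
            node = self.or_expr()
            if self.take() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR: {self.rule!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"misplaced token {tok!r} in GPR rule: {self.rule!r}")
        return tok


def _eval(node: Node, absent: Set[str]) -> bool:
    if isinstance(node, str):
        return node not in absent
    op, children = node
    if op == "and":
        return all(_eval(c, absent) for c in children)
    return any(_eval(c, absent) for c in children)


def _genes(node: Node, out: Set[str]) -> None:
    if isinstance(node, str):
        out.add(node)
        return
    for c in node[1]:
        _genes(c, out)


def _to_string(node: Node, parent_op: Optional[str] = None) -> str:
    if isinstance(node, str):
        return node
    op, children = node
    joined = f" {op} ".join(_to_string(c, op) for c in children)
    # parenthesize "or" under "and" (and any nested compound) for round-trip fidelity
    if parent_op is not None and op != parent_op:
        return f"({joined})"
    return joined


@dataclass(frozen=True)
class GPRExpression:
    """Boolean gene rule of a reaction; empty tree means constitutive."""

    root: Optional[Node] = None
    _gene_cache: FrozenSet[str] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    @property
    def genes(self) -> FrozenSet[str]:
        if self._gene_cache is None:
            acc: Set[str] = set()
            if self.root is not None:
                _genes(self.root, acc)
            object.__setattr__(self, "_gene_cache", frozenset(acc))
        return self._gene_cache

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """True iff the reaction remains active given the knocked-out genes."""
        absent = set(knocked_out)
        if self.root is None:
            return True
        return _eval(self.root, absent)

    def to_string(self) -> str:
        return "" if self.root is None else _to_string(self.root)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_gpr(rule: str) -> GPRExpression:
    """Parse an infix GPR string using ``and``/``or`` and parentheses.

    An empty or whitespace-only string yields the constitutive rule.
    """
    if rule is None or not rule.strip():
        return GPRExpression(None)
    tokens = _tokenize(rule)
    return GPRExpression(_Parser(tokens, rule).parse())
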