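"""Query expression trees and the query-string grammar.

Grammar (minimal, deterministic)::

    expr     := and_expr ( "OR" and_expr )*
    and_expr := unary ( ["AND"] unary )*        # adjacency is implicit AND
    unary    := "(" expr ")" | atom
    atom     := path ":" op number              # range, op in > >= < <=
              | path ":" value                  # fielded term (trailing * = prefix)
              | value                           # bare term over all keyword paths

Values may be double-quoted to preserve spaces; a trailing unquoted ``*``
makes a prefix wildcard.  ``AND`` binds tighter than ``OR``; both operators
must be uppercase to count as operators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .errors import QueryParseError

RANGE_OPS = (">=", "<=", ">", "<")


@dataclass(frozen=True)
class Term:
    """Bare term: matched against every keyword-mapped path."""

    value: str


@dataclass(frozen=True)
class FieldTerm:
    path: str
    value: str


@dataclass(frozen=True)
class Range:
    path: str
    op: str  # one of > >= < <=
    number: float


@dataclass(frozen=True)
class Wildcard:
    path: Optional[str]  # None = all keyword paths
    prefix: str


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]


Node = Union[Term, FieldTerm, Range, Wildcard, And, Or]


@dataclass(frozen=True)
class _Token:
    kind: str  # lparen | rparen | and | or | term
    text: str
    position: int
    quoted_spans: tuple[tuple[int, int], ...] = ()  # offsets into text that were quoted

    def is_quoted(self, offset: int) -> bool:
        return any(a <= offset < b for a, b in self.quoted_spans)


def _tokenize(q: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(q)
    while i < n:
        ch = q[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(_Token("lparen" if ch == "(" else "rparen", ch, i))
            i += 1
            continue
        start = i
        text_parts: list[str] = []
        spans: list[tuple[int, int]] = []
        while i < n and not q[i].isspace() and q[i] not in "()":
            if q[i] == '"':
                close = q.find('"', i + 1)
                if close == -1:
                    raise QueryParseError("unbalanced quote", i)
                begin = sum(len(p) for p in text_parts)
                text_parts.append(q[i + 1 : close])
                spans.append((begin, begin + close - i - 1))
                i = close + 1
            else:
                text_parts.append(q[i])
                i += 1
        text = "".join(text_parts)
        if text == "AND" and not spans:
            tokens.append(_Token("and", text, start))
        elif text == "OR" and not spans:
            tokens.append(_Token("or", text, start))
        else:
            tokens.append(_Token("term", text, start, tuple(spans)))
    return tokens


def _parse_number(text: str, position: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise QueryParseError(f"expected a number, got {text!r}", position) from None


def _atom(token: _Token) -> Node:
    text = token.text
    if not text:
        raise QueryParseError("empty term", token.position)
    # find an unquoted ':' separating path from value
    colon = -1
    for offset, ch in enumerate(text):
        if ch == ":" and not token.is_quoted(offset):
            colon = offset
            break
    if colon > 0:
        path, rest = text[:colon], text[colon + 1 :]
        if not rest:
            raise QueryParseError("missing value after ':'", token.position + colon)
        for op in RANGE_OPS:
            if rest.startswith(op) and not token.is_quoted(colon + 1):
                number = _parse_number(rest[len(op) :], token.position + colon + 1)
                return Range(path=path, op=op, number=number)
        if rest.endswith("*") and not token.is_quoted(len(text) - 1):
            return Wildcard(path=path, prefix=rest[:-1])
        return FieldTerm(path=path, value=rest)
    if colon == 0:
        raise QueryParseError("missing field path before ':'", token.position)
    if text.endswith("*") and not token.is_quoted(len(text) - 1):
        return Wildcard(path=None, prefix=text[:-1])
    return Term(value=text)


class _Parser:
    def __init__(self, tokens: list[_Token], length: int):
        self.tokens = tokens
        self.pos = 0
        self.length = length

    def peek(self) -> Optional[_Token]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def advance(self) -> _Token:
        token = self.tokens[self.pos]
        self.pos += 1
        return token

    def parse_expr(self) -> Node:
        children = [self.parse_and()]
        while (token := self.peek()) and token.kind == "or":
            self.advance()
            nxt = self.peek()
            if nxt is None or nxt.kind in ("or", "and", "rparen"):
                raise QueryParseError("dangling OR", token.position)
            children.append(self.parse_and())
        if len(children) == 1:
            return children[0]
        return Or(tuple(children))

    def parse_and(self) -> Node:
        children = [self.parse_unary()]
        while (token := self.peek()) is not None:
            if token.kind == "and":
                self.advance()
                nxt = self.peek()
                if nxt is None or nxt.kind in ("or", "and", "rparen"):
                    raise QueryParseError("dangling AND", token.position)
                children.append(self.parse_unary())
            elif token.kind in ("term", "lparen"):
                children.append(self.parse_unary())  # implicit AND
            else:
                break
        if len(children) == 1:
            return children[0]
        return And(tuple(children))

    def parse_unary(self) -> Node:
        token = self.peek()
        if token is None:
            raise QueryParseError("unexpected end of query", self.length)
        if token.kind == "lparen":
            self.advance()
            node = self.parse_expr()
            closing = self.peek()
            if closing is None or closing.kind != "rparen":
                raise QueryParseError("unbalanced parenthesis", token.position)
            self.advance()
            return node
        if token.kind == "term":
            self.advance()
            return _atom(token)
        raise QueryParseError(f"unexpected {token.text!r}", token.position)


def parse_query(q: str) -> Node:
    """Parse a query string into an expression tree.

    Raises :class:`QueryParseError` (with position) on empty input,
    unbalanced quotes or parentheses, and dangling operators.
    """
    if not q or not q.strip():
        raise QueryParseError("empty query", 0)
    tokens = _tokenize(q)
    first = tokens[0]
    if first.kind in ("and", "or"):
        raise QueryParseError(f"dangling {first.text}", first.position)
    parser = _Parser(tokens, len(q))
    node = parser.parse_expr()
    trailing = parser.peek()
    if trailing is not None:
        raise QueryParseError(
            f"unexpected {trailing.text!r}", trailing.position
        )
    return node
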