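"""Boolean expression trees and the ``targets, factors`` file dialect.

Expressions are immutable trees over four node kinds: variable literals,
negation, conjunction, disjunction, plus the two constants.  The textual
dialect uses ``!`` (NOT), ``&`` (AND), ``|`` (OR), parentheses and the
constants ``0``/``1``; precedence is NOT > AND > OR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping


class ExpressionError(ValueError):
    """Malformed expression text or an unrepresentable expression."""


@dataclass(frozen=True)
class Expr:
    """Base class for Boolean expression nodes."""

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        raise NotImplementedError

    def literals(self, negated: bool = False) -> Iterator[tuple[str, bool]]:
        """Yield (variable, is_negated) for every literal occurrence."""
        raise NotImplementedError

    def substitute(self, mapping: Mapping[str, "Expr"]) -> "Expr":
        """Replace variables by expressions; unmentioned variables stay."""
        raise NotImplementedError

    def variables(self) -> set[str]:
        return {name for name, _ in self.literals()}


@dataclass(frozen=True)
class Const(Expr):
    value: int

    def evaluate(self, assignment):
        return self.value

    def literals(self, negated=False):
        return iter(())

    def substitute(self, mapping):
        return self


TRUE = Const(1)
FALSE = Const(0)


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, assignment):
        return int(assignment[self.name])

    def literals(self, negated=False):
        yield (self.name, negated)

    def substitute(self, mapping):
        return mapping.get(self.name, self)


@dataclass(frozen=True)
class Not(Expr):
    arg: Expr

    def evaluate(self, assignment):
        return 1 - self.arg.evaluate(assignment)

    def literals(self, negated=False):
        yield from self.arg.literals(not negated)

    def substitute(self, mapping):
        return Not(self.arg.substitute(mapping))


@dataclass(frozen=True)
class And(Expr):
    args: tuple[Expr, ...]

    def evaluate(self, assignment):
        return int(all(a.evaluate(assignment) for a in self.args))

    def literals(self, negated=False):
        for a in self.args:
            yield from a.literals(negated)

    def substitute(self, mapping):
        return And(tuple(a.substitute(mapping) for a in self.args))


@dataclass(frozen=True)
class Or(Expr):
    args: tuple[Expr, ...]

    def evaluate(self, assignment):
        return int(any(a.evaluate(assignment) for a in self.args))

    def literals(self, negated=False):
        for a in self.args:
            yield from a.literals(negated)

    def substitute(self, mapping):
        return Or(tuple(a.substitute(mapping) for a in self.args))


# ---------------------------------------------------------------------------
# Parsing

_NAME_CHARS = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_."


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "!&|()":
            tokens.append(c)
            i += 1
        elif c in _NAME_CHARS:
            j = i
            while j < len(text) and text[j] in _NAME_CHARS:
                j += 1
            tokens.append(text[i:j])
            i = j
        else:
            raise ExpressionError(f"unexpected character {c!r} in expression")
    return tokens


class _Parser:
    """Recursive-descent parser; precedence NOT > AND > OR."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise ExpressionError(f"trailing token {self.peek()!r}")
        return expr

    def parse_or(self) -> Expr:
        args = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            args.append(self.parse_and())
        return args[0] if len(args) == 1 else Or(tuple(args))

    def parse_and(self) -> Expr:
        args = [self.parse_unary()]
        while self.peek() == "&":
            self.take()
            args.append(self.parse_unary())
        return args[0] if len(args) == 1 else And(tuple(args))

    def parse_unary(self) -> Expr:
        tok = self.take()
        if tok == "!":
            return Not(self.parse_unary())
        if tok == "(":
            inner = self.parse_or()
            if self.take() != ")":
                raise ExpressionError("missing closing parenthesis")
            return inner
        if tok in ("0", "1"):
            return Const(int(tok))
        if tok[0] in _NAME_CHARS and tok not in "!&|()":
            return Var(tok)
        raise ExpressionError(f"unexpected token {tok!r}")


def parse_expression(text: str) -> Expr:
    """Parse one Boolean expression in the ``!``/``&``/``|`` dialect."""
    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionError("empty expression")
    return _Parser(tokens).parse()


def format_expression(expr: Expr) -> str:
    """Serialize an expression; re-parsing yields an equivalent expression."""
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Not):
        inner = format_expression(expr.arg)
        if isinstance(expr.arg, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"
    if isinstance(expr, And):
        parts = []
        for a in expr.args:
            s = format_expression(a)
            if isinstance(a, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)
    if isinstance(expr, Or):
        return " | ".join(format_expression(a) for a in expr.args)
    raise ExpressionError(f"cannot serialize {expr!r}")
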