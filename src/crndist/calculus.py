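"""The distribution calculus: syntax, semantics and completeness.

Formulas are built from the literals ``one`` and ``zero`` with sum (pmf
convolution), minimum, scaling by a non-negative rational ``k = k1/k2``
(multiply the support by ``k1``, then floor-divide by ``k2``), and convex
combination whose weight may be an affine expression over environmental
input variables.  ``evaluate`` maps a formula and an environment to the
exact pmf it denotes; ``pmf_to_formula`` shows completeness by compiling
any finite-support pmf on N back into a formula.

Surface syntax (this package's own; the calculus has no canonical one)::

    formula :=  term ('+' term)*                  sum, left-associative
    term    :=  atom ('[' dexpr ']' ':' term)?    convex, right-associative
    atom    :=  'one' | 'zero' | rat '*' atom
             |  'min' '(' formula ',' formula ')' | '(' formula ')'
    dexpr   :=  dterm ('+' dterm)*
    dterm   :=  rat ('*' var)?  |  var

Rationals are ``a/b`` or decimal literals; decimals are converted to exact
fractions.  Convex binds tighter than '+'.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Union

from .pmf import Pmf, convex, convolve, minimum, pmf_one, pmf_zero, point_mass, scalar_divide, scalar_multiply

__all__ = [
    "Formula",
    "One",
    "Zero",
    "Sum",
    "Min",
    "Scale",
    "Convex",
    "DExpr",
    "Environment",
    "ParseError",
    "parse",
    "pretty",
    "eval_D",
    "evaluate",
    "free_variables",
    "pmf_to_formula",
]


def _rat(v) -> Fraction:
    if isinstance(v, float):
        raise TypeError("use Fraction or string literals, not floats")
    return Fraction(v)


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DExpr:
    """Affine probability expression ``p0 + sum_i p_i * c_i``.

    Both the sum of the coefficients ``p_i`` and the total ``p0 + sum p_i``
    must lie in [0, 1], so the valuation is a probability for every
    environment.  Variable names are distinct.
    """

    constant: Fraction
    terms: tuple[tuple[Fraction, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "constant", _rat(self.constant))
        terms = tuple((_rat(c), str(v)) for c, v in self.terms)
        object.__setattr__(self, "terms", terms)
        if not 0 <= self.constant <= 1:
            raise ValueError(f"constant {self.constant} outside [0, 1]")
        names = [v for _, v in terms]
        if len(names) != len(set(names)):
            raise ValueError("repeated variable in affine expression")
        coeff_sum = sum((c for c, _ in terms), Fraction(0))
        if not 0 <= coeff_sum <= 1:
            raise ValueError(f"coefficient sum {coeff_sum} outside [0, 1]")
        if not 0 <= self.constant + coeff_sum <= 1:
            raise ValueError(
                f"constant + coefficient sum {self.constant + coeff_sum} outside [0, 1]"
            )
        for c, v in terms:
            if not 0 <= c <= 1:
                raise ValueError(f"coefficient {c} of {v} outside [0, 1]")

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(v for _, v in self.terms)


class Formula:
    """Base class of calculus AST nodes."""

    __slots__ = ()

    def __repr__(self) -> str:
        return pretty(self)


@dataclass(frozen=True, repr=False)
class One(Formula):
    pass


@dataclass(frozen=True, repr=False)
class Zero(Formula):
    pass


@dataclass(frozen=True, repr=False)
class Sum(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True, repr=False)
class Min(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True, repr=False)
class Scale(Formula):
    """Scaling by ``k = k1/k2`` stored as the reduced fraction, k1 >= 0, k2 >= 1."""

    k1: int
    k2: int
    child: Formula

    def __post_init__(self):
        k = Fraction(int(self.k1), int(self.k2))
        if k < 0:
            raise ValueError("scale constant must be non-negative")
        object.__setattr__(self, "k1", k.numerator)
        object.__setattr__(self, "k2", k.denominator)


@dataclass(frozen=True, repr=False)
class Convex(Formula):
    weight: DExpr
    left: Formula
    right: Formula


Environment = Mapping[str, Union[Fraction, int, str]]


def _env_value(env: Environment, name: str) -> Fraction:
    if name not in env:
        raise KeyError(f"variable '{name}' is not bound in the environment")
    v = _rat(env[name])
    if not 0 <= v <= 1:
        raise ValueError(f"environment value {v} for '{name}' outside [0, 1]")
    return v


# ---------------------------------------------------------------------------
# Semantics
# ---------------------------------------------------------------------------


def eval_D(d: DExpr, env: Environment | None = None) -> Fraction:
    """Valuation ``p0 + sum_i p_i * E(c_i)``, exact and always in [0, 1]."""
    env = env or {}
    acc = d.constant
    for c, v in d.terms:
        acc += c * _env_value(env, v)
    return acc


def evaluate(f: Formula, env: Environment | None = None) -> Pmf:
    """The pmf denoted by ``f`` under ``env`` (structural recursion)."""
    env = env or {}
    if isinstance(f, One):
        return pmf_one()
    if isinstance(f, Zero):
        return pmf_zero()
    if isinstance(f, Sum):
        return convolve(evaluate(f.left, env), evaluate(f.right, env))
    if isinstance(f, Min):
        return minimum(evaluate(f.left, env), evaluate(f.right, env))
    if isinstance(f, Scale):
        child = evaluate(f.child, env)
        if f.k1 == 0:
            return pmf_zero()  # k = 0 maps all mass to the point 0
        return scalar_divide(scalar_multiply(child, f.k1), f.k2)
    if isinstance(f, Convex):
        return convex(
            evaluate(f.left, env), evaluate(f.right, env), eval_D(f.weight, env)
        )
    raise TypeError(f"not a Formula node: {f!r}")


def free_variables(f: Formula) -> frozenset[str]:
    """Union of the environmental variables of all convex weights in ``f``."""
    if isinstance(f, (One, Zero)):
        return frozenset()
    if isinstance(f, (Sum, Min)):
        return free_variables(f.left) | free_variables(f.right)
    if isinstance(f, Scale):
        return free_variables(f.child)
    if isinstance(f, Convex):
        return f.weight.variables | free_variables(f.left) | free_variables(f.right)
    raise TypeError(f"not a Formula node: {f!r}")


# ---------------------------------------------------------------------------
# Completeness: pmf -> formula
# ---------------------------------------------------------------------------


def pmf_to_formula(p: Pmf) -> Formula:
    """Compile a finite one-dimensional pmf into a formula denoting it exactly.

    Builds a right-nested chain of convex choices over ``z_i * one``; the
    weight at level ``i`` is the mass of ``z_i`` renormalized by the residual
    mass ``1 - sum_{j<i} f(z_j)``, so evaluation returns ``p`` bit-exactly.
    """
    if p.dim != 1:
        raise ValueError("pmf_to_formula is defined for one-dimensional pmfs")
    points = [(z, pr) for (z,), pr in p.items()]
    node: Formula = Scale(points[-1][0], 1, One())
    residual = points[-1][1]
    for z, pr in reversed(points[:-1]):
        residual += pr
        node = Convex(DExpr(pr / residual), Scale(z, 1, One()), node)
    return node


# ---------------------------------------------------------------------------
# Printer
# ---------------------------------------------------------------------------


def _rat_str(q: Fraction) -> str:
    return str(q.numerator) if q.denominator == 1 else f"{q.numerator}/{q.denominator}"


def _dexpr_str(d: DExpr) -> str:
    parts = [f"{_rat_str(c)}*{v}" for c, v in d.terms]
    if d.constant != 0 or not parts:
        parts.append(_rat_str(d.constant))
    return " + ".join(parts)


def pretty(f: Formula) -> str:
    """Canonical fully-parenthesized text form; ``parse(pretty(f)) == f``."""
    if isinstance(f, One):
        return "one"
    if isinstance(f, Zero):
        return "zero"
    if isinstance(f, Sum):
        return f"({pretty(f.left)}) + ({pretty(f.right)})"
    if isinstance(f, Min):
        return f"min({pretty(f.left)}, {pretty(f.right)})"
    if isinstance(f, Scale):
        return f"{_rat_str(Fraction(f.k1, f.k2))}*({pretty(f.child)})"
    if isinstance(f, Convex):
        return f"({pretty(f.left)})[{_dexpr_str(f.weight)}]:({pretty(f.right)})"
    raise TypeError(f"not a Formula node: {f!r}")


# ---------------------------------------------------------------------------
# Parser (recursive descent)
# ---------------------------------------------------------------------------


class ParseError(ValueError):
    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+(?:\.\d+)?(?:/\d+)?)|(?P<name>[A-Za-z_]\w*)|(?P<sym>[()\[\]:,+*]))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


def _parse_rat(text: str) -> Fraction:
    if "." in text:
        whole, frac = text.split(".")
        return Fraction(int(whole or 0)) + Fraction(int(frac or 0), 10 ** len(frac))
    return Fraction(text)


class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, val, pos = self.next()
        if val != value:
            raise ParseError(f"expected {value!r}, found {val or 'end of input'!r}", pos)

    def formula(self) -> Formula:
        node = self.term()
        while self.peek()[1] == "+":
            self.next()
            node = Sum(node, self.term())
        return node

    def term(self) -> Formula:
        node = self.atom()
        if self.peek()[1] == "[":
            self.next()
            d = self.dexpr()
            self.expect("]")
            self.expect(":")
            right = self.term()  # right-associative
            try:
                return Convex(d, node, right)
            except ValueError as e:
                raise ParseError(str(e), self.peek()[2]) from None
        return node

    def atom(self) -> Formula:
        kind, val, pos = self.peek()
        if val == "one":
            self.next()
            return One()
        if val == "zero":
            self.next()
            return Zero()
        if val == "min":
            self.next()
            self.expect("(")
            left = self.formula()
            self.expect(",")
            right = self.formula()
            self.expect(")")
            return Min(left, right)
        if val == "(":
            self.next()
            node = self.formula()
            self.expect(")")
            return node
        if kind == "num":
            self.next()
            k = _parse_rat(val)
            self.expect("*")
            child = self.atom()
            return Scale(k.numerator, k.denominator, child)
        raise ParseError(f"expected a formula, found {val or 'end of input'!r}", pos)

    def dexpr(self) -> DExpr:
        constant = Fraction(0)
        terms: list[tuple[Fraction, str]] = []
        while True:
            kind, val, pos = self.next()
            if kind == "num":
                coeff = _parse_rat(val)
                if self.peek()[1] == "*":
                    self.next()
                    nk, name, npos = self.next()
                    if nk != "name":
                        raise ParseError("expected a variable name", npos)
                    terms.append((coeff, name))
                else:
                    constant += coeff
            elif kind == "name":
                terms.append((Fraction(1), val))
            else:
                raise ParseError("expected a coefficient or variable", pos)
            if self.peek()[1] != "+":
                break
            self.next()
        try:
            return DExpr(constant, tuple(terms))
        except ValueError as e:
            raise ParseError(str(e), pos) from None


def parse(text: str) -> Formula:
    """Parse the surface syntax into a :class:`Formula` (round-trips with pretty)."""
    p = _Parser(text)
    node = p.formula()
    kind, val, pos = p.peek()
    if kind != "end":
        raise ParseError(f"trailing input {val!r}", pos)
    return node
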