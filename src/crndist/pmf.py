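"""Exact finite-support probability mass functions over non-negative integer tuples.

A :class:`Pmf` stores an exact rational probability for every point of a finite
support in ``N^m``.  All five algebraic operations used by the distribution
calculus (convolution, minimum, integer scaling, floor division, convex
combination) are closed on this representation and computed without any
floating point, so compiler/verifier round trips can be asserted bit-exactly.
"""

from __future__ import annotations

import json
from fractions import Fraction
from typing import Callable, Iterable, Iterator, Mapping

__all__ = [
    "Pmf",
    "convolve",
    "minimum",
    "scalar_multiply",
    "scalar_divide",
    "convex",
    "l1_distance",
    "mult_error",
    "truncate",
    "point_mass",
    "pmf_one",
    "pmf_zero",
]

Point = tuple[int, ...]


def _as_fraction(v) -> Fraction:
    # str goes through Fraction("a/b"); float is rejected to keep exactness.
    if isinstance(v, float):
        raise TypeError("floating-point probabilities are not allowed; use Fraction or 'a/b'")
    return Fraction(v)


def _as_point(p, dim: int | None = None) -> Point:
    if isinstance(p, int):
        pt = (p,)
    else:
        pt = tuple(int(c) for c in p)
    if any(c < 0 for c in pt):
        raise ValueError(f"support point {pt} has a negative component")
    if dim is not None and len(pt) != dim:
        raise ValueError(f"support point {pt} does not have dimension {dim}")
    return pt


class Pmf:
    """Finite-support pmf over ``N^m`` with exact rational masses.

    Parameters
    ----------
    mass
        Mapping from support point (int or tuple of ints) to probability
        (``Fraction``, int, or exact string like ``"1/6"``).  Zero-mass
        entries are dropped; the remaining masses must sum exactly to 1.
    dim
        Dimension ``m``.  Inferred from the points when omitted.
    """

    __slots__ = ("_dim", "_mass")

    def __init__(self, mass: Mapping, dim: int | None = None):
        items: dict[Point, Fraction] = {}
        for pt, pr in mass.items():
            pr = _as_fraction(pr)
            if pr < 0 or pr > 1:
                raise ValueError(f"probability {pr} outside [0, 1]")
            if pr == 0:
                continue
            pt = _as_point(pt, dim)
            if dim is None:
                dim = len(pt)
            if pt in items:
                raise ValueError(f"duplicate support point {pt}")
            items[pt] = pr
        if dim is None:
            raise ValueError("cannot infer dimension from an empty mass map")
        total = sum(items.values(), Fraction(0))
        if total != 1:
            raise ValueError(f"masses sum to {total}, expected exactly 1")
        self._dim = dim
        self._mass = items

    @property
    def dim(self) -> int:
        return self._dim

    @property
    def support(self) -> frozenset[Point]:
        return frozenset(self._mass)

    def __call__(self, point) -> Fraction:
        """Mass at ``point`` (0 off-support)."""
        return self._mass.get(_as_point(point, self._dim), Fraction(0))

    def items(self) -> Iterator[tuple[Point, Fraction]]:
        return iter(sorted(self._mass.items()))

    def __len__(self) -> int:
        return len(self._mass)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pmf):
            return NotImplemented
        return self._dim == other._dim and self._mass == other._mass

    def __hash__(self) -> int:
        return hash((self._dim, frozenset(self._mass.items())))

    def __repr__(self) -> str:
        body = ", ".join(f"{pt if self._dim > 1 else pt[0]}: {pr}" for pt, pr in self.items())
        return f"Pmf({{{body}}})"

    def mean(self) -> tuple[Fraction, ...]:
        """Componentwise expectation (exact)."""
        acc = [Fraction(0)] * self._dim
        for pt, pr in self._mass.items():
            for d, c in enumerate(pt):
                acc[d] += c * pr
        return tuple(acc)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        entries = [
            {"point": list(pt), "p": f"{pr.numerator}/{pr.denominator}"}
            for pt, pr in self.items()
        ]
        return json.dumps({"dim": self._dim, "mass": entries}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Pmf":
        doc = json.loads(text)
        mass = {tuple(e["point"]): Fraction(e["p"]) for e in doc["mass"]}
        return cls(mass, dim=int(doc["dim"]))


def point_mass(point, dim: int | None = None) -> Pmf:
    return Pmf({_as_point(point, dim): Fraction(1)}, dim=dim)


def pmf_one() -> Pmf:
    """The pmf with all mass on 1 (the calculus literal ``one``)."""
    return point_mass(1)


def pmf_zero() -> Pmf:
    """The pmf with all mass on 0 (the calculus literal ``zero``)."""
    return point_mass(0)


def _require_1d(*ps: Pmf) -> None:
    for p in ps:
        if p.dim != 1:
            raise ValueError(
                "operation is defined for one-dimensional pmfs only "
                f"(got dimension {p.dim})"
            )


def _require_same_dim(p1: Pmf, p2: Pmf) -> None:
    if p1.dim != p2.dim:
        raise ValueError(f"dimension mismatch: {p1.dim} != {p2.dim}")


def convolve(p1: Pmf, p2: Pmf) -> Pmf:
    """Sum of independent variables: mass at y is sum over yi+yj=y of p1(yi)p2(yj)."""
    _require_1d(p1, p2)
    out: dict[Point, Fraction] = {}
    for (yi,), pi in p1.items():
        for (yj,), pj in p2.items():
            key = (yi + yj,)
            out[key] = out.get(key, Fraction(0)) + pi * pj
    return Pmf(out, dim=1)


def minimum(p1: Pmf, p2: Pmf) -> Pmf:
    """Minimum of independent variables: mass at y sums pairs with min(yi,yj)=y."""
    _require_1d(p1, p2)
    out: dict[Point, Fraction] = {}
    for (yi,), pi in p1.items():
        for (yj,), pj in p2.items():
            key = (min(yi, yj),)
            out[key] = out.get(key, Fraction(0)) + pi * pj
    return Pmf(out, dim=1)


def scalar_multiply(p: Pmf, k1: int) -> Pmf:
    """Scale the support pointwise by the positive integer ``k1``."""
    _require_1d(p)
    k1 = int(k1)
    if k1 < 1:
        raise ValueError("k1 must be a positive integer")
    return Pmf({(y * k1,): pr for (y,), pr in p.items()}, dim=1)


def scalar_divide(p: Pmf, k2: int) -> Pmf:
    """Floor-divide the support by the positive integer ``k2`` (masses merge)."""
    _require_1d(p)
    k2 = int(k2)
    if k2 < 1:
        raise ValueError("k2 must be a positive integer")
    out: dict[Point, Fraction] = {}
    for (y,), pr in p.items():
        key = (y // k2,)
        out[key] = out.get(key, Fraction(0)) + pr
    return Pmf(out, dim=1)


def convex(p1: Pmf, p2: Pmf, p) -> Pmf:
    """Mixture ``p*p1 + (1-p)*p2`` for rational ``p`` in [0, 1]."""
    _require_same_dim(p1, p2)
    p = _as_fraction(p)
    if p < 0 or p > 1:
        raise ValueError(f"mixture weight {p} outside [0, 1]")
    out: dict[Point, Fraction] = {}
    for pt, pr in p1.items():
        out[pt] = out.get(pt, Fraction(0)) + p * pr
    for pt, pr in p2.items():
        out[pt] = out.get(pt, Fraction(0)) + (1 - p) * pr
    return Pmf(out, dim=p1.dim)


def l1_distance(p1: Pmf, p2: Pmf) -> Fraction:
    """L1 distance ``sum_n |p1(n) - p2(n)|``; always in [0, 2] for pmfs."""
    _require_same_dim(p1, p2)
    pts = p1.support | p2.support
    return sum((abs(p1(pt) - p2(pt)) for pt in pts), Fraction(0))


def mult_error(p1: Pmf, p2: Pmf) -> Fraction:
    """Multiplicative error ``max_n min(p1(n)/p2(n), p2(n)/p1(n))``.

    Points where exactly one mass is zero contribute ratio 0; points where
    both are zero contribute nothing.  Identical pmfs give 1.
    """
    _require_same_dim(p1, p2)
    best = Fraction(0)
    for pt in p1.support | p2.support:
        a, b = p1(pt), p2(pt)
        if a == 0 or b == 0:
            ratio = Fraction(0)
        else:
            ratio = min(a / b, b / a)
        best = max(best, ratio)
    return best


def truncate(enumerated: Iterable[tuple], epsilon) -> Pmf:
    """Truncate a countable-support pmf to a finite one within ``epsilon`` in L1.

    ``enumerated`` yields ``(point, mass)`` pairs in a fixed enumeration order
    of the support.  Points are kept until the retained mass exceeds
    ``1 - epsilon/2``; the kept masses are renormalized, which bounds the L1
    distance to the original below ``epsilon``.
    """
    epsilon = _as_fraction(epsilon)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    threshold = 1 - epsilon / 2
    kept: dict[Point, Fraction] = {}
    total = Fraction(0)
    for pt, pr in enumerated:
        pr = _as_fraction(pr)
        if pr == 0:
            continue
        kept[_as_point(pt)] = pr
        total += pr
        if total > threshold:
            break
    else:
        if total != 1:  # exhausted enumeration without reaching mass 1
            if total <= threshold:
                raise ValueError(
                    f"enumeration exhausted at retained mass {total} <= {threshold}"
                )
    return Pmf({pt: pr / total for pt, pr in kept.items()})
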