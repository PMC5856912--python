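"""Deterministic generators of random pmfs, formulas, and worked examples.

Everything the test surface needs is produced programmatically: random
finite-support pmfs with exact rational masses (integer compositions of a
bounded denominator), random well-formed calculus formulas, and the named
worked examples used throughout the documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .calculus import Convex, DExpr, Formula, Min, One, Scale, Sum, Zero
from .crn import NroSystem
from .pmf import Pmf

__all__ = ["FixtureSpec", "random_pmf", "random_formula", "worked_examples"]


@dataclass(frozen=True)
class FixtureSpec:
    """Bounds for fixture generation; generation is a pure function of this spec."""

    seed: int = 0
    max_support: int = 4
    max_value: int = 8
    max_depth: int = 3
    denominator_bound: int = 64
    allow_variables: bool = False
    dim: int = 1

    def __post_init__(self):
        if min(self.max_support, self.max_value, self.max_depth, self.denominator_bound, self.dim) < 1:
            raise ValueError("all bounds must be positive")


def _rng(spec: FixtureSpec, salt: int = 0):
    return np.random.default_rng([spec.seed, salt, 0x5EED])


def random_pmf(spec: FixtureSpec) -> Pmf:
    """Random pmf: masses are a random integer composition of a denominator <= bound."""
    rng = _rng(spec, 1)
    n = int(rng.integers(1, spec.max_support + 1))
    # distinct support points
    pts: set[tuple[int, ...]] = set()
    while len(pts) < n:
        pts.add(tuple(int(v) for v in rng.integers(0, spec.max_value + 1, size=spec.dim)))
    denom = int(rng.integers(n, spec.denominator_bound + 1))
    # composition of denom into n positive parts
    if n == 1:
        parts = [denom]
    else:
        cuts = sorted(rng.choice(np.arange(1, denom), size=n - 1, replace=False))
        parts = np.diff([0, *cuts, denom]).tolist()
    mass = {pt: Fraction(int(c), denom) for pt, c in zip(sorted(pts), parts)}
    return Pmf(mass, dim=spec.dim)


def _random_weight(rng, bound: int) -> Fraction:
    den = int(rng.integers(1, bound + 1))
    num = int(rng.integers(0, den + 1))
    return Fraction(num, den)


def random_formula(spec: FixtureSpec) -> Formula:
    """Random well-formed formula within the depth/kind bounds of ``spec``."""
    rng = _rng(spec, 2)

    def gen(depth: int) -> Formula:
        at_leaf = depth + 1 >= spec.max_depth
        if at_leaf:
            kind = rng.choice(["one", "zero", "scale"])
        else:
            kind = rng.choice(["one", "zero", "scale", "sum", "min", "convex"])
        if kind == "one":
            return One()
        if kind == "zero":
            return Zero()
        if kind == "scale":
            k1 = int(rng.integers(0, 5))
            k2 = int(rng.integers(1, 4))
            child = One() if at_leaf else gen(depth + 1)
            return Scale(k1, k2, child)
        if kind == "sum":
            return Sum(gen(depth + 1), gen(depth + 1))
        if kind == "min":
            return Min(gen(depth + 1), gen(depth + 1))
        w = _random_weight(rng, spec.denominator_bound)
        if spec.allow_variables and rng.random() < 0.5:
            var = f"c{int(rng.integers(1, 3))}"
            coeff = w
            const = _random_weight(rng, spec.denominator_bound) * (1 - coeff)
            d = DExpr(const, ((coeff, var),))
        else:
            d = DExpr(w)
        return Convex(d, gen(depth + 1), gen(depth + 1))

    return gen(0)


def worked_examples() -> dict:
    """Named worked-example fixtures used across the documentation and tests."""
    from .calculus import parse

    f_three_point = Pmf({2: Fraction(1, 6), 5: Fraction(1, 3), 10: Fraction(1, 2)})
    f_joint = Pmf(
        {(3, 1): Fraction(1, 6), (3, 2): Fraction(1, 3), (1, 5): Fraction(1, 2)}
    )
    pi1 = Pmf({3: Fraction(1, 6), 0: Fraction(5, 6)})
    pi2 = Pmf({5: Fraction(1, 2), 1: Fraction(1, 2)})
    switch_formula = parse(
        "(one)[1/1000*c + 1/5]:(4*one) + (2*one)[2/5]:(3*one)"
    )
    # two trivial single-species networks holding 10 and 20 molecules
    c1 = NroSystem(["A"], [], {"A": 10}, outputs=["A"])
    c2 = NroSystem(["B"], [], {"B": 20}, outputs=["B"])
    return {
        "three_point": f_three_point,
        "joint_2d": f_joint,
        "pi1": pi1,
        "pi2": pi2,
        "switch_formula": switch_formula,
        "holder_10": (c1, "A"),
        "holder_20": (c2, "B"),
    }
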