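"""Chemical reaction systems with stochastic mass-action kinetics.

A :class:`ReactionSystem` is a set of species, mass-action reactions with
exact rational rate constants, and an integer initial state.  The
:class:`NroSystem` variant declares output species that never appear as
reactants, so their counts grow monotonically and the network composes.

Propensities use the combinatorial (binomial-coefficient) convention of the
stochastic semantics: a reaction with reactant multiset ``r`` fires at rate
``k * prod_s C(x(s), r(s))``.  For the networks in this package reactants
are unary or distinct species, where this reduces to the plain product.

Plain-text ``.crn`` format::

    # comment
    species: A B C
    init: A=2 C=1
    outputs: C
    A + B -> C @ 1/6
    2A -> 0

Multiplicity is written either by repetition (``A + A``) or with an integer
prefix (``2A``); ``0`` denotes the empty complex; a missing ``@ rate``
defaults to 1.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Reaction",
    "ReactionSystem",
    "NroSystem",
    "propensity",
    "non_reacting_species",
    "validate_nro",
    "read_crn",
    "write_crn",
]


def _rate(v) -> Fraction:
    if isinstance(v, float):
        raise TypeError("rates must be exact rationals, not floats")
    r = Fraction(v)
    if r <= 0:
        raise ValueError(f"rate must be positive, got {r}")
    return r


def _multiset(m) -> tuple[tuple[str, int], ...]:
    """Normalize a reactant/product specification to sorted (species, count) pairs."""
    if isinstance(m, Mapping):
        c = Counter({str(k): int(v) for k, v in m.items()})
    else:
        items = list(m)
        if items and all(
            isinstance(e, tuple) and len(e) == 2 and isinstance(e[0], str) for e in items
        ):
            c = Counter(dict(items))  # (species, count) pairs
        else:
            c = Counter(str(s) for s in items)
    for s, n in c.items():
        if n < 0:
            raise ValueError(f"negative multiplicity for {s}")
    return tuple(sorted((s, n) for s, n in c.items() if n > 0))


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction ``reactants ->^rate products``.

    ``reactants``/``products`` accept an iterable of species names (with
    repetition for multiplicity) or a ``{species: count}`` map.  The net
    change vector is derived, not stored.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: Fraction = Fraction(1)

    def __init__(self, reactants, products, rate=Fraction(1)):
        object.__setattr__(self, "reactants", _multiset(reactants))
        object.__setattr__(self, "products", _multiset(products))
        object.__setattr__(self, "rate", _rate(rate))

    @property
    def species(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.reactants) | frozenset(
            s for s, _ in self.products
        )

    def reactant_count(self, species: str) -> int:
        return dict(self.reactants).get(species, 0)

    def net_change(self) -> dict[str, int]:
        delta = {s: -n for s, n in self.reactants}
        for s, n in self.products:
            delta[s] = delta.get(s, 0) + n
        return {s: d for s, d in delta.items() if d != 0}

    def __str__(self) -> str:
        def side(ms):
            if not ms:
                return "0"
            return " + ".join(s if n == 1 else f"{n}{s}" for s, n in ms)

        r = self.rate
        rate = str(r.numerator) if r.denominator == 1 else f"{r.numerator}/{r.denominator}"
        return f"{side(self.reactants)} -> {side(self.products)} @ {rate}"


class ReactionSystem:
    """Species, reactions, and initial molecular counts (a CRS)."""

    def __init__(
        self,
        species: Sequence[str],
        reactions: Iterable[Reaction] = (),
        init: Mapping[str, int] | None = None,
    ):
        self.species: tuple[str, ...] = tuple(dict.fromkeys(str(s) for s in species))
        declared = set(self.species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        for rx in self.reactions:
            undeclared = rx.species - declared
            if undeclared:
                raise ValueError(f"reaction {rx} uses undeclared species {sorted(undeclared)}")
        init = dict(init or {})
        undeclared = set(init) - declared
        if undeclared:
            raise ValueError(f"initial state uses undeclared species {sorted(undeclared)}")
        self.init: dict[str, int] = {s: int(init.get(s, 0)) for s in self.species}
        if any(v < 0 for v in self.init.values()):
            raise ValueError("initial counts must be non-negative")

    def initial_state(self) -> tuple[int, ...]:
        return tuple(self.init[s] for s in self.species)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionSystem):
            return NotImplemented
        return (
            self.species == other.species
            and sorted(map(str, self.reactions)) == sorted(map(str, other.reactions))
            and self.init == other.init
        )

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}(species={len(self.species)}, "
            f"reactions={len(self.reactions)})"
        )


class NroSystem(ReactionSystem):
    """ReactionSystem with declared non-reacting output species."""

    def __init__(self, species, reactions=(), init=None, outputs: Sequence[str] = ()):
        super().__init__(species, reactions, init)
        self.outputs: tuple[str, ...] = tuple(dict.fromkeys(str(s) for s in outputs))
        if not self.outputs:
            raise ValueError("an NRO system must declare at least one output species")
        undeclared = set(self.outputs) - set(self.species)
        if undeclared:
            raise ValueError(f"outputs {sorted(undeclared)} are not declared species")
        bad = validate_nro(self)
        if bad:
            detail = "; ".join(f"{s} reacts in '{rx}'" for s, rx in bad)
            raise ValueError(f"output species must be non-reacting: {detail}")


def propensity(rx: Reaction, state: Mapping[str, int]) -> Fraction:
    """Stochastic mass-action propensity ``k * prod_s C(x(s), r(s))`` at ``state``."""
    a = rx.rate
    for s, n in rx.reactants:
        x = state[s]
        if x < n:
            return Fraction(0)
        a *= math.comb(x, n)
    return a


def non_reacting_species(c: ReactionSystem) -> frozenset[str]:
    reacting = set()
    for rx in c.reactions:
        reacting.update(s for s, _ in rx.reactants)
    return frozenset(c.species) - reacting


def validate_nro(c: ReactionSystem, outputs: Sequence[str] | None = None):
    """Diagnostics for the non-reacting-output condition.

    Returns a list of ``(species, reaction)`` pairs where a declared output
    occurs as a reactant; empty iff the system is a valid NRO-CRS.
    """
    outs = tuple(outputs) if outputs is not None else getattr(c, "outputs", ())
    bad = []
    for rx in c.reactions:
        for s in outs:
            if rx.reactant_count(s) > 0:
                bad.append((s, rx))
    return bad


# ---------------------------------------------------------------------------
# Text format
# ---------------------------------------------------------------------------

_SPECIES_TERM = re.compile(r"^(\d*)\s*([A-Za-z_]\w*)$")


def _parse_side(text: str) -> Counter:
    text = text.strip()
    out: Counter = Counter()
    if text == "0":
        return out
    for part in text.split("+"):
        m = _SPECIES_TERM.match(part.strip())
        if not m:
            raise ValueError(f"malformed complex term {part.strip()!r}")
        mult = int(m.group(1)) if m.group(1) else 1
        out[m.group(2)] += mult
    return out


def read_crn(text: str) -> ReactionSystem:
    """Parse the ``.crn`` text format; returns :class:`NroSystem` when outputs are declared."""
    species: list[str] = []
    init: dict[str, int] = {}
    outputs: list[str] = []
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            if line.startswith("species:"):
                species.extend(line[len("species:"):].split())
            elif line.startswith("init:"):
                for item in line[len("init:"):].split():
                    name, _, count = item.partition("=")
                    init[name] = int(count)
            elif line.startswith("outputs:"):
                outputs.extend(line[len("outputs:"):].split())
            elif "->" in line:
                lhs, rhs = line.split("->", 1)
                rhs, _, rate_txt = rhs.partition("@")
                rate = Fraction(rate_txt.strip()) if rate_txt.strip() else Fraction(1)
                reactions.append(Reaction(_parse_side(lhs), _parse_side(rhs), rate))
            else:
                raise ValueError(f"unrecognized line {line!r}")
        except (ValueError, ZeroDivisionError) as e:
            raise ValueError(f"line {lineno}: {e}") from None
    if outputs:
        return NroSystem(species, reactions, init, outputs)
    return ReactionSystem(species, reactions, init)


def write_crn(c: ReactionSystem) -> str:
    """Serialize to the ``.crn`` format (deterministic; round-trips with read_crn)."""
    lines = ["species: " + " ".join(c.species)]
    nonzero = [f"{s}={n}" for s, n in c.init.items() if n]
    if nonzero:
        lines.append("init: " + " ".join(nonzero))
    if isinstance(c, NroSystem):
        lines.append("outputs: " + " ".join(c.outputs))
    lines.extend(str(rx) for rx in c.reactions)
    return "\n".join(lines) + "\n"
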