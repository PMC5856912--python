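"""Compilers from pmfs, formulas and environments to reaction networks.

The direct compiler turns a finite-support pmf on N into a leader-based
network: a single leader molecule picks a support point with the pmf's
probability (encoded in the selector rates, or in catalyst counts for the
rate-free variant), and a catalysed transfer then copies that point's
payload into the non-reacting output species.  The multidimensional
compiler generalizes the pattern to joint pmfs on N^m.  Compact special
networks produce Poisson, binomial and uniform laws at stationarity.

Composable network operators mirror the pmf algebra: Sum, Min, Mul, Div and
Con act on non-reacting outputs and realize convolution, minimum, integer
scaling, floor division and convex combination exactly; ConE realizes a
convex combination whose weight is an affine function of external inputs,
with an error that vanishes as the fast/slow rate ratio grows.  ``translate``
maps any calculus formula to a network by structural recursion over these
operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .calculus import (
    Convex,
    DExpr,
    Environment,
    Formula,
    Min,
    One,
    Scale,
    Sum,
    Zero,
    eval_D,
)
from .pmf import Pmf
from .crn import NroSystem, Reaction, ReactionSystem

__all__ = [
    "FreshNamer",
    "RateFreeConfig",
    "ConEConfig",
    "compile_direct",
    "compile_rate_free",
    "compile_multidim",
    "poisson_network",
    "binomial_network",
    "uniform_network",
    "op_sum",
    "op_min",
    "op_mul",
    "op_div",
    "op_con",
    "op_con_external",
    "rename",
    "translate",
]


class FreshNamer:
    """Deterministic source of species names absent from all operand systems."""

    def __init__(self, reserved=()):
        self._reserved: set[str] = set(reserved)
        self._counters: dict[str, int] = {}

    def reserve(self, names) -> None:
        self._reserved.update(names)

    def fresh(self, prefix: str) -> str:
        n = self._counters.get(prefix, 0)
        while True:
            n += 1
            name = f"{prefix}{n}"
            if name not in self._reserved:
                self._counters[prefix] = n
                self._reserved.add(name)
                return name


@dataclass(frozen=True)
class RateFreeConfig:
    """Granularity ``L`` (every f(z)*L must be integral) and the common rate ``k``."""

    L: int
    k: Fraction = Fraction(1)

    def __post_init__(self):
        if int(self.L) < 1:
            raise ValueError("granularity L must be a positive integer")
        object.__setattr__(self, "L", int(self.L))
        object.__setattr__(self, "k", Fraction(self.k))
        if self.k <= 0:
            raise ValueError("common rate k must be positive")


@dataclass(frozen=True)
class ConEConfig:
    """Fast/slow rate ratio ``rho`` and optional input granularity ``L`` for ConE.

    ``rho = k1/k2 > 1`` separates the input-computing reactions from the
    selector; the approximation error shrinks as rho grows.  ``L`` must make
    the evaluated weight times L an integer; when None the weight's
    denominator is used (the smallest admissible granularity).
    """

    rho: Fraction = Fraction(1000)
    L: int | None = None
    k2: Fraction = Fraction(1)

    def __post_init__(self):
        object.__setattr__(self, "rho", Fraction(self.rho))
        object.__setattr__(self, "k2", Fraction(self.k2))
        if self.rho <= 1:
            raise ValueError("rho must be > 1")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.L is not None:
            object.__setattr__(self, "L", int(self.L))
            if self.L < 1:
                raise ValueError("L must be >= 1")


# ---------------------------------------------------------------------------
# Direct compilation of pmfs
# ---------------------------------------------------------------------------


def _support_1d(f: Pmf) -> list[tuple[int, Fraction]]:
    if f.dim != 1:
        raise ValueError("a one-dimensional pmf is required")
    return [(z, pr) for (z,), pr in f.items()]


def compile_direct(f: Pmf) -> NroSystem:
    """Leader-selection network whose absorption law of ``OUT`` equals ``f`` exactly.

    For support ``(z_1..z_n)``: payload species ``X{i}`` start at ``z_i``;
    the leader ``Z`` (one copy) fires ``Z ->^{f(z_i)} C{i}`` selecting branch
    i, then ``X{i} + C{i} -> C{i} + OUT`` transfers the payload.  2n
    reactions, 2n+2 species.
    """
    pts = _support_1d(f)
    species = ["Z"]
    init = {"Z": 1}
    reactions = []
    for i, (z, pr) in enumerate(pts, 1):
        x, cat = f"X{i}", f"C{i}"
        species += [x, cat]
        init[x] = z
        reactions.append(Reaction(["Z"], [cat], pr))
        reactions.append(Reaction([x, cat], [cat, "OUT"]))
    species.append("OUT")
    return NroSystem(species, reactions, init, outputs=["OUT"])


def compile_rate_free(f: Pmf, cfg: RateFreeConfig) -> NroSystem:
    """Direct compiler variant with all rates equal to ``cfg.k``.

    Branch probabilities are moved from the selector rates into counts of
    catalyst species ``F{i}`` initialized at ``f(z_i) * L``; the selection
    race then picks branch i with probability proportional to that count.
    """
    pts = _support_1d(f)
    for z, pr in pts:
        scaled = pr * cfg.L
        if scaled.denominator != 1:
            raise ValueError(
                f"granularity L={cfg.L} does not make f({z})*L integral; "
                f"L must be a multiple of {pr.denominator}"
            )
    species = ["Z"]
    init = {"Z": 1}
    reactions = []
    for i, (z, pr) in enumerate(pts, 1):
        x, cat, fuel = f"X{i}", f"C{i}", f"F{i}"
        species += [x, cat, fuel]
        init[x] = z
        init[fuel] = int(pr * cfg.L)
        reactions.append(Reaction(["Z", fuel], [cat], cfg.k))
        reactions.append(Reaction([x, cat], [cat, "OUT"], cfg.k))
    species.append("OUT")
    return NroSystem(species, reactions, init, outputs=["OUT"])


def compile_multidim(f: Pmf) -> NroSystem:
    """Joint-pmf compiler: one selector per support point, one output per axis.

    ``Z ->^{f(z_i)} SEL{i}`` picks point i; for each dimension d the payload
    ``X{i}_{d}`` (initialized at ``z_i[d]``) is transferred to ``OUT{d}``
    catalysed by ``SEL{i}``.  The joint absorption law of (OUT1..OUTm)
    equals ``f`` exactly.
    """
    pts = list(f.items())
    if not pts:
        raise ValueError("empty support")
    m = f.dim
    species = ["Z"]
    init = {"Z": 1}
    reactions = []
    for i, (z, pr) in enumerate(pts, 1):
        sel = f"SEL{i}"
        species.append(sel)
        reactions.append(Reaction(["Z"], [sel], pr))
        for d in range(1, m + 1):
            x = f"X{i}_{d}"
            species.append(x)
            init[x] = z[d - 1]
            reactions.append(Reaction([x, sel], [sel, f"OUT{d}"]))
    outs = [f"OUT{d}" for d in range(1, m + 1)]
    species.extend(outs)
    return NroSystem(species, reactions, init, outputs=outs)


# ---------------------------------------------------------------------------
# Special stationary networks
# ---------------------------------------------------------------------------


def poisson_network(k1, k2) -> ReactionSystem:
    """Birth-death network ``0 ->^{k1} L; L ->^{k2} 0``: stationary Poisson(k1/k2).

    The chain is infinite; exact analysis requires truncation of the state
    space (see :func:`crndist.ctmc.enumerate_states` caps).
    """
    return ReactionSystem(
        ["L"],
        [Reaction([], ["L"], Fraction(k1)), Reaction(["L"], [], Fraction(k2))],
        {"L": 0},
    )


def binomial_network(k1, k2, K: int, M: int = 0) -> ReactionSystem:
    """Two-species exchange ``L1 <->^{k1,k2} L2`` with L1+L2 = K conserved.

    Stationary marginals are Binomial(K, k2/(k1+k2)) for L1 and
    Binomial(K, k1/(k1+k2)) for L2, independent of the split M.
    """
    K, M = int(K), int(M)
    if K < 0 or not 0 <= M <= K:
        raise ValueError("need K >= 0 and 0 <= M <= K")
    return ReactionSystem(
        ["L1", "L2"],
        [Reaction(["L1"], ["L2"], Fraction(k1)), Reaction(["L2"], ["L1"], Fraction(k2))],
        {"L1": K - M, "L2": M},
    )


def uniform_network(K: int, M: int = 0, k=Fraction(1)) -> ReactionSystem:
    """Exchange plus direct-competition network: stationary uniform on {0..K}.

    Four reactions with a common rate; total count K is conserved and each
    of the K+1 configurations has stationary probability 1/(K+1) regardless
    of the initial split M.
    """
    K, M = int(K), int(M)
    if K < 0 or not 0 <= M <= K:
        raise ValueError("need K >= 0 and 0 <= M <= K")
    k = Fraction(k)
    return ReactionSystem(
        ["L1", "L2"],
        [
            Reaction(["L1"], ["L2"], k),
            Reaction(["L2"], ["L1"], k),
            Reaction(["L1", "L2"], ["L1", "L1"], k),
            Reaction(["L1", "L2"], ["L2", "L2"], k),
        ],
        {"L1": K - M, "L2": M},
    )


# ---------------------------------------------------------------------------
# NRO-CRS operators
# ---------------------------------------------------------------------------


def rename(c: ReactionSystem, new: str, old: str) -> ReactionSystem:
    """Replace every occurrence of species ``old`` by ``new`` (new must be fresh)."""
    if old not in c.species:
        raise ValueError(f"{old!r} is not a species of the system")
    if new in c.species:
        raise ValueError(f"{new!r} is already a species of the system")

    def sub(name: str) -> str:
        return new if name == old else name

    species = [sub(s) for s in c.species]
    reactions = [
        Reaction(
            {sub(s): n for s, n in rx.reactants},
            {sub(s): n for s, n in rx.products},
            rx.rate,
        )
        for rx in c.reactions
    ]
    init = {sub(s): n for s, n in c.init.items()}
    if isinstance(c, NroSystem):
        return NroSystem(species, reactions, init, [sub(s) for s in c.outputs])
    return ReactionSystem(species, reactions, init)


def _prep_operands(
    c1: NroSystem, o1: str, c2: NroSystem | None, o2: str | None, namer: FreshNamer | None
):
    """Check outputs, make operand species sets disjoint, and return a namer."""
    if o1 not in c1.outputs:
        raise ValueError(f"{o1!r} is not an output of the first operand")
    if c2 is not None and o2 not in c2.outputs:
        raise ValueError(f"{o2!r} is not an output of the second operand")
    if namer is None:
        namer = FreshNamer()
    namer.reserve(c1.species)
    if c2 is not None:
        clash = set(c1.species) & set(c2.species)
        for s in sorted(clash):
            fresh = namer.fresh("S")
            c2 = rename(c2, fresh, s)
            if s == o2:
                o2 = fresh
        namer.reserve(c2.species)
    return c1, o1, c2, o2, namer


def _merge(c1: NroSystem, c2: NroSystem | None, *fresh: str):
    species = list(c1.species) + (list(c2.species) if c2 is not None else [])
    clash = set(fresh) & set(species)
    if clash:
        raise ValueError(f"fresh species {sorted(clash)} collide with operand species")
    reactions = list(c1.reactions) + (list(c2.reactions) if c2 is not None else [])
    init = dict(c1.init)
    if c2 is not None:
        init.update(c2.init)
    return species, reactions, init


def op_sum(c1: NroSystem, o1: str, c2: NroSystem, o2: str, out: str | None = None,
           namer: FreshNamer | None = None) -> NroSystem:
    """Sum operator: adds ``o1 -> out`` and ``o2 -> out`` (convolution of outputs)."""
    c1, o1, c2, o2, namer = _prep_operands(c1, o1, c2, o2, namer)
    out = out or namer.fresh("OUT")
    species, reactions, init = _merge(c1, c2, out)
    species.append(out)
    reactions += [Reaction([o1], [out]), Reaction([o2], [out])]
    return NroSystem(species, reactions, init, outputs=[out])


def op_min(c1: NroSystem, o1: str, c2: NroSystem, o2: str, out: str | None = None,
           namer: FreshNamer | None = None) -> NroSystem:
    """Min operator: adds ``o1 + o2 -> out`` (minimum of outputs)."""
    c1, o1, c2, o2, namer = _prep_operands(c1, o1, c2, o2, namer)
    out = out or namer.fresh("OUT")
    species, reactions, init = _merge(c1, c2, out)
    species.append(out)
    reactions.append(Reaction([o1, o2], [out]))
    return NroSystem(species, reactions, init, outputs=[out])


def op_mul(c1: NroSystem, o1: str, k: int, out: str | None = None,
           namer: FreshNamer | None = None) -> NroSystem:
    """Mul operator: adds ``o1 -> k*out`` (k = 0 gives ``o1 -> 0``, the zero pmf)."""
    k = int(k)
    if k < 0:
        raise ValueError("k must be a non-negative integer")
    c1, o1, _, _, namer = _prep_operands(c1, o1, None, None, namer)
    out = out or namer.fresh("OUT")
    species, reactions, init = _merge(c1, None, out)
    species.append(out)
    reactions.append(Reaction([o1], {out: k}))
    return NroSystem(species, reactions, init, outputs=[out])


def op_div(c1: NroSystem, o1: str, k: int, out: str | None = None,
           namer: FreshNamer | None = None) -> NroSystem:
    """Div operator: adds ``k*o1 -> out`` (floor division of the output)."""
    k = int(k)
    if k < 1:
        raise ValueError("k must be a positive integer")
    c1, o1, _, _, namer = _prep_operands(c1, o1, None, None, namer)
    out = out or namer.fresh("OUT")
    species, reactions, init = _merge(c1, None, out)
    species.append(out)
    reactions.append(Reaction({o1: k}, [out]))
    return NroSystem(species, reactions, init, outputs=[out])


def op_con(c1: NroSystem, o1: str, c2: NroSystem, o2: str, p, out: str | None = None,
           namer: FreshNamer | None = None) -> NroSystem:
    """Con operator: a one-shot selector routes o1 or o2 to ``out``.

    ``Z ->^p R1; Z ->^{1-p} R2`` (one leader Z) followed by the catalysed
    transfers ``o1 + R1 -> R1 + out`` and ``o2 + R2 -> R2 + out``; the output
    law is the exact convex combination with weight p.
    """
    p = Fraction(p)
    if not 0 <= p <= 1:
        raise ValueError(f"weight {p} outside [0, 1]")
    c1, o1, c2, o2, namer = _prep_operands(c1, o1, c2, o2, namer)
    out = out or namer.fresh("OUT")
    z, r1, r2 = (namer.fresh(s) for s in ("Z", "R", "R"))
    species, reactions, init = _merge(c1, c2, z, r1, r2, out)
    species += [z, r1, r2, out]
    init[z] = 1
    if p > 0:
        reactions.append(Reaction([z], [r1], p))
    if p < 1:
        reactions.append(Reaction([z], [r2], 1 - p))
    reactions += [
        Reaction([o1, r1], [r1, out]),
        Reaction([o2, r2], [r2, out]),
    ]
    return NroSystem(species, reactions, init, outputs=[out])


def op_con_external(
    c1: NroSystem,
    o1: str,
    c2: NroSystem,
    o2: str,
    d: DExpr,
    env: Environment,
    cfg: ConEConfig | None = None,
    out: str | None = None,
    namer: FreshNamer | None = None,
) -> NroSystem:
    """ConE operator: convex combination with an externally-controlled weight.

    The weight ``w = eval_D(d, env)`` is loaded as molecule counts: ``CIN``
    starts at ``w*L`` and ``TOT`` at ``L``.  Fast reactions (rate rho*k2)
    compute the pair (w*L, (1-w)*L) into catalysts; slow reactions let the
    leader ``Z`` pick branch 1 with probability approaching w as rho grows::

        CIN ->^{rho k2} CAT1 + CAT2     TOT + CAT2 ->^{rho k2} 0
        Z + CAT1 ->^{k2} G1             Z + TOT ->^{k2} G2
        o1 + G1 -> G1 + out             o2 + G2 -> G2 + out

    A constant expression (no variables) needs no approximation and is
    delegated to the exact :func:`op_con`.
    """
    if not d.variables:
        return op_con(c1, o1, c2, o2, eval_D(d, {}), out, namer)
    cfg = cfg or ConEConfig()
    w = eval_D(d, env)
    L = cfg.L if cfg.L is not None else w.denominator
    scaled = w * L
    if scaled.denominator != 1:
        raise ValueError(
            f"granularity L={L} does not make the weight {w} integral; "
            f"the minimal admissible L is {w.denominator}"
        )
    c1, o1, c2, o2, namer = _prep_operands(c1, o1, c2, o2, namer)
    out = out or namer.fresh("OUT")
    cin, tot, cat1, cat2, z, g1, g2 = (
        namer.fresh(s) for s in ("CIN", "TOT", "CAT", "CAT", "Z", "G", "G")
    )
    k1 = cfg.rho * cfg.k2
    species, reactions, init = _merge(c1, c2, cin, tot, cat1, cat2, z, g1, g2, out)
    species += [cin, tot, cat1, cat2, z, g1, g2, out]
    init.update({cin: int(scaled), tot: L, z: 1})
    reactions += [
        Reaction([cin], [cat1, cat2], k1),
        Reaction([tot, cat2], [], k1),
        Reaction([z, cat1], [g1], cfg.k2),
        Reaction([z, tot], [g2], cfg.k2),
        Reaction([o1, g1], [g1, out]),
        Reaction([o2, g2], [g2, out]),
    ]
    return NroSystem(species, reactions, init, outputs=[out])


# ---------------------------------------------------------------------------
# Translation of formulas
# ---------------------------------------------------------------------------


def translate(
    f: Formula,
    env: Environment | None = None,
    cfg: ConEConfig | None = None,
) -> NroSystem:
    """Compile a calculus formula into an NRO network with one output species.

    Structural recursion: literals become empty-reaction systems with output
    count 1 (``one``) or 0 (``zero``); Sum/Min/Scale/Convex map to the
    corresponding network operators, with each child's output renamed to a
    fresh internal name before composition.  Convex weights with variables
    use ConE and are approximate (error controlled by ``cfg.rho``);
    everything else is exact.
    """
    env = env or {}
    namer = FreshNamer()

    def leaf(count: int) -> tuple[NroSystem, str]:
        o = namer.fresh("P")
        return NroSystem([o], [], {o: count}, outputs=[o]), o

    def bury(c: NroSystem, o: str) -> tuple[NroSystem, str]:
        # Rename the child's output to a fresh internal name so the
        # composed system has a single declared output.
        fresh = namer.fresh("T")
        return rename(c, fresh, o), fresh

    def tr(node: Formula) -> tuple[NroSystem, str]:
        if isinstance(node, One):
            return leaf(1)
        if isinstance(node, Zero):
            return leaf(0)
        if isinstance(node, (Sum, Min)):
            ca, oa = bury(*tr(node.left))
            cb, ob = bury(*tr(node.right))
            out = namer.fresh("OUT")
            op = op_sum if isinstance(node, Sum) else op_min
            return op(ca, oa, cb, ob, out, namer), out
        if isinstance(node, Scale):
            c, o = bury(*tr(node.child))
            mid = namer.fresh("OUT")
            cm = op_mul(c, o, node.k1, mid, namer)
            cm, om = bury(cm, mid)
            out = namer.fresh("OUT")
            return op_div(cm, om, node.k2, out, namer), out
        if isinstance(node, Convex):
            ca, oa = bury(*tr(node.left))
            cb, ob = bury(*tr(node.right))
            out = namer.fresh("OUT")
            if node.weight.variables:
                return (
                    op_con_external(ca, oa, cb, ob, node.weight, env, cfg, out, namer),
                    out,
                )
            return op_con(ca, oa, cb, ob, eval_D(node.weight, {}), out, namer), out
        raise TypeError(f"not a Formula node: {node!r}")

    system, _ = tr(f)
    return system
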