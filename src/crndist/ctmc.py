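"""Exact CTMC analysis of reaction systems.

The stochastic semantics of a reaction system is a continuous-time Markov
chain on molecule-count vectors.  This module enumerates the reachable
state space, solves the global balance equations ``pi Q = 0`` for
irreducible chains, and computes absorption distributions over terminal
states for terminating (non-reacting-output) networks — all in exact
rational arithmetic at the scales the constructions produce, with a
floating-point sparse fallback behind the same interface for larger
spaces.

Every compiled NRO network in this package has an *acyclic* state graph
(each reaction strictly consumes some non-renewable resource), so its
absorption distribution is obtained by a single exact forward pass in
topological order rather than a linear solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .crn import ReactionSystem, propensity
from .pmf import Pmf

__all__ = [
    "StateSpace",
    "StateDistribution",
    "StateSpaceCapExceeded",
    "enumerate_states",
    "stationary",
    "absorption",
    "marginal",
    "EXACT_SOLVE_LIMIT",
    "EXACT_FORWARD_LIMIT",
    "DEFAULT_MAX_STATES",
]

EXACT_SOLVE_LIMIT = 2000  # above this, dense linear solves switch to floating point
EXACT_FORWARD_LIMIT = 30_000  # acyclic forward propagation stays exact up to here
DEFAULT_MAX_STATES = 100_000
_FLOAT_RESIDUAL_TOL = 1e-9


class StateSpaceCapExceeded(RuntimeError):
    """Raised when BFS exceeds ``max_states`` (non-finite or too-large chain)."""

    def __init__(self, cap: int, frontier: int):
        super().__init__(
            f"state-space cap {cap} exceeded with {frontier} states still on the "
            "frontier; the chain is infinite or needs truncation"
        )
        self.cap = cap
        self.frontier = frontier


@dataclass
class StateSpace:
    """Reachable configurations of a reaction system with generator entries."""

    system: ReactionSystem
    states: list[tuple[int, ...]]
    transitions: list[tuple[int, int, Fraction]]  # (from, to, rate > 0)
    initial: int
    terminal: list[bool]
    index: dict[tuple[int, ...], int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {s: i for i, s in enumerate(self.states)}

    def __len__(self) -> int:
        return len(self.states)

    def terminal_indices(self) -> list[int]:
        return [i for i, t in enumerate(self.terminal) if t]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.states)))
        g.add_edges_from((i, j) for i, j, _ in self.transitions)
        return g


@dataclass
class StateDistribution:
    """Exact distribution over state indices (stationary or absorption)."""

    space: StateSpace
    probs: dict[int, Fraction]
    kind: str  # "stationary" | "absorption"

    def __post_init__(self):
        total = sum(self.probs.values(), Fraction(0))
        if total != 1:
            raise ValueError(f"state probabilities sum to {total}, expected 1")


def enumerate_states(
    c: ReactionSystem, max_states: int = DEFAULT_MAX_STATES
) -> StateSpace:
    """Breadth-first closure of the initial state under positive-propensity reactions.

    Deterministic given the species and reaction orders.  Raises
    :class:`StateSpaceCapExceeded` when more than ``max_states`` states are found.
    """
    if max_states < 1:
        raise ValueError("max_states must be >= 1")
    species = c.species
    deltas = []
    for rx in c.reactions:
        d = rx.net_change()
        deltas.append(tuple(d.get(s, 0) for s in species))

    x0 = c.initial_state()
    states = [x0]
    index = {x0: 0}
    transitions: list[tuple[int, int, Fraction]] = []
    terminal: list[bool] = []
    head = 0
    while head < len(states):
        x = states[head]
        xmap = dict(zip(species, x))
        out_any = False
        for rx, delta in zip(c.reactions, deltas):
            a = propensity(rx, xmap)
            if a == 0:
                continue
            y = tuple(xi + di for xi, di in zip(x, delta))
            j = index.get(y)
            if j is None:
                if len(states) >= max_states:
                    raise StateSpaceCapExceeded(max_states, len(states) - head)
                j = len(states)
                index[y] = j
                states.append(y)
            if j != head:  # self-loops cannot occur under mass action, but be safe
                transitions.append((head, j, a))
                out_any = True
        terminal.append(not out_any)
        head += 1
    return StateSpace(c, states, transitions, 0, terminal, index)


# ---------------------------------------------------------------------------
# Exact linear algebra helpers
# ---------------------------------------------------------------------------


def _solve_fraction(rows: list[list[Fraction]], rhs: list[Fraction]) -> list[Fraction]:
    """Gaussian elimination with partial (first-nonzero) pivoting over Q."""
    n = len(rows)
    a = [row[:] + [b] for row, b in zip(rows, rhs)]
    perm = list(range(n))
    for col in range(n):
        pivot = next((r for r in range(col, n) if a[r][col] != 0), None)
        if pivot is None:
            raise np.linalg.LinAlgError("singular exact system")
        a[col], a[pivot] = a[pivot], a[col]
        inv = 1 / a[col][col]
        a[col] = [v * inv for v in a[col]]
        for r in range(n):
            if r != col and a[r][col] != 0:
                f = a[r][col]
                a[r] = [vr - f * vc for vr, vc in zip(a[r], a[col])]
    return [a[i][n] for i in range(n)]


def stationary(space: StateSpace) -> StateDistribution:
    """Unique solution of ``pi Q = 0`` with ``sum(pi) = 1`` for an irreducible chain."""
    n = len(space)
    g = space.graph()
    if not nx.is_strongly_connected(g):
        raise ValueError(
            "state space is not irreducible; use absorption() for terminating systems"
        )
    if n <= EXACT_SOLVE_LIMIT:
        # Columns of Q^T; replace the last equation with the normalization.
        rows = [[Fraction(0)] * n for _ in range(n)]
        for i, j, rate in space.transitions:
            rows[j][i] += rate
            rows[i][i] -= rate
        rows[n - 1] = [Fraction(1)] * n
        rhs = [Fraction(0)] * (n - 1) + [Fraction(1)]
        pi = _solve_fraction(rows, rhs)
        probs = {i: p for i, p in enumerate(pi) if p != 0}
        if any(p < 0 for p in probs.values()):
            raise ArithmeticError("negative stationary probability (inconsistent system)")
    else:
        q = sp.lil_matrix((n, n))
        for i, j, rate in space.transitions:
            q[j, i] += float(rate)
            q[i, i] -= float(rate)
        q[n - 1, :] = 1.0
        rhs = np.zeros(n)
        rhs[n - 1] = 1.0
        pi = spla.spsolve(sp.csc_matrix(q), rhs)
        if abs(pi.sum() - 1.0) > _FLOAT_RESIDUAL_TOL:
            raise ArithmeticError("float stationary solve failed residual check")
        probs = {i: Fraction(float(p)) for i, p in enumerate(pi) if p > 1e-15}
        total = sum(probs.values(), Fraction(0))
        probs = {i: p / total for i, p in probs.items()}
    return StateDistribution(space, probs, "stationary")


def _check_singleton_bsccs(space: StateSpace, g: nx.DiGraph) -> None:
    cond = nx.condensation(g)
    for comp in cond.nodes:
        if cond.out_degree(comp) == 0:
            members = cond.nodes[comp]["members"]
            if len(members) > 1:
                raise ValueError(
                    f"bottom strongly connected component {sorted(members)[:8]}... "
                    "is not a single terminal state; use stationary() on it"
                )


def absorption(space: StateSpace) -> StateDistribution:
    """Exact distribution over terminal states reached from the initial state.

    Requires every bottom SCC to be a singleton terminal state (true for all
    non-reacting-output constructions here).  Acyclic state graphs — the
    generic case for these networks — are handled by exact forward
    propagation of probability mass through embedded jump probabilities;
    graphs with transient cycles fall back to a first-step linear solve.
    """
    g = space.graph()
    _check_singleton_bsccs(space, g)
    n = len(space)

    out_rate = [Fraction(0)] * n
    succ: list[list[tuple[int, Fraction]]] = [[] for _ in range(n)]
    for i, j, rate in space.transitions:
        out_rate[i] += rate
        succ[i].append((j, rate))

    if nx.is_directed_acyclic_graph(g):
        if n <= EXACT_FORWARD_LIMIT:
            mass = [Fraction(0)] * n
            mass[space.initial] = Fraction(1)
            for i in nx.topological_sort(g):
                if mass[i] == 0 or space.terminal[i]:
                    continue
                total = out_rate[i]
                for j, rate in succ[i]:
                    mass[j] += mass[i] * rate / total
                mass[i] = Fraction(0)
            probs = {i: m for i, m in enumerate(mass) if m != 0}
        else:
            fm = np.zeros(n)
            fm[space.initial] = 1.0
            for i in nx.topological_sort(g):
                if fm[i] == 0.0 or space.terminal[i]:
                    continue
                total = float(out_rate[i])
                for j, rate in succ[i]:
                    fm[j] += fm[i] * float(rate) / total
                fm[i] = 0.0
            total_mass = fm.sum()
            if abs(total_mass - 1.0) > _FLOAT_RESIDUAL_TOL:
                raise ArithmeticError("float forward pass failed residual check")
            probs = {i: Fraction(float(v)) for i, v in enumerate(fm) if v > 1e-15}
            s = sum(probs.values(), Fraction(0))
            probs = {i: v / s for i, v in probs.items()}
        return StateDistribution(space, probs, "absorption")

    # Transient cycles: solve expected-visit equations mu (I - P_TT) = e_init.
    transient = [i for i in range(n) if not space.terminal[i]]
    tpos = {i: k for k, i in enumerate(transient)}
    m = len(transient)
    if m <= EXACT_SOLVE_LIMIT:
        # Solve transposed: (I - P_TT)^T mu = e_init as columns.
        rows = [[Fraction(0)] * m for _ in range(m)]
        for k, i in enumerate(transient):
            rows[k][k] += 1
        for i, j, rate in space.transitions:
            if j in tpos:
                rows[tpos[j]][tpos[i]] -= rate / out_rate[i]
        rhs = [Fraction(0)] * m
        rhs[tpos[space.initial]] = Fraction(1)
        mu = _solve_fraction(rows, rhs)
        probs: dict[int, Fraction] = {}
        for i, j, rate in space.transitions:
            if space.terminal[j]:
                probs[j] = probs.get(j, Fraction(0)) + mu[tpos[i]] * rate / out_rate[i]
    else:
        a = sp.lil_matrix((m, m))
        for k in range(m):
            a[k, k] = 1.0
        for i, j, rate in space.transitions:
            if j in tpos:
                a[tpos[j], tpos[i]] -= float(rate / out_rate[i])
        rhs = np.zeros(m)
        rhs[tpos[space.initial]] = 1.0
        mu = spla.spsolve(sp.csc_matrix(a), rhs)
        acc: dict[int, float] = {}
        for i, j, rate in space.transitions:
            if space.terminal[j]:
                acc[j] = acc.get(j, 0.0) + mu[tpos[i]] * float(rate / out_rate[i])
        total = sum(acc.values())
        if abs(total - 1.0) > _FLOAT_RESIDUAL_TOL:
            raise ArithmeticError("float absorption solve failed residual check")
        probs = {j: Fraction(v) for j, v in acc.items() if v > 1e-15}
        s = sum(probs.values(), Fraction(0))
        probs = {j: v / s for j, v in probs.items()}
    if space.terminal[space.initial]:
        probs = {space.initial: Fraction(1)}
    return StateDistribution(space, probs, "absorption")


def marginal(dist: StateDistribution, species: Sequence[str] | str) -> Pmf:
    """Project a state distribution onto the counts of the named species.

    A single name yields a one-dimensional pmf; several names yield their
    joint pmf in the given order.
    """
    if isinstance(species, str):
        names: tuple[str, ...] = (species,)
    else:
        names = tuple(species)
    order = dist.space.system.species
    try:
        cols = [order.index(s) for s in names]
    except ValueError as e:
        raise KeyError(f"unknown species in {names}") from e
    acc: dict[tuple[int, ...], Fraction] = {}
    for i, pr in dist.probs.items():
        state = dist.space.states[i]
        key = tuple(state[c] for c in cols)
        acc[key] = acc.get(key, Fraction(0)) + pr
    return Pmf(acc, dim=len(names))
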