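"""Gillespie stochastic simulation (direct method).

The operational counterpart of the CTMC semantics: exponential waiting
times with total propensity as rate, and the next reaction drawn with
probability proportional to its propensity.  Used for Monte-Carlo
cross-validation of the exact engine and for chains too large to solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .crn import NroSystem, ReactionSystem
from .pmf import Pmf

__all__ = ["Trajectory", "simulate", "sample_terminal", "occupancy"]


@dataclass
class Trajectory:
    """(time, state) sequence of one run; ``terminal`` means no reaction was enabled."""

    species: tuple[str, ...]
    times: list[float]
    states: list[tuple[int, ...]]
    terminal: bool
    seed: object


def _tables(c: ReactionSystem):
    species = c.species
    idx = {s: i for i, s in enumerate(species)}
    reactant_rows = []
    delta_rows = []
    rates = []
    for rx in c.reactions:
        req = np.zeros(len(species), dtype=np.int64)
        for s, n in rx.reactants:
            req[idx[s]] = n
        d = np.zeros(len(species), dtype=np.int64)
        for s, n in rx.net_change().items():
            d[idx[s]] = n
        reactant_rows.append(req)
        delta_rows.append(d)
        rates.append(float(rx.rate))
    return (
        np.array(reactant_rows, dtype=np.int64).reshape(len(rates), len(species)),
        np.array(delta_rows, dtype=np.int64).reshape(len(rates), len(species)),
        np.array(rates),
    )


def _propensities(x, req, rates):
    # Combinatorial mass action prod_s C(x_s, r_s); reactant orders here are
    # at most 2 per species, so an explicit product is cheap and exact enough.
    a = rates.copy()
    for r in range(req.shape[0]):
        for s in np.nonzero(req[r])[0]:
            n = req[r, s]
            xs = x[s]
            if xs < n:
                a[r] = 0.0
                break
            c = 1.0
            for t in range(n):
                c *= (xs - t) / (t + 1)
            a[r] *= c
    return a


def simulate(
    c: ReactionSystem,
    seed,
    t_max: float = np.inf,
    stop_on_terminal: bool = True,
    max_events: int | None = None,
    _tables_cache=None,
) -> Trajectory:
    """One direct-method run from the initial state; reproducible given ``seed``."""
    if not np.isfinite(t_max) and not stop_on_terminal and max_events is None:
        raise ValueError("need t_max, stop_on_terminal or max_events to bound the run")
    rng = np.random.default_rng(seed)
    req, delta, rates = _tables_cache if _tables_cache is not None else _tables(c)
    x = np.array(c.initial_state(), dtype=np.int64)
    t = 0.0
    times = [0.0]
    states = [tuple(int(v) for v in x)]
    terminal = False
    events = 0
    while True:
        a = _propensities(x, req, rates) if len(rates) else np.zeros(0)
        total = a.sum()
        if total == 0.0:
            terminal = True
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        r = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, total), side="right"))
        r = min(r, len(rates) - 1)
        x = x + delta[r]
        times.append(t)
        states.append(tuple(int(v) for v in x))
        events += 1
        if max_events is not None and events >= max_events:
            break
    return Trajectory(c.species, times, states, terminal, seed)


def sample_terminal(
    c: NroSystem, n: int, seed, t_max: float = np.inf, max_events: int = 10_000_000
):
    """Empirical pmf of the output counts over ``n`` independent terminal samples.

    Each run gets its own generator derived from ``(seed, run index)`` so
    batches are order-independent.  Returns ``(pmf, censored)`` where
    ``censored`` counts runs cut at ``t_max``/``max_events`` before
    terminating (excluded from the pmf).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cols = [c.species.index(s) for s in c.outputs]
    tables = _tables(c)
    counts: dict[tuple[int, ...], int] = {}
    censored = 0
    for run in range(n):
        traj = simulate(
            c, seed=[seed, run], t_max=t_max, max_events=max_events,
            _tables_cache=tables,
        )
        if not traj.terminal:
            censored += 1
            continue
        key = tuple(traj.states[-1][col] for col in cols)
        counts[key] = counts.get(key, 0) + 1
    done = n - censored
    if done == 0:
        raise RuntimeError("no run terminated; raise t_max or max_events")
    pmf = Pmf({k: Fraction(v, done) for k, v in counts.items()}, dim=len(cols))
    return pmf, censored


def occupancy(
    c: ReactionSystem,
    species: str,
    seed,
    n_events: int,
    burn_in: float = 0.1,
) -> Pmf:
    """Time-averaged occupancy distribution of one species over a long run.

    Simulates ``n_events`` reaction events, discards the first ``burn_in``
    fraction, and weights each visited count by the time spent there — an
    ergodic estimate of the stationary marginal for irreducible chains.
    """
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in must be in [0, 1)")
    traj = simulate(c, seed=seed, stop_on_terminal=True, max_events=n_events)
    col = c.species.index(species)
    if len(traj.times) < 2:
        return Pmf({traj.states[-1][col]: 1})
    t0 = traj.times[-1] * burn_in
    weights: dict[int, float] = {}
    for k in range(len(traj.times) - 1):
        start, end = traj.times[k], traj.times[k + 1]
        if end <= t0:
            continue
        dur = end - max(start, t0)
        count = traj.states[k][col]
        weights[count] = weights.get(count, 0.0) + dur
    total = sum(weights.values())
    # quantize to a common denominator so the result is a valid exact Pmf
    denom = 10**12
    q = {k: round(v / total * denom) for k, v in weights.items()}
    drift = denom - sum(q.values())
    top = max(q, key=q.get)
    q[top] += drift
    return Pmf({k: Fraction(v, denom) for k, v in q.items() if v > 0})
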