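# Methods

## Model

A chemical reaction system (CRS) is a triple `(Λ, R, x0)`: species, mass-action
reactions with rational rate constants, and an integer initial state.  Its
stochastic semantics is a continuous-time Markov chain (CTMC) on molecule-count
vectors: a reaction `τ` with reactant multiset `r_τ` and rate `k_τ` fires in
state `x` with propensity

    α_τ(x) = k_τ · ∏_s C(x(s), r_τ(s)),

the combinatorial (distinct-combinations) convention of stochastic mass-action
kinetics.  For the networks this package builds, reactants are unary or
distinct species, where the convention reduces to the plain product; the only
construction with a repeated reactant (the Div operator's `k·o → out`) has a
terminal state that does not depend on rates, so the choice cannot affect any
distribution computed here.  It is nonetheless recorded as an assumption,
because the general repeated-reactant case admits other conventions.

The *limit distribution* of a species is the `t → ∞` law of its count.  Two
regimes matter:

* **Irreducible finite chains** (the binomial and uniform special networks):
  the limit is the unique solution of the global balance equations `πQ = 0`
  with `Σπ = 1`.
* **Terminating networks**: every bottom strongly connected component of the
  reachable state graph is a single terminal state, and the limit is the
  *absorption distribution* — the probability of ending in each terminal
  state.

## Non-reacting outputs and compositionality

A network is *non-reacting-output* (NRO) when its declared output species
never appear as reactants.  Output counts are then monotone, the network runs
to termination, and — crucially — output species of one network can be safely
consumed by a downstream combinator without disturbing the upstream dynamics.
All compiled networks here are NRO by construction and `validate_nro`
re-checks the property as diagnostics.

## Compiling a pmf

Given a finite-support pmf `f` on ℕ with support `(z_1..z_n)`, the direct
compiler emits, for each support point, a payload species `X_i` (initial count
`z_i`) and a branch catalyst `C_i`, plus a one-copy leader `Z`:

    Z →(f(z_i)) C_i          (selection: exactly one branch wins)
    X_i + C_i → C_i + OUT    (transfer: the winning payload is copied out)

2n reactions and 2n+2 species.  The first firing is a race among the selector
reactions whose win probabilities are exactly `f(z_i)`; afterwards the chosen
branch drains deterministically, so the absorption law of `OUT` equals `f`
bit-exactly.  The rate-free variant moves the branch probability from rates to
molecule counts: `Z + F_i →(k) C_i` with `x0(F_i) = f(z_i)·L`, where the
granularity `L` makes every `f(z_i)·L` an integer; all reactions then share
one rate `k` and the selection race is won with probability proportional to
the catalyst count.  The multidimensional compiler uses one selector species
per support point and one payload per (point, axis), giving the exact joint
law of `(OUT_1..OUT_m)`.

Countable-support pmfs are handled by `truncate`: keep an initial segment of
an enumeration whose retained mass exceeds `1 − ε/2` and renormalize, which
bounds the L1 distance to the original below `ε`.

## The distribution calculus

Formulas are generated by

    P := (P + P) | min(P, P) | k·P | (P)_D : P | one | zero
    D := p | p·c + D

with `k = k1/k2` a non-negative rational and `D` an affine probability
expression over environmental inputs valued in `[0,1]`.  Semantics: `+` is
convolution, `min` the pairwise minimum, `k·P` multiplies the support by `k1`
then floor-divides by `k2` (the order matters and is fixed:
multiply-then-divide), and `(P1)_D:P2` is the mixture with weight `⟦D⟧_E`.
`k = 0` maps all mass to the point 0.  Every finite pmf is denoted by some
formula: the completeness compiler builds a right-nested chain of convex
choices over `z_i·one` with residual-mass weights
`f(z_i) / (1 − Σ_{j<i} f(z_j))`, which renormalizes the remaining mass at
each level and makes the round trip `evaluate(pmf_to_formula(p)) = p` exact.
(The equivalent product form `∏_{j<i}(1 − f(z_j))` is only correct for
supports of size ≤ 2; the residual-sum denominator is the general one.)

The surface grammar is this package's own design (the calculus has no
canonical one): `(P)[D]:(Q)` for convex choice, `q*P` for scaling, infix `+`,
`min(P,Q)`, with decimal literals converted to exact rationals.  Convex binds
tighter than `+` and associates to the right; the printer emits fully
parenthesized text that re-parses to an equal tree.  A repeated variable
inside one `D` is rejected rather than merged, since the affine form leaves
the intended meaning ambiguous.

## Network operators and translation

Each calculus operation has a network counterpart acting on NRO outputs:

| operator | added reactions |
|---|---|
| Sum   | `o1 → out`, `o2 → out` |
| Min   | `o1 + o2 → out` |
| Mul k | `o1 → k·out` (`k = 0`: `o1 → ∅`) |
| Div k | `k·o1 → out` |
| Con p | `Z →(p) R1`, `Z →(1−p) R2`, `o1+R1 → R1+out`, `o2+R2 → R2+out` |

Operand species sets are made disjoint automatically (deterministic fresh
names from a counter-based namer, so compiled systems are reproducible
byte-for-byte).  Sum, Min, Mul, Div and Con are *exact*: the absorption law
of `out` equals the corresponding pmf operation applied to the operand laws,
which the test suite verifies against the independent pmf-algebra
implementation on seeded random operands.

The externally-controlled mixture ConE loads the weight `w = ⟦D⟧_E` as
molecule counts — `CIN` at `w·L`, `TOT` at `L` — and computes the pair
`(w·L, (1−w)·L)` with fast reactions while a slow leader race selects the
branch:

    CIN →(ρk) CAT1 + CAT2      TOT + CAT2 →(ρk) ∅
    Z + CAT1 →(k) G1           Z + TOT →(k) G2
    o1 + G1 → G1 + out         o2 + G2 → G2 + out

If the fast phase completed before the leader fired, the race odds are
exactly `w·L : (1−w)·L`; the error comes from early leader firings and
scales like `L/ρ` (measured: L1 ≈ 0.52, 0.096, 0.011 at ρ = 10, 100, 1000
with `L = 10` on point-mass operands at 10 and 20).  Hence the defaults:
`ρ = 1000`, and `L` equal to the denominator of the evaluated weight — the
smallest admissible granularity, which also minimizes the number of fast
events racing the leader.  Both are configuration values, not claims; a
constant weight bypasses the approximation entirely and uses the exact Con.
An externally-controlled two-state switch is the special case of ConE with
point-mass operands.

`translate` maps formulas to networks by structural recursion, renaming each
child's output to a fresh internal name before composing so the result has a
single declared output.  `k·P` always goes through Div∘Mul, including the
trivial `k2 = 1` relay — the uniform rule keeps the translation a
homomorphism at the cost of one extra relay reaction.

## Special networks

* **Poisson**: `∅ →(k1) λ; λ →(k2) ∅` — stationary Poisson(k1/k2).  The chain
  is infinite; exact analysis requires truncation, and the state-space
  enumerator reports a capped-explosion error rather than looping.  The
  package verifies this network by long-run simulated occupancy.
* **Binomial**: `λ1 ⇄ λ2` with rates `k1, k2` and `λ1+λ2 = K` conserved.
  Detailed balance on the birth–death chain in `j = x(λ2)` gives stationary
  marginals Binomial(K, k2/(k1+k2)) for `λ1` and Binomial(K, k1/(k1+k2)) for
  `λ2`; the success probabilities follow from detailed balance and are
  re-verified by the exact solver.
* **Uniform**: the exchange pair plus the direct-competition pair
  `λ1+λ2 → 2λ1 | 2λ2`, all at one common rate.  The total `K` is conserved,
  the chain on the K+1 configurations `(K−j, j)` is irreducible, and the
  balance equations are satisfied by the constant vector: every configuration
  has probability `1/(K+1)` regardless of the initial split.  (The chain has
  K+1 reachable configurations, `j = 0..K` — an easy off-by-one to make; the
  closed form sums K+1 terms of `1/(K+1)` and the enumerator follows that
  count.)

These compact networks have reacting outputs, so they do not compose with the
NRO operators; they are verified through `stationary`, not `absorption`.

## Exact analysis

State spaces are enumerated breadth-first from `x0` with a deterministic
order (reaction order, then species order), so state indices and serialized
results are reproducible.  Numerical policy:

* All probabilities, rates and solves are exact `Fraction` arithmetic by
  default; no floating point enters any equality-checked path.
* Every NRO construction here has an *acyclic* state graph (each reaction
  strictly decreases a weighted species total), so the absorption
  distribution is computed by forward propagation of mass through embedded
  jump probabilities in topological order — O(edges) exact arithmetic, kept
  exact up to 30,000 states.
* Cyclic-but-absorbing chains use expected-visit linear equations; irreducible
  chains solve `πQ = 0` by fraction-preserving Gaussian elimination.  Dense
  exact solves are used up to 2,000 states; beyond either limit the same
  interfaces switch to scipy sparse floating-point solves with a residual
  check (and results are then approximate, never equality-asserted).
* Default state-space cap: 100,000 states.

## Stochastic simulation

The simulator is the plain direct method (one exponential and one categorical
draw per event) — the systems here are tiny and clarity wins over the
next-reaction method.  Each run in a batch derives its generator from
`(master seed, run index)`, so batches are order-independent and individual
runs can be replayed.  Terminal sampling reports censored runs (cut at
`t_max`/`max_events`) separately; the time-average occupancy estimator for
irreducible chains discards a 10% burn-in fraction by default and quantizes
the weights to denominator 10^12 to return a valid exact pmf.

## Synthetic inputs

The fixture generator draws exact random pmfs as integer compositions of a
random denominator bounded by 64 — small denominators keep the state spaces
of compiled fixtures within the exact-solver range — with support size,
support values and dimension bounded by the fixture spec; formulas are drawn
over all node kinds with bounded depth.  Generation is a pure function of the
spec (seeded), so every fixture is reproducible.  These fixtures exercise the
full algebra but are not meant to emulate any laboratory reality: real
molecular implementations face leak reactions, rate uncertainty, and
non-ideal mixing that the exact CTMC semantics deliberately excludes, so
passing tests certify the constructions *given* mass-action semantics, not a
wet-lab device.

## Problem sizes and verification scope

The verification suite uses random pmfs with support ≤ 4 and values ≤ 8
(operators: support ≤ 3, values ≤ 6), formulas of depth ≤ 3 whose denoted
support stays within 30, uniform networks up to K = 25, binomial up to
K = 12, 10^5-event occupancy runs, and 10^4-run terminal sampling.  These
sizes keep every exact solve in rational arithmetic while covering all
construction branches; the constructions themselves scale further (the
engine switches to sparse floating point past the exact thresholds).

## Known limitations

* Convolution and minimum are defined for one-dimensional pmfs only, matching
  the calculus's restriction to support in ℕ; multidimensional operands are
  rejected.
* The ConE error has no closed-form rate-to-error bound here; only monotone
  improvement in ρ is asserted (and observed).
* The multiplicative-error measure `e_m(f1,f2) = max_n min(f1/f2, f2/f1)` is
  implemented literally as a best-case ratio; with the zero-mass convention
  (one-sided zero → 0, two-sided zero → skip) it equals 1 whenever the pmfs
  share any equal-mass point, so it flags support mismatch rather than
  worst-case deviation.  The convention is isolated behind one function so it
  can be swapped.
* No SBML import/export, no transient analysis, no tau-leaping or fluid
  approximations.
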