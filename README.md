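# crndist

**Programming discrete probability distributions with stochastic chemical
reaction networks.**

Molecular systems with species in low copy numbers are intrinsically
stochastic: the state of a chemical reaction network (CRN) under mass-action
kinetics is a continuous-time Markov chain over molecule counts, and the
long-run count of a species is a random variable.  `crndist` treats that
randomness as a computational resource.  It answers, constructively, the
question: *given a target probability mass function (pmf), which network of
chemical reactions has a species whose limit distribution is exactly that
pmf?* — and provides the machinery to verify the answer.

The package is aimed at molecular programming and stochastic systems-biology
work: design of synthetic circuits that must *sample* (make randomized
decisions) rather than compute deterministic values, and exact analysis of
small CRN models.

## What is inside

* **Exact pmf algebra** (`crndist.pmf`) — finite-support pmfs over ℕ^m with
  rational masses, and the operations sum/convolution `π1 + π2`, minimum
  `min(π1, π2)`, scaling `k·π`, floor division `π/k`, convex combination
  `(π1)_p : π2`, plus L1 distance, a multiplicative-error measure, and
  ε-truncation of countable-support pmfs.  Everything is `fractions.Fraction`
  end-to-end; no floating point.
* **A distribution calculus** (`crndist.calculus`) — formulas
  `P := P+P | min(P,P) | k·P | (P)_D:P | one | zero`, where the convex weight
  `D` may be an affine expression over environmental inputs evaluated by an
  environment `E`.  Parser, printer, exact evaluator, and a completeness
  compiler turning any finite pmf into a formula that denotes it.
* **Compilers to reaction networks** (`crndist.compile`) — the direct
  leader-based construction (2|J| reactions, 2|J|+2 species for support J), a
  rate-free variant encoding probabilities in molecule counts, a
  multidimensional joint compiler, compact special networks for the Poisson,
  binomial and uniform distributions, composable network operators
  (Sum/Min/Mul/Div/Con and the externally-controlled ConE), and a structural
  translation of any formula into a non-reacting-output network.
* **Verification engines** — exact CTMC analysis (`crndist.ctmc`: reachable
  state-space enumeration, stationary `πQ = 0` solves, absorption
  distributions over terminal states, marginalization) and Gillespie
  simulation (`crndist.ssa`: direct method, terminal sampling, time-average
  occupancy).

The central guarantees, all re-verified by the test suite against independent
oracles: the compiled network of a pmf `f` has absorption law of its output
species *exactly* `f`; each network operator realizes its pmf operation
*exactly*; the uniform network is exactly `1/(K+1)` on `{0..K}`; and the
approximate ConE operator's error decreases as its fast/slow rate ratio
grows.

## Worked example

Compile the three-point pmf `f = {2: 1/6, 5: 1/3, 10: 1/2}` and recover it
exactly from the network's terminal behaviour:

```python
from fractions import Fraction as F
import crndist as cd

f = cd.Pmf({2: F(1, 6), 5: F(1, 3), 10: F(1, 2)})
net = cd.compile_direct(f)
print(cd.write_crn(net))
print(cd.output_distribution(net))
```

```
species: Z X1 C1 X2 C2 X3 C3 OUT
init: Z=1 X1=2 X2=5 X3=10
outputs: OUT
Z -> C1 @ 1/6
C1 + X1 -> C1 + OUT @ 1
Z -> C2 @ 1/3
C2 + X2 -> C2 + OUT @ 1
Z -> C3 @ 1/2
C3 + X3 -> C3 + OUT @ 1

Pmf({2: 1/6, 5: 1/3, 10: 1/2})
```

The single leader molecule `Z` fires exactly one selector reaction — branch
`i` with probability `f(z_i)` — and the chosen catalyst `C_i` then transfers
its payload `X_i` (initialized at `z_i`) into the output.  The recovered
distribution is the *exact* absorption law computed by rational-arithmetic
CTMC analysis, and it equals `f` bit-for-bit: the printed masses `1/6, 1/3,
1/2` are Fractions, not floats.

The same round trip works through the calculus:

```python
p = cd.evaluate(cd.parse("(one)[1/4]:(3*one + 2*one)"))
print(p)                                       # Pmf({1: 1/4, 5: 3/4})
print(cd.output_distribution(cd.translate(cd.parse("(one)[1/4]:(3*one + 2*one)"))))
                                               # Pmf({1: 1/4, 5: 3/4}) — exact
```

A shell interface covers the same pipeline: `crndist compile-pmf f.json`,
`crndist translate "(one)[1/2]:(zero)"`, `crndist special uniform -K 10`,
`crndist steady net.crn`, `crndist simulate net.crn --n 10000 --seed 42`, and
`crndist verify f.json` (exit code 0 iff the recovered distribution matches).

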