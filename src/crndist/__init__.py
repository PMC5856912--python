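"""crndist: programming discrete probability distributions with chemical reaction networks.

An exact pmf algebra, a distribution calculus with environments, compilers
from pmfs and formulas to non-reacting-output reaction networks, and exact
(CTMC) and stochastic (Gillespie) verification engines that recover each
compiled network's limit distribution.
"""

from .pmf import (
    Pmf,
    convolve,
    minimum,
    scalar_multiply,
    scalar_divide,
    convex,
    l1_distance,
    mult_error,
    truncate,
    point_mass,
    pmf_one,
    pmf_zero,
)
from .calculus import (
    Formula,
    One,
    Zero,
    Sum,
    Min,
    Scale,
    Convex,
    DExpr,
    parse,
    pretty,
    eval_D,
    evaluate,
    free_variables,
    pmf_to_formula,
)
from .crn import (
    Reaction,
    ReactionSystem,
    NroSystem,
    propensity,
    validate_nro,
    read_crn,
    write_crn,
)
from .compile import (
    FreshNamer,
    RateFreeConfig,
    ConEConfig,
    compile_direct,
    compile_rate_free,
    compile_multidim,
    poisson_network,
    binomial_network,
    uniform_network,
    op_sum,
    op_min,
    op_mul,
    op_div,
    op_con,
    op_con_external,
    rename,
    translate,
)
from .ctmc import (
    StateSpace,
    StateDistribution,
    StateSpaceCapExceeded,
    enumerate_states,
    stationary,
    absorption,
    marginal,
)
from .ssa import Trajectory, simulate, sample_terminal, occupancy
from . import fixtures

__version__ = "0.1.0"


def output_distribution(system: NroSystem, max_states: int = 100_000) -> Pmf:
    """Exact absorption marginal of a network's declared outputs.

    Convenience wrapper: enumerate, solve, and marginalize onto the output
    species (joint when there are several).
    """
    space = enumerate_states(system, max_states=max_states)
    dist = absorption(space)
    return marginal(dist, system.outputs if len(system.outputs) > 1 else system.outputs[0])
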