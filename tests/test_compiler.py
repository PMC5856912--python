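"""Compilers and network operators, verified against the exact pmf algebra."""

from fractions import Fraction as F
from math import lcm

import pytest

import crndist as cd
from crndist.calculus import DExpr
from crndist.compile import ConEConfig, FreshNamer, RateFreeConfig
from crndist.fixtures import FixtureSpec, random_formula, random_pmf


def output_pmf(net, max_states=100_000):
    return cd.output_distribution(net, max_states=max_states)


def holder(name, count):
    """Single-species network holding ``count`` molecules of its output."""
    return cd.NroSystem([name], [], {name: count}, outputs=[name])


def solvable_formula(seed, max_value=30):
    """Deterministically pick the seed-th random variable-free formula whose
    denoted support stays within the exact-solve scale used by this suite."""
    found = -1
    candidate = 0
    while True:
        f = random_formula(FixtureSpec(seed=candidate, max_depth=3))
        p = cd.evaluate(f)
        if max(z for (z,) in p.support) <= max_value:
            found += 1
            if found == seed:
                return f
        candidate += 1


class TestCompileDirect:
    def test_three_point_structure(self, three_point):
        net = cd.compile_direct(three_point)
        assert len(net.reactions) == 6  # 2|J|
        assert len(net.species) == 8  # 2|J| + 2
        assert net.init["Z"] == 1 and net.init["OUT"] == 0
        assert (net.init["X1"], net.init["X2"], net.init["X3"]) == (2, 5, 10)
        selector_rates = [rx.rate for rx in net.reactions if dict(rx.reactants) == {"Z": 1}]
        assert selector_rates == [F(1, 6), F(1, 3), F(1, 2)]

    def test_point_mass_at_zero(self):
        net = cd.compile_direct(cd.point_mass(0))
        assert len(net.reactions) == 2
        assert output_pmf(net) == cd.point_mass(0)

    def test_reaction_and_species_counts(self):
        for seed in range(5):
            p = random_pmf(FixtureSpec(seed=seed))
            net = cd.compile_direct(p)
            assert len(net.reactions) == 2 * len(p)
            assert len(net.species) == 2 * len(p) + 2

    @pytest.mark.parametrize("seed", range(25))
    def test_absorption_recovers_pmf_exactly(self, seed):
        p = random_pmf(FixtureSpec(seed=seed, max_support=4, max_value=8))
        net = cd.compile_direct(p)
        assert cd.validate_nro(net) == []
        assert output_pmf(net) == p


class TestCompileRateFree:
    def test_catalyst_counts(self, three_point):
        net = cd.compile_rate_free(three_point, RateFreeConfig(L=6))
        assert (net.init["F1"], net.init["F2"], net.init["F3"]) == (1, 2, 3)
        assert len({rx.rate for rx in net.reactions}) == 1

    def test_point_mass_minimal_granularity(self):
        net = cd.compile_rate_free(cd.point_mass(4), RateFreeConfig(L=1))
        assert net.init["F1"] == 1

    def test_inadmissible_granularity_reports_denominator(self, three_point):
        with pytest.raises(ValueError, match="multiple of 6"):
            cd.compile_rate_free(three_point, RateFreeConfig(L=2))

    @pytest.mark.parametrize("seed", range(15))
    @pytest.mark.parametrize("k", [F(1), F(7, 3)])
    def test_absorption_recovers_pmf_for_any_common_rate(self, seed, k):
        p = random_pmf(FixtureSpec(seed=seed, max_support=4, max_value=8))
        L = lcm(*[pr.denominator for _, pr in p.items()])
        net = cd.compile_rate_free(p, RateFreeConfig(L=L, k=k))
        assert output_pmf(net) == p


class TestCompileMultidim:
    def test_2d_worked_example_structure(self, joint_2d):
        net = cd.compile_multidim(joint_2d)
        assert len(net.reactions) == 9  # 3 selectors + 3 points * 2 dims
        inits = [
            (net.init[f"X{i}_1"], net.init[f"X{i}_2"]) for i in (1, 2, 3)
        ]
        assert inits == [(1, 5), (3, 1), (3, 2)]  # lexicographic point order

    def test_2d_worked_example_distribution(self, joint_2d):
        assert output_pmf(cd.compile_multidim(joint_2d)) == joint_2d

    def test_1d_collapses_to_direct_structure(self, three_point):
        net = cd.compile_multidim(three_point)
        assert len(net.reactions) == 6
        assert output_pmf(net) == three_point

    @pytest.mark.parametrize("seed", range(10))
    def test_random_2d_pmfs_recovered(self, seed):
        p = random_pmf(FixtureSpec(seed=seed, max_support=4, max_value=6, dim=2))
        net = cd.compile_multidim(p)
        assert cd.validate_nro(net) == []
        assert output_pmf(net) == p


class TestSpecialNetworks:
    def test_poisson_network_shape(self):
        net = cd.poisson_network(2, 1)
        assert len(net.reactions) == 2 and net.species == ("L",)

    def test_binomial_exact_stationary(self):
        from math import comb

        for k1, k2, K in [(1, 1, 10), (2, 1, 6), (1, 3, 5)]:
            dist = cd.stationary(cd.enumerate_states(cd.binomial_network(k1, k2, K)))
            c1 = F(k2, k1 + k2)
            expected = cd.Pmf(
                {y: comb(K, y) * c1**y * (1 - c1) ** (K - y) for y in range(K + 1)}
            )
            assert cd.marginal(dist, "L1") == expected

    def test_binomial_zero_total(self):
        dist = cd.absorption(cd.enumerate_states(cd.binomial_network(1, 1, 0)))
        assert cd.marginal(dist, ["L1", "L2"]) == cd.point_mass((0, 0))

    def test_binomial_independent_of_split(self):
        base = None
        for m in range(7):
            dist = cd.stationary(cd.enumerate_states(cd.binomial_network(1, 2, 6, m)))
            marg = cd.marginal(dist, "L2")
            base = base or marg
            assert marg == base

    def test_uniform_two_states(self):
        dist = cd.stationary(cd.enumerate_states(cd.uniform_network(1, 0)))
        assert set(dist.probs.values()) == {F(1, 2)}

    def test_uniform_exact_closed_form(self):
        for m in (0, 3, 10):
            dist = cd.stationary(cd.enumerate_states(cd.uniform_network(10, m)))
            assert all(p == F(1, 11) for p in dist.probs.values())


class TestOperators:
    @pytest.mark.parametrize("seed", range(12))
    def test_sum_min_con_match_pmf_algebra(self, seed):
        p1 = random_pmf(FixtureSpec(seed=seed, max_support=3, max_value=6))
        p2 = random_pmf(FixtureSpec(seed=seed + 500, max_support=3, max_value=6))
        c1, c2 = cd.compile_direct(p1), cd.compile_direct(p2)
        assert output_pmf(cd.op_sum(c1, "OUT", c2, "OUT")) == cd.convolve(p1, p2)
        assert output_pmf(cd.op_min(c1, "OUT", c2, "OUT")) == cd.minimum(p1, p2)
        w = F(seed, 13)
        assert output_pmf(cd.op_con(c1, "OUT", c2, "OUT", w)) == cd.convex(p1, p2, w)

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_mul_div_match_pmf_algebra(self, seed, k):
        p = random_pmf(FixtureSpec(seed=seed, max_support=3, max_value=6))
        c = cd.compile_direct(p)
        assert output_pmf(cd.op_mul(c, "OUT", k)) == cd.scalar_multiply(p, k)
        assert output_pmf(cd.op_div(c, "OUT", k)) == cd.scalar_divide(p, k)

    def test_mul_zero_gives_zero_pmf(self, pi2):
        net = cd.op_mul(cd.compile_direct(pi2), "OUT", 0)
        assert output_pmf(net) == cd.pmf_zero()

    def test_sum_adds_two_transfer_reactions(self, pi1, pi2):
        c1, c2 = cd.compile_direct(pi1), cd.compile_direct(pi2)
        s = cd.op_sum(c1, "OUT", c2, "OUT", "FIN")
        new = [rx for rx in s.reactions if "FIN" in dict(rx.products)]
        assert len(new) == 2
        assert all(len(rx.reactants) == 1 and rx.rate == 1 for rx in new)
        assert output_pmf(s) == cd.convolve(pi1, pi2)

    def test_con_selector_structure(self):
        # two degenerate holder networks, weight 0.3
        net = cd.op_con(holder("A", 10), "A", holder("B", 20), "B", F(3, 10), "OUT")
        sel = [rx for rx in net.reactions if dict(rx.reactants) == {"Z1": 1}]
        assert sorted(rx.rate for rx in sel) == [F(3, 10), F(7, 10)]
        assert net.init["Z1"] == 1
        transfers = [rx for rx in net.reactions if len(rx.reactants) == 2]
        assert len(transfers) == 2
        assert output_pmf(net) == cd.Pmf({10: F(3, 10), 20: F(7, 10)})

    def test_colliding_operand_species_renamed_automatically(self, pi1):
        c1 = cd.compile_direct(pi1)
        c2 = cd.compile_direct(pi1)  # same species names on both sides
        s = cd.op_sum(c1, "OUT", c2, "OUT")
        assert output_pmf(s) == cd.convolve(pi1, pi1)

    def test_operand_output_must_be_declared(self, pi1, pi2):
        with pytest.raises(ValueError, match="not an output"):
            cd.op_sum(cd.compile_direct(pi1), "Z", cd.compile_direct(pi2), "OUT")


class TestConExternal:
    def test_example_instance_structure(self):
        # holders at 10 and 20, weight E(c) with E(c)=1/2, L=1000
        net = cd.op_con_external(
            holder("A", 10), "A", holder("B", 20), "B",
            DExpr(F(0), ((F(1), "c"),)), {"c": F(1, 2)},
            ConEConfig(rho=1000, L=1000),
        )
        assert net.init["CIN1"] == 500 and net.init["TOT1"] == 1000
        assert net.init["Z1"] == 1
        fast = [rx for rx in net.reactions if rx.rate == 1000]
        slow = [rx for rx in net.reactions if rx.rate == 1]
        assert len(fast) == 2 and len(slow) == 4

    def test_constant_weight_redirects_to_exact_con(self):
        net = cd.op_con_external(
            holder("A", 1), "A", holder("B", 2), "B", DExpr(F(1, 4)), {},
        )
        assert output_pmf(net) == cd.Pmf({1: F(1, 4), 2: F(3, 4)})
        assert not any("CIN" in s for s in net.species)

    def test_granularity_violation_reports_minimal_L(self):
        with pytest.raises(ValueError, match="minimal admissible L is 3"):
            cd.op_con_external(
                holder("A", 1), "A", holder("B", 2), "B",
                DExpr(F(0), ((F(1), "c"),)), {"c": F(1, 3)},
                ConEConfig(rho=10, L=2),
            )

    def test_error_below_tolerance_at_high_ratio(self):
        exact = cd.Pmf({4: F(1, 3), 9: F(2, 3)})
        net = cd.op_con_external(
            holder("A", 4), "A", holder("B", 9), "B",
            DExpr(F(0), ((F(1), "c"),)), {"c": F(1, 3)},
            ConEConfig(rho=1000),
        )
        err = cd.l1_distance(output_pmf(net), exact)
        assert err < F(1, 50)

    def test_error_decreases_with_rate_separation(self):
        d = DExpr(F(0), ((F(1), "c"),))
        env = {"c": F(1, 2)}
        exact = cd.convex(cd.point_mass(10), cd.point_mass(20), F(1, 2))
        errors = []
        for rho in (10, 100, 1000):
            net = cd.op_con_external(
                holder("A", 10), "A", holder("B", 20), "B", d, env,
                ConEConfig(rho=rho, L=10),
            )
            errors.append(cd.l1_distance(output_pmf(net), exact))
        assert errors[0] > errors[1] > errors[2]


class TestRename:
    def test_round_trip_is_identity(self, three_point):
        net = cd.compile_direct(three_point)
        there = cd.rename(net, "FRESH", "OUT")
        back = cd.rename(there, "OUT", "FRESH")
        assert back == net and back.outputs == net.outputs

    def test_preserves_absorption_distribution(self, three_point):
        net = cd.compile_direct(three_point)
        renamed = cd.rename(net, "RESULT", "OUT")
        dist = cd.absorption(cd.enumerate_states(renamed))
        assert cd.marginal(dist, "RESULT") == three_point

    def test_preconditions(self, three_point):
        net = cd.compile_direct(three_point)
        with pytest.raises(ValueError):
            cd.rename(net, "OUT", "Z")  # new name already present
        with pytest.raises(ValueError):
            cd.rename(net, "Q", "NOPE")  # old name absent


class TestFreshNamer:
    def test_never_emits_reserved_names(self):
        namer = FreshNamer(["OUT1", "OUT2"])
        assert namer.fresh("OUT") == "OUT3"
        assert namer.fresh("OUT") == "OUT4"

    def test_counter_is_deterministic(self):
        na, nb = FreshNamer(), FreshNamer()
        a = [na.fresh("S") for _ in range(3)]
        b = [nb.fresh("S") for _ in range(3)]
        assert a == b == ["S1", "S2", "S3"]


class TestTranslate:
    def test_literals(self):
        assert output_pmf(cd.translate(cd.parse("one"))) == cd.pmf_one()
        assert output_pmf(cd.translate(cd.parse("zero"))) == cd.pmf_zero()

    def test_bernoulli_formula(self):
        net = cd.translate(cd.parse("(one)[3/10]:(zero)"))
        assert output_pmf(net) == cd.Pmf({1: F(3, 10), 0: F(7, 10)})

    def test_scale_uses_mul_then_div(self):
        net = cd.translate(cd.parse("3/2*one"))
        assert output_pmf(net) == cd.point_mass(1)

    def test_single_declared_output(self):
        net = cd.translate(cd.parse("min(one, zero) + 2*one"))
        assert len(net.outputs) == 1
        assert cd.validate_nro(net) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_variable_free_formulas_match_semantics(self, seed):
        f = solvable_formula(seed)
        assert output_pmf(cd.translate(f)) == cd.evaluate(f)

    def test_switch_formula_reaction_pattern(self):
        # the two-branch externally-controlled switch: the translation contains
        # the ConE fast pair, the Con selector with rates 2/5 and 3/5, and two
        # relays into the single declared output
        f = cd.parse("(one)[0.001*c + 0.2]:(4*one) + (2*one)[0.4]:(3*one)")
        net = cd.translate(f, {"c": F(1, 2)}, ConEConfig(rho=1000))
        assert cd.validate_nro(net) == []
        assert len(net.outputs) == 1
        fast = [rx for rx in net.reactions if rx.rate == 1000]
        assert len(fast) == 2
        sel = sorted(rx.rate for rx in net.reactions if rx.rate in (F(2, 5), F(3, 5)))
        assert sel == [F(2, 5), F(3, 5)]
        out = net.outputs[0]
        relays = [
            rx for rx in net.reactions
            if dict(rx.products) == {out: 1} and len(rx.reactants) == 1
        ]
        assert len(relays) == 2
        # the environment weight is loaded as counts: E(c)*L and L
        w = F(1, 1000) * F(1, 2) + F(1, 5)
        cin = next(s for s in net.species if s.startswith("CIN"))
        tot = next(s for s in net.species if s.startswith("TOT"))
        assert F(net.init[cin], net.init[tot]) == w

    def test_environment_weight_approximated_within_tolerance(self):
        # a coarse-grained switch solvable exactly: weight 1/10*c + 1/5 at c = 1/2
        f = cd.parse("(one)[1/10*c + 1/5]:(4*one) + (2*one)[2/5]:(3*one)")
        env = {"c": F(1, 2)}
        net = cd.translate(f, env, ConEConfig(rho=1000))
        expected = cd.evaluate(f, env)
        err = cd.l1_distance(output_pmf(net), expected)
        assert err < F(1, 50)
        assert cd.validate_nro(net) == []
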