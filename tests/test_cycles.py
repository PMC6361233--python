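"""Cycle enumeration, epistasis classification and higher-order couplings."""

from itertools import combinations

import numpy as np
import pytest

import skempi2 as sk
from skempi2.cycles import (aggregate_ddg, classify_epistasis, cycle_report,
                            enumerate_double_cycles, enumerate_quad_cycles,
                            enumerate_triple_cubes, interaction_energy)
from skempi2.io import Qualifier


from oracles import (cycle, make_entry, mut, oracle_classify,
                     recursive_interaction_energy)

# ---------------------------------------------------------------------------

class TestAggregate:
    def test_mean_of_replicates(self):
        entries = [make_entry("1ABC", [mut("A", 1)], 1.0),
                   make_entry("1ABC", [mut("A", 1)], 2.0)]
        (agg,) = aggregate_ddg(entries).values()
        assert agg.ddg == pytest.approx(1.5)
        assert agg.n_replicates == 2 and agg.quantified

    def test_single_entry_keeps_own_ddg(self):
        entries = [make_entry("1ABC", [mut("A", 1)], 0.7)]
        (agg,) = aggregate_ddg(entries).values()
        assert agg.ddg == pytest.approx(0.7)

    @pytest.mark.parametrize("qualifiers,expect_quantified", [
        # rule table: quantified iff at least one exact replicate
        ((Qualifier.EXACT,), True),
        ((Qualifier.GREATER_THAN,), False),
        ((Qualifier.NON_BINDING,), False),
        ((Qualifier.EXACT, Qualifier.GREATER_THAN), True),
        ((Qualifier.EXACT, Qualifier.NON_BINDING), True),
        ((Qualifier.GREATER_THAN, Qualifier.LESS_THAN), False),
        ((Qualifier.NON_BINDING, Qualifier.GREATER_THAN, Qualifier.EXACT),
         True),
    ])
    def test_qualifier_rule_table(self, qualifiers, expect_quantified):
        entries = [make_entry("1ABC", [mut("A", 1)], 1.0, qualifier=q)
                   for q in qualifiers]
        (agg,) = aggregate_ddg(entries).values()
        assert agg.quantified is expect_quantified
        if expect_quantified:
            assert agg.ddg == pytest.approx(1.0)
            exact_only = [1.0] * sum(q is Qualifier.EXACT for q in qualifiers)
            assert len(exact_only) >= 1
        else:
            assert agg.ddg is None

    def test_mutation_order_is_canonicalized(self):
        e1 = make_entry("1ABC", [mut("A", 1), mut("A", 2)], 1.0)
        e2 = make_entry("1ABC", [mut("A", 2), mut("A", 1)], 3.0)
        agg = aggregate_ddg([e1, e2])
        assert len(agg) == 1
        assert next(iter(agg.values())).ddg == pytest.approx(2.0)


class TestEnumerate:
    def test_minimal_additive_cycle(self):
        a, b = mut("A", 1), mut("A", 2)
        entries = [make_entry("1ABC", [a], 1.0),
                   make_entry("1ABC", [b], 1.0),
                   make_entry("1ABC", [a, b], 2.0)]
        (c,) = enumerate_double_cycles(aggregate_ddg(entries))
        assert c.is_direct and c.quantified
        assert c.ddg_int == pytest.approx(0.0)

    def test_background_cycle_re_references_energies(self):
        a, b, c0 = mut("A", 1), mut("A", 2), mut("B", 3)
        entries = [make_entry("1ABC", [c0], 0.5),
                   make_entry("1ABC", [c0, a], 1.5),
                   make_entry("1ABC", [c0, b], 2.5),
                   make_entry("1ABC", [c0, a, b], 3.0)]
        (c,) = enumerate_double_cycles(aggregate_ddg(entries))
        assert c.background == frozenset({c0})
        assert c.ddg_a == pytest.approx(1.0)
        assert c.ddg_b == pytest.approx(2.0)
        assert c.ddg_int == pytest.approx(-0.5)

    def test_non_quantified_vertex_propagates(self):
        a, b = mut("A", 1), mut("A", 2)
        entries = [make_entry("1ABC", [a], 1.0),
                   make_entry("1ABC", [b], 1.0,
                              qualifier=Qualifier.NON_BINDING),
                   make_entry("1ABC", [a, b], 2.0)]
        (c,) = enumerate_double_cycles(aggregate_ddg(entries))
        assert not c.quantified and c.ddg_int is None
        with pytest.raises(ValueError):
            classify_epistasis(c)

    def test_same_reference_requires_common_citation(self):
        a, b = mut("A", 1), mut("A", 2)
        entries = [make_entry("1ABC", [a], 1.0, reference="R1"),
                   make_entry("1ABC", [b], 1.0, reference="R2"),
                   make_entry("1ABC", [a, b], 2.0, reference="R1")]
        (c,) = enumerate_double_cycles(aggregate_ddg(entries))
        assert not c.same_reference

    def test_mixed_temperature_flagged(self):
        a, b = mut("A", 1), mut("A", 2)
        entries = [make_entry("1ABC", [a], 1.0, temperature=277.0),
                   make_entry("1ABC", [b], 1.0),
                   make_entry("1ABC", [a, b], 2.0)]
        (c,) = enumerate_double_cycles(aggregate_ddg(entries))
        assert c.mixed_temperature


class TestClassify:
    def test_zero_coupling_is_additive(self):
        assert classify_epistasis(cycle(1.0, -0.5, 0.5)).is_additive

    def test_antagonistic_positive(self):
        call = classify_epistasis(cycle(1.0, 1.0, 1.0))
        assert (call.additivity, call.subclass) == ("positive", "antagonistic")

    def test_reciprocal_stabilizing_to_destabilizing(self):
        call = classify_epistasis(cycle(-1.0, -1.0, 1.0))
        assert call.sign_epistasis == "reciprocal_stabilizing_to_destabilizing"
        assert (call.additivity, call.subclass) == ("negative", "antagonistic")

    def test_matches_rule_table_oracle_on_grid(self):
        grid = np.linspace(-2.0, 2.0, 13)
        for a in grid:
            for b in grid:
                for ab in grid:
                    assert classify_epistasis(cycle(a, b, ab)) == \
                        oracle_classify(a, b, ab)

    def test_path_independence_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            a, b, ab = rng.normal(0, 2, 3)
            c = cycle(a, b, ab)
            assert abs((c.ddg_a_in_b - c.ddg_a) - (c.ddg_b_in_a - c.ddg_b)) \
                < 1e-12
            assert c.ddg_int == pytest.approx(c.ddg_a_in_b - c.ddg_a,
                                              abs=1e-12)


class TestHigherOrder:
    def _random_vertex(self, muts, rng):
        v = {frozenset(): 0.0}
        for r in range(1, len(muts) + 1):
            for s in combinations(muts, r):
                v[frozenset(s)] = float(rng.normal(0, 2))
        return v

    @pytest.mark.parametrize("order", [2, 3, 4])
    def test_alternating_sum_equals_recursive_definition(self, order):
        rng = np.random.default_rng(order)
        muts = [mut("A", i + 1) for i in range(order)]
        for _ in range(50):
            v = self._random_vertex(muts, rng)
            assert interaction_energy(v, muts) == pytest.approx(
                recursive_interaction_energy(v, muts), abs=1e-10)

    @pytest.mark.parametrize("order", [3, 4])
    def test_permutation_symmetry(self, order):
        rng = np.random.default_rng(order + 10)
        muts = [mut("A", i + 1) for i in range(order)]
        v = self._random_vertex(muts, rng)
        ref = interaction_energy(v, muts)
        perm = rng.permutation(order)
        assert interaction_energy(v, [muts[i] for i in perm]) == \
            pytest.approx(ref, abs=1e-10)

    def test_additive_data_has_zero_higher_order_terms(self):
        rng = np.random.default_rng(3)
        muts = [mut("A", i + 1) for i in range(3)]
        singles = {m: float(rng.normal(0, 1)) for m in muts}
        entries = []
        for r in range(1, 4):
            for s in combinations(muts, r):
                entries.append(make_entry(
                    "1ABC", list(s), sum(singles[m] for m in s)))
        ddg_map = aggregate_ddg(entries)
        (cube,) = enumerate_triple_cubes(ddg_map)
        assert cube.interaction_energy == pytest.approx(0.0, abs=1e-9)
        for c in enumerate_double_cycles(ddg_map):
            assert abs(c.ddg_int) < 1e-9

    def test_cube_and_quad_counts_on_complete_sets(self):
        rng = np.random.default_rng(4)
        muts = [mut("A", i + 1) for i in range(4)]
        entries = []
        for r in range(1, 5):
            for s in combinations(muts, r):
                entries.append(make_entry("1ABC", list(s),
                                          float(rng.normal(0, 1))))
        ddg_map = aggregate_ddg(entries)
        assert len(enumerate_triple_cubes(ddg_map)) == 4  # C(4,3)
        (quad,) = enumerate_quad_cycles(ddg_map)
        assert quad.quantified
        assert quad.interaction_energy == pytest.approx(
            recursive_interaction_energy(quad.vertex_ddg, list(quad.mutations)),
            abs=1e-10)


class TestReport:
    def test_empty_input_all_zero(self):
        r = cycle_report([])
        assert r["n_cycles"] == 0 and r["n_quantified"] == 0
        assert r["ddg_int_min"] is None

    def test_partition_of_quantified_cycles(self, default_table):
        entries, _ = default_table
        cycles = enumerate_double_cycles(aggregate_ddg(entries))
        r = cycle_report(cycles)
        assert r["n_additive"] + r["n_positive"] + r["n_negative"] == \
            r["n_quantified"]
        assert r["n_direct"] + r["n_background"] == r["n_cycles"]
        assert (r["n_positive_synergistic"] + r["n_positive_antagonistic"]
                + r["n_positive_mixed"]) == r["n_positive"]

    def test_planted_labels_recovered(self, default_table):
        entries, truth = default_table
        cycles = enumerate_double_cycles(aggregate_ddg(entries))
        by_key = {(c.interaction, c.background,
                   frozenset({c.mut_a, c.mut_b})): c for c in cycles}
        assert truth.planted_cycles
        for p in truth.planted_cycles:
            c = by_key[(p.interaction, p.background,
                        frozenset({p.mut_a, p.mut_b}))]
            assert classify_epistasis(c) == p.call, p.label
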