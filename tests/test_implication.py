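"""Contingency tables, rule templates, scope/precision statistics, and induction."""

import numpy as np
import pytest

from plbin import (
    ContingencyTable,
    PlantedRuleSpec,
    StateVector,
    build_contingency,
    default_templates,
    gen_null_categorical,
    gen_planted_implications,
    induce_network,
    precision_weighted_form,
    rule_stats,
    select_rule,
)
from plbin.errors import InputError
from plbin.implication import TEMPLATE_ORDER
from conftest import random_table


def tpl(name, arity=2, semantics="strict"):
    return {r.name: r for r in default_templates(arity, arity, semantics)}[name]


class TestBuildContingency:
    def test_exhaustive_binary_enumeration(self):
        a = StateVector("a", [1, 1, 0, 0], arity=2)
        b = StateVector("b", [1, 0, 1, 0], arity=2)
        t = build_contingency(a, b)
        assert t.total == 4
        np.testing.assert_array_equal(t.counts, np.ones((2, 2)))

    def test_pairwise_deletion_of_missing(self):
        a = StateVector("a", [1, 1, np.nan], arity=2)
        b = StateVector("b", [1, 1, 1], arity=2)
        t = build_contingency(a, b)
        assert t.total == 2
        assert t.counts[1, 1] == 2

    def test_ternary_identity_diagonal(self):
        a = StateVector("a", [1, 0, -1])
        t = build_contingency(a, StateVector("b", [1, 0, -1]))
        np.testing.assert_array_equal(t.counts, np.eye(3))

    def test_no_retained_samples_is_an_error(self):
        a = StateVector("a", [np.nan, 1], arity=2)
        b = StateVector("b", [1, np.nan], arity=2)
        with pytest.raises(InputError):
            build_contingency(a, b)

    def test_margins_conserved(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = random_table(rng)
            assert t.row_margins.sum() == t.total
            assert t.col_margins.sum() == t.total


class TestTemplates:
    def test_binary_strict_reduces_to_quadrant_rules(self):
        assert tpl("UP_UP").error_cells == frozenset({(1, 0)})
        assert tpl("DOWN_DOWN").error_cells == frozenset({(0, 1)})
        assert tpl("EQUIVALENT").error_cells == frozenset({(1, 0), (0, 1)})
        assert tpl("OPPOSITE").error_cells == frozenset({(1, 1), (0, 0)})

    def test_binary_semantics_coincide(self):
        for name in TEMPLATE_ORDER:
            assert tpl(name, 2, "strict").error_cells == tpl(name, 2, "lenient").error_cells

    def test_ternary_strict_and_lenient_up_up(self):
        assert tpl("UP_UP", 3).error_cells == frozenset({(1, 0), (1, -1)})
        assert tpl("UP_UP", 3, "lenient").error_cells == frozenset({(1, -1)})

    def test_ternary_symmetric_templates_are_transpose_closed(self):
        for name in ("EQUIVALENT", "OPPOSITE"):
            t = tpl(name, 3)
            assert t.error_cells == t.transpose().error_cells

    def test_unsupported_arity(self):
        with pytest.raises(InputError):
            default_templates(4, 3)


class TestRuleStats:
    def test_worked_binary_example(self, binary_table):
        s = rule_stats(binary_table, tpl("UP_UP"), z_preset=1.645)
        assert s.scope == pytest.approx(0.225)
        assert s.error_count == 1
        assert s.precision == pytest.approx(1 - (1 / 20) / 0.225)
        assert s.z_stat == pytest.approx((20 * 0.225 - 1) / np.sqrt(20 * 0.225 * 0.775))
        assert s.significant

    def test_perfect_rule_has_unit_precision(self):
        t = ContingencyTable((0, 1), (0, 1), np.array([[10, 5], [0, 10]]))
        s = rule_stats(t, tpl("UP_UP"))
        assert s.error_count == 0
        assert s.precision == 1.0

    def test_independence_table_gives_zero_precision(self):
        t = ContingencyTable((0, 1), (0, 1), np.full((2, 2), 5))
        for name in TEMPLATE_ORDER:
            s = rule_stats(t, tpl(name))
            assert s.precision == pytest.approx(0.0, abs=1e-14)
            assert not s.significant

    def test_degenerate_margins_marked_undefined(self):
        t = ContingencyTable((0, 1), (0, 1), np.array([[4, 3], [0, 0]]))
        s = rule_stats(t, tpl("UP_UP"))  # row UP empty -> scope 0
        assert s.scope == 0.0
        assert np.isnan(s.precision)
        assert not s.significant

    def test_weighted_form_matches_closed_form(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            t = random_table(rng)
            for name in TEMPLATE_ORDER:
                r = tpl(name, 3)
                s = rule_stats(t, r)
                w = precision_weighted_form(t, r)
                if np.isnan(s.precision):
                    assert np.isnan(w)
                else:
                    assert abs(w - s.precision) < 1e-12
                assert 0.0 <= s.scope <= 1.0

    def test_transposition_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = random_table(rng)
            for name in TEMPLATE_ORDER:
                r = tpl(name, 3)
                a = rule_stats(t, r)
                b = rule_stats(t.transpose(), r.transpose())
                assert a.scope == pytest.approx(b.scope)
                if not np.isnan(a.precision):
                    assert a.precision == pytest.approx(b.precision)

    def test_moving_mass_out_of_error_cell_never_decreases_precision(self):
        # moving one sample from error cell (UP, DOWN) to (UP, UP) keeps the
        # antecedent row margin fixed and must not lower precision
        rng = np.random.default_rng(8)
        r = tpl("UP_UP", 3)
        for _ in range(100):
            t = random_table(rng)
            if t.counts[2, 0] == 0:  # state order (-1,0,1): cell (UP, DOWN)
                continue
            counts2 = t.counts.copy()
            counts2[2, 0] -= 1
            counts2[2, 2] += 1
            t2 = ContingencyTable(t.row_states, t.col_states, counts2)
            s1, s2 = rule_stats(t, r), rule_stats(t2, r)
            if np.isnan(s1.precision) or np.isnan(s2.precision):
                continue
            assert s2.precision >= s1.precision - 1e-12

    def test_precision_lower_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            t = random_table(rng)
            for name in TEMPLATE_ORDER:
                s = rule_stats(t, tpl(name, 3))
                if not np.isnan(s.precision):
                    assert s.precision <= 1.0 + 1e-12
                    assert s.precision >= 1.0 - 1.0 / s.scope - 1e-9


class TestSelectRule:
    def test_precision_first_picks_up_up(self, binary_table):
        sel = select_rule(binary_table, default_templates(2, 2))
        assert sel is not None
        assert sel[0].name == "UP_UP"
        assert sel[1].precision == pytest.approx(7 / 9)

    def test_strict_dominance_finds_no_dominant_rule(self, binary_table):
        # UP_UP has maximal precision but EQUIVALENT has maximal scope
        assert select_rule(binary_table, default_templates(2, 2), policy="strict_dominance") is None

    def test_no_significant_template_returns_none(self):
        t = ContingencyTable((0, 1), (0, 1), np.full((2, 2), 5))
        assert select_rule(t, default_templates(2, 2)) is None


class TestInduceNetwork:
    def test_planted_pair_recovered_perfectly(self):
        m = gen_planted_implications(
            [PlantedRuleSpec(0, 1, "UP_UP", 0.0)], 52, 200, seed=1
        )
        net = induce_network(m)
        planted = [
            e for e in net.edges if e.source_id == "G0" and e.target_id == "G1"
        ]
        assert any(e.template == "UP_UP" and e.stats.precision == 1.0 for e in planted)

    def test_constant_matrix_yields_empty_network(self):
        from plbin.matrix import CategorizedMatrix

        m = CategorizedMatrix(
            ["a", "b", "c"], ["s0", "s1", "s2"], np.zeros((3, 3)), arity=3
        )
        net = induce_network(m)
        assert net.n_edges == 0
        assert net.params["skipped_single_state"] == 3

    def test_matches_pairwise_selection_route(self):
        # blocked vectorized induction must agree with per-pair select_rule
        m = gen_null_categorical(12, 120, seed=3)
        m.states[0] = np.where(m.states[1] == 1, 1.0, m.states[0])  # correlate a pair
        net = induce_network(m, min_samples=10)
        got = {
            (e.source_id, e.target_id, e.template): (
                e.stats.scope,
                e.stats.precision,
            )
            for e in net.edges
        }
        templates = default_templates(3, 3)
        expected = {}
        for i, a in enumerate(m.gene_ids):
            for j, b in enumerate(m.gene_ids):
                if i == j:
                    continue
                t = build_contingency(
                    StateVector(a, m.states[i]), StateVector(b, m.states[j])
                )
                sel = select_rule(t, templates)
                if sel is None:
                    continue
                name = sel[0].name
                src, tgt = a, b
                if name in ("EQUIVALENT", "OPPOSITE") and src > tgt:
                    src, tgt = tgt, src
                expected[(src, tgt, name)] = (sel[1].scope, sel[1].precision)
        assert set(got) == set(expected)
        for key, (u, nab) in expected.items():
            assert got[key][0] == pytest.approx(u, abs=1e-9)
            assert got[key][1] == pytest.approx(nab, abs=1e-9)

    def test_deterministic_and_chunking_invariant(self):
        m = gen_null_categorical(60, 80, seed=9)
        f1 = induce_network(m, chunk_size=7).to_frame()
        f2 = induce_network(m, chunk_size=64).to_frame()
        assert f1.equals(f2)

    def test_too_few_genes_rejected(self):
        m = gen_null_categorical(1, 50, seed=0)
        with pytest.raises(InputError):
            induce_network(m)

    def test_min_samples_filter(self):
        m = gen_planted_implications(
            [PlantedRuleSpec(0, 1, "UP_UP", 0.0)], 4, 8, seed=2
        )
        net = induce_network(m, min_samples=10)
        assert net.n_edges == 0
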