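"""Relevance networks, entropy/MI, StepMiner + sparse-quadrant implication, BBN."""

import itertools

import numpy as np
import pytest

from plbin import (
    DiscreteBBN,
    ExpressionMatrix,
    QuadrantCounts,
    bbn_joint_probability,
    categorical_entropy,
    mutual_information,
    pcc_network,
    pearson_cc,
    quadrant_counts,
    sahoo_rules,
    sahoo_test,
    stepminer_threshold,
)
from plbin.errors import InputError


class TestPearson:
    def test_perfect_correlations(self):
        assert pearson_cc([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_cc([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_hand_evaluated_half(self):
        assert pearson_cc([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            pearson_cc([1, 1, 1], [1, 2, 3])

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = pearson_cc(x, y)
        assert pearson_cc(3.2 * x + 7, y) == pytest.approx(r)
        assert pearson_cc(x, 0.1 * y - 4) == pytest.approx(r)

    def test_network_recovers_planted_pair(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 50))
        # plant r ~ 0.95 between genes 0 and 1
        vals[1] = 0.95 * vals[0] + np.sqrt(1 - 0.95**2) * rng.normal(size=50)
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(10)], [f"s{j}" for j in range(50)], vals
        )
        edges = pcc_network(expr, 0.8)
        assert ("g0", "g1") in {(a, b) for a, b, _ in edges}
        # brute-force check: every reported edge really crosses the threshold
        for a, b, r in edges:
            direct = pearson_cc(expr.gene_values(a), expr.gene_values(b))
            assert abs(direct) >= 0.8
            assert r == pytest.approx(direct)

    def test_collinear_pair_single_edge(self):
        expr = ExpressionMatrix(
            ["a", "b", "c"],
            ["s0", "s1", "s2"],
            np.array([[1.0, 2, 3], [2.0, 4, 6], [1.0, 5, 2]]),
        )
        edges = pcc_network(expr, 0.99)
        assert [(a, b) for a, b, _ in edges] == [("a", "b")]


class TestEntropyMI:
    def test_entropy_examples(self):
        assert categorical_entropy([0, 1, 0, 1]) == pytest.approx(1.0)
        assert categorical_entropy([7, 7, 7]) == 0.0
        assert categorical_entropy([0, 1, 1, 1]) == pytest.approx(0.8113, abs=1e-4)

    def test_mi_of_identical_variable_is_its_entropy(self):
        x = [0, 1] * 5
        assert mutual_information(x, x) == pytest.approx(categorical_entropy(x))

    def test_mi_zero_under_exact_independence(self):
        x = [0] * 4 + [1] * 4
        y = [0, 0, 1, 1] * 2
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_mi_hand_example(self):
        # joint counts [[4,1],[1,4]], N=10
        x = [0] * 5 + [1] * 5
        y = [0, 0, 0, 0, 1, 0, 1, 1, 1, 1]
        assert mutual_information(x, y) == pytest.approx(0.2781, abs=1e-4)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x = rng.integers(0, 3, 40).tolist()
            y = rng.integers(0, 2, 40).tolist()
            mi = mutual_information(x, y)
            assert mi == pytest.approx(mutual_information(y, x))
            assert -1e-12 <= mi <= min(
                categorical_entropy(x), categorical_entropy(y)
            ) + 1e-12


def _exhaustive_step(values):
    """Independent oracle: try every split of the sorted vector directly."""
    v = sorted(values)
    n = len(v)
    best = None
    for k in range(1, n):
        left, right = v[:k], v[k:]
        lm, rm = np.mean(left), np.mean(right)
        sse = sum((x - lm) ** 2 for x in left) + sum((x - rm) ** 2 for x in right)
        key = (round(sse, 12), abs(k - (n - k)))
        if best is None or key < best[0]:
            best = (key, (lm + rm) / 2, sse)
    return best[1], best[2]


class TestStepMiner:
    def test_clean_steps(self):
        f = stepminer_threshold([1, 1, 1, 5, 5, 5])
        assert (f.threshold, f.sse) == (3.0, 0.0)
        assert stepminer_threshold([1, 1, 1, 1, 9]).threshold == 5.0

    def test_constant_vector_rejected(self):
        with pytest.raises(InputError):
            stepminer_threshold([2.0, 2.0, 2.0, 2.0])

    def test_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            n = int(rng.integers(4, 51))
            v = rng.normal(size=n)
            f = stepminer_threshold(v)
            t_oracle, sse_oracle = _exhaustive_step(v)
            assert f.threshold == pytest.approx(t_oracle, abs=1e-9)
            assert f.sse == pytest.approx(sse_oracle, abs=1e-9)


class TestQuadrants:
    def test_clean_quadrant_assignment(self):
        fa = stepminer_threshold([0.0, 0, 5, 5])
        fb = stepminer_threshold([0.0, 5, 0, 5])
        q = quadrant_counts([0, 0, 5, 5], [0, 5, 0, 5], fa, fb)
        assert (q.a_i, q.a_ii, q.a_iii, q.a_iv) == (1, 1, 1, 1)

    def test_intermediate_zone_excluded(self):
        fa = stepminer_threshold([0.0, 0, 5, 5])  # t = 2.5
        fb = stepminer_threshold([0.0, 0, 5, 5])
        q = quadrant_counts([0, 2.6, 5, 5], [0, 5, 0, 5], fa, fb)
        # sample with value 2.6 sits inside 2.5 +/- 0.5 and is dropped
        assert q.total == 3
        assert (q.a_i, q.a_ii, q.a_iii, q.a_iv) == (1, 0, 1, 1)

    def test_all_excluded_is_an_error(self):
        fa = stepminer_threshold([0.0, 0, 5, 5])
        with pytest.raises(InputError):
            quadrant_counts([2.5, 2.5], [2.5, 2.5], fa, fa)


class TestSahooTest:
    def test_worked_example(self):
        q = QuadrantCounts(40, 15, 40, 1)
        stat, err, sig = sahoo_test(q, "IV")
        assert stat == pytest.approx(3.9456, abs=1e-3)
        assert err == pytest.approx(1 / 41, abs=1e-6)
        assert sig

    def test_observed_equal_expected_not_significant(self):
        q = QuadrantCounts(10, 10, 10, 10)
        stat, _, sig = sahoo_test(q, "IV")
        assert stat == pytest.approx(0.0)
        assert not sig

    def test_statistic_threshold_is_strict(self):
        # counts chosen so expected = 16, observed = 4: statistic exactly 3.0
        # with error rate 1/12 < 0.1, isolating the strict ">" requirement
        q = QuadrantCounts(44, 52, 44, 4)
        stat, err, sig = sahoo_test(q, "IV")
        assert stat == pytest.approx(3.0)
        assert err < 0.1
        assert not sig

    def test_antisymmetry_around_expected(self):
        q = QuadrantCounts(40, 15, 40, 1)
        row, col = q.margins("IV")
        expected = row * col / q.total
        stat, _, _ = sahoo_test(q, "IV")
        mirrored = QuadrantCounts(40, 15, 40, int(round(2 * expected - 1)))
        # same margins are not preserved exactly, so compare the raw formula
        obs2 = 2 * expected - 1
        assert (expected - obs2) / np.sqrt(expected) == pytest.approx(-stat)


class TestSahooRules:
    def _vectors_with_sparse(self, sparse):
        """Build value vectors whose quadrant counts are 40 except `sparse` = 0."""
        counts = {"I": 40, "II": 40, "III": 40, "IV": 40}
        for quad in sparse:
            counts[quad] = 0
        xa, xb = [], []
        layout = {"I": (5, 5), "II": (0, 5), "III": (0, 0), "IV": (5, 0)}
        for quad, c in counts.items():
            a, b = layout[quad]
            xa += [a] * c
            xb += [b] * c
        # thresholds at 2.5 via symmetric low/high calibration vectors
        f = stepminer_threshold([0.0, 0, 5, 5])
        return xa, xb, f, f

    def test_single_sparse_quadrant_iv(self):
        assert sahoo_rules(*self._vectors_with_sparse({"IV"})) == {"A-high=>B-high"}

    def test_equivalent_replaces_pair(self):
        assert sahoo_rules(*self._vectors_with_sparse({"II", "IV"})) == {"equivalent"}

    def test_opposite_replaces_pair(self):
        assert sahoo_rules(*self._vectors_with_sparse({"I", "III"})) == {"opposite"}

    def test_no_sparse_quadrant_empty(self):
        assert sahoo_rules(*self._vectors_with_sparse(set())) == set()


def _chain_bbn():
    return DiscreteBBN(
        ["A", "B", "C"],
        {"A": ("B",), "B": (), "C": ("A", "B")},
        {
            "B": {(0,): 0.4, (1,): 0.6},
            "A": {(1, 1): 0.7, (1, 0): 0.3, (0, 1): 0.4, (0, 0): 0.6},
            "C": {
                (1, 1, 1): 0.7,
                (1, 1, 0): 0.3,
                (1, 0, 1): 0.2,
                (1, 0, 0): 0.8,
                (0, 1, 1): 0.5,
                (0, 1, 0): 0.5,
                (0, 0, 1): 0.1,
                (0, 0, 0): 0.9,
            },
        },
    )


class TestBBN:
    def test_chain_rule_worked_example(self):
        assert bbn_joint_probability(_chain_bbn(), {"A": 1, "B": 1, "C": 1}) == (
            pytest.approx(0.294)
        )

    def test_single_root(self):
        b = DiscreteBBN(["X"], {"X": ()}, {"X": {(0,): 0.4, (1,): 0.6}})
        assert bbn_joint_probability(b, {"X": 1}) == pytest.approx(0.6)

    def test_joint_normalizes(self):
        b = _chain_bbn()
        total = sum(
            bbn_joint_probability(b, dict(zip("ABC", states)))
            for states in itertools.product([0, 1], repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_random_dags_normalize(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(2, 5))
            nodes = [f"X{i}" for i in range(n)]
            parents = {
                nodes[i]: tuple(nodes[j] for j in range(i) if rng.random() < 0.5)
                for i in range(n)
            }
            cpts = {}
            for i, node in enumerate(nodes):
                cpt = {}
                for cond in itertools.product([0, 1], repeat=len(parents[node])):
                    p = float(rng.random())
                    cpt[cond + (0,)] = p
                    cpt[cond + (1,)] = 1.0 - p
                cpts[node] = cpt
            b = DiscreteBBN(nodes, parents, cpts)
            total = sum(
                bbn_joint_probability(b, dict(zip(nodes, s)))
                for s in itertools.product([0, 1], repeat=n)
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_cycle_rejected(self):
        with pytest.raises(InputError):
            DiscreteBBN(
                ["A", "B"],
                {"A": ("B",), "B": ("A",)},
                {
                    "A": {(0, 0): 0.5, (0, 1): 0.5, (1, 0): 0.5, (1, 1): 0.5},
                    "B": {(0, 0): 0.5, (0, 1): 0.5, (1, 0): 0.5, (1, 1): 0.5},
                },
            )

    def test_missing_cpt_entry(self):
        b = _chain_bbn()
        with pytest.raises(InputError):
            bbn_joint_probability(b, {"A": 1, "B": 2, "C": 1})
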