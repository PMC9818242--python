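"""Printed-formula baseline methods for network inference comparison.

Four families of reference methods accompany the prediction-logic networks:

* Pearson-correlation relevance networks (threshold on |r|).
* Shannon entropy and plug-in mutual information on discrete states.
* The classical binary Boolean-implication test of Sahoo-style networks:
  a per-gene step threshold (one-step least-squares fit), an intermediate
  exclusion zone of t ± 0.5 (log2-scale data), and a sparse-quadrant test
  (statistic > 3.0, error rate < 0.1).
* Joint-probability evaluation of a discrete Bayesian belief network by
  the chain rule P(X_1..X_n) = Π P(X_i | parents(X_i)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from .errors import InputError
from .matrix import ExpressionMatrix

__all__ = [
    "StepFit",
    "QuadrantCounts",
    "DiscreteBBN",
    "pearson_cc",
    "pcc_network",
    "categorical_entropy",
    "mutual_information",
    "stepminer_threshold",
    "quadrant_counts",
    "sahoo_test",
    "sahoo_rules",
    "bbn_joint_probability",
]


# ---------------------------------------------------------------------------
# relevance networks


def pearson_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise InputError("need at least two observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise InputError("correlation undefined for zero-variance input")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.dot(xc, xc)) * np.sqrt(np.dot(yc, yc))
    if denom == 0.0:  # variance underflow on denormal inputs
        raise InputError("correlation undefined for zero-variance input")
    return float(np.dot(xc, yc) / denom)


def pcc_network(
    expr: ExpressionMatrix, threshold: float, use_absolute: bool = True
) -> list[tuple[str, str, float]]:
    """Undirected relevance network: edge iff |PCC| (or signed PCC) ≥ threshold.

    Returns (gene_a, gene_b, r) tuples with gene_a < gene_b, sorted.
    Zero-variance genes are skipped with a warning.
    """
    if not 0.0 < threshold <= 1.0:
        raise InputError("threshold must lie in (0, 1]")
    import warnings

    values = expr.values
    sd = np.nanstd(values, axis=1)
    keep = np.flatnonzero(sd > 0)
    if keep.size < values.shape[0]:
        warnings.warn(
            f"skipping {values.shape[0] - keep.size} zero-variance gene(s)",
            stacklevel=2,
        )
    sub = values[keep]
    # row-standardize, then correlations come from one matrix product
    means = np.nanmean(sub, axis=1, keepdims=True)
    centered = np.where(np.isnan(sub), 0.0, sub - means)
    norms = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    r_mat = (centered / norms) @ (centered / norms).T
    score = np.abs(r_mat) if use_absolute else r_mat
    edges = []
    ids = [expr.gene_ids[i] for i in keep]
    iu, ju = np.triu_indices(len(ids), k=1)
    hit = score[iu, ju] >= threshold
    for i, j in zip(iu[hit], ju[hit]):
        a, b = sorted((ids[i], ids[j]))
        edges.append((a, b, float(r_mat[i, j])))
    edges.sort()
    return edges


# ---------------------------------------------------------------------------
# entropy and mutual information


def categorical_entropy(states: Sequence[Hashable]) -> float:
    """Plug-in Shannon entropy H = −Σ p log2 p (bits) of a discrete sample."""
    states = list(states)
    if not states:
        raise InputError("empty input")
    from collections import Counter

    counts = np.array(list(Counter(states).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(x: Sequence[Hashable], y: Sequence[Hashable]) -> float:
    """Plug-in mutual information MI(X,Y) = H(X) + H(Y) − H(X,Y) (bits)."""
    x, y = list(x), list(y)
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    joint = [(a, b) for a, b in zip(x, y)]
    mi = categorical_entropy(x) + categorical_entropy(y) - categorical_entropy(joint)
    return max(mi, 0.0) if mi > -1e-12 else mi


# ---------------------------------------------------------------------------
# Sahoo-style binary Boolean implication


@dataclass
class StepFit:
    """One-step least-squares fit of a sorted expression vector.

    ``threshold`` is the midpoint of the optimal left/right means; values in
    ``threshold ± intermediate_margin`` are "intermediate" and excluded from
    implication testing (the 0.5 margin presumes log2-scale data).
    """

    threshold: float
    left_mean: float
    right_mean: float
    sse: float
    intermediate_margin: float = 0.5

    def __post_init__(self) -> None:
        if self.left_mean > self.right_mean:
            raise InputError("left_mean must not exceed right_mean")
        if self.sse < 0:
            raise InputError("sse must be non-negative")

    def classify(self, value: float) -> str:
        """'low' / 'intermediate' / 'high' relative to the step threshold."""
        if value < self.threshold - self.intermediate_margin:
            return "low"
        if value > self.threshold + self.intermediate_margin:
            return "high"
        return "intermediate"


def stepminer_threshold(
    values: Sequence[float], intermediate_margin: float = 0.5
) -> StepFit:
    """Fit a one-step function to a vector and return its threshold.

    The values are sorted ascending and every split position k in [1, n−1]
    is scored by the summed squared error of a left-mean/right-mean step
    fit; the threshold is the midpoint of the optimal means.  SSE ties are
    broken by the most balanced split.
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    n = v.size
    if n < 4:
        raise InputError("need at least 4 values")
    if np.ptp(v) == 0.0:
        raise InputError("cannot fit a step to a constant vector")
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    ks = np.arange(1, n)
    left_sum, right_sum = csum[ks - 1], csum[-1] - csum[ks - 1]
    left_sq, right_sq = csq[ks - 1], csq[-1] - csq[ks - 1]
    left_mean = left_sum / ks
    right_mean = right_sum / (n - ks)
    sse = (left_sq - left_sum**2 / ks) + (right_sq - right_sum**2 / (n - ks))
    sse = np.maximum(sse, 0.0)  # numerical floor
    balance = np.abs(ks - (n - ks))
    best = np.lexsort((balance, np.round(sse, 12)))[0]
    return StepFit(
        threshold=float((left_mean[best] + right_mean[best]) / 2.0),
        left_mean=float(left_mean[best]),
        right_mean=float(right_mean[best]),
        sse=float(sse[best]),
        intermediate_margin=intermediate_margin,
    )


@dataclass
class QuadrantCounts:
    """High/low joint counts of a gene pair after intermediate-zone exclusion.

    Quadrants: I = A-high/B-high, II = A-low/B-high, III = A-low/B-low,
    IV = A-high/B-low.
    """

    a_i: int
    a_ii: int
    a_iii: int
    a_iv: int

    @property
    def total(self) -> int:
        return self.a_i + self.a_ii + self.a_iii + self.a_iv

    def margins(self, quadrant: str) -> tuple[int, int]:
        """(row, column) margins of the tested quadrant, e.g. IV → (n_Ahigh, n_Blow)."""
        n_a_high = self.a_i + self.a_iv
        n_a_low = self.a_ii + self.a_iii
        n_b_high = self.a_i + self.a_ii
        n_b_low = self.a_iii + self.a_iv
        table = {
            "I": (n_a_high, n_b_high),
            "II": (n_a_low, n_b_high),
            "III": (n_a_low, n_b_low),
            "IV": (n_a_high, n_b_low),
        }
        if quadrant not in table:
            raise InputError(f"unknown quadrant {quadrant!r}")
        return table[quadrant]

    def observed(self, quadrant: str) -> int:
        return {"I": self.a_i, "II": self.a_ii, "III": self.a_iii, "IV": self.a_iv}[
            quadrant
        ]


def quadrant_counts(
    xa: Sequence[float], xb: Sequence[float], fa: StepFit, fb: StepFit
) -> QuadrantCounts:
    """Assign samples to high/low quadrants, excluding intermediate values."""
    xa = np.asarray(list(xa), dtype=float)
    xb = np.asarray(list(xb), dtype=float)
    if xa.shape != xb.shape:
        raise InputError("xa and xb must have equal length")
    ca = np.array([fa.classify(v) for v in xa])
    cb = np.array([fb.classify(v) for v in xb])
    keep = (ca != "intermediate") & (cb != "intermediate")
    if not keep.any():
        raise InputError("all samples fall in an intermediate zone")
    a_high = ca[keep] == "high"
    b_high = cb[keep] == "high"
    return QuadrantCounts(
        a_i=int(np.sum(a_high & b_high)),
        a_ii=int(np.sum(~a_high & b_high)),
        a_iii=int(np.sum(~a_high & ~b_high)),
        a_iv=int(np.sum(a_high & ~b_high)),
    )


def sahoo_test(q: QuadrantCounts, quadrant: str) -> tuple[float, float, bool]:
    """Sparse-quadrant test: (statistic, error_rate, significant).

    With the tested quadrant's row margin R and column margin C,
    expected = R·C/total, statistic = (expected − observed)/sqrt(expected),
    error rate = (observed/R + observed/C)/2.  The quadrant is significantly
    sparse iff statistic > 3.0 and error rate < 0.1 (both strict).
    """
    row, col = q.margins(quadrant)
    if row == 0 or col == 0:
        raise InputError(f"quadrant {quadrant} has a zero margin")
    expected = row * col / q.total
    if expected == 0:
        raise InputError("expected count is zero; test undefined")
    observed = q.observed(quadrant)
    statistic = (expected - observed) / np.sqrt(expected)
    error_rate = 0.5 * (observed / row + observed / col)
    return float(statistic), float(error_rate), bool(statistic > 3.0 and error_rate < 0.1)


#: sparse quadrant → implied asymmetric rule (contrapositive of the empty corner)
_SPARSE_RULE = {
    "IV": "A-high=>B-high",
    "I": "A-high=>B-low",
    "II": "A-low=>B-low",
    "III": "A-low=>B-high",
}


def sahoo_rules(
    xa: Sequence[float], xb: Sequence[float], fa: StepFit, fb: StepFit
) -> set[str]:
    """Significant Boolean implication relations for one gene pair.

    Each significantly sparse quadrant contributes its asymmetric rule
    (a sparse quadrant IV, A-high/B-low, means "A high ⇒ B high").  Sparse
    II and IV together give "equivalent"; sparse I and III give "opposite";
    a symmetric relation replaces its constituent asymmetric pair.
    """
    q = quadrant_counts(xa, xb, fa, fb)
    sparse = set()
    for quad in ("I", "II", "III", "IV"):
        row, col = q.margins(quad)
        if row == 0 or col == 0:
            continue
        _, _, sig = sahoo_test(q, quad)
        if sig:
            sparse.add(quad)
    rules = {_SPARSE_RULE[quad] for quad in sparse}
    if {"II", "IV"} <= sparse:
        rules -= {_SPARSE_RULE["II"], _SPARSE_RULE["IV"]}
        rules.add("equivalent")
    if {"I", "III"} <= sparse:
        rules -= {_SPARSE_RULE["I"], _SPARSE_RULE["III"]}
        rules.add("opposite")
    return rules


# ---------------------------------------------------------------------------
# discrete Bayesian belief networks (joint-probability evaluation only)


@dataclass
class DiscreteBBN:
    """A discrete Bayesian belief network with explicit CPTs.

    ``parents`` maps node → ordered parent tuple (must be acyclic);
    ``cpts`` maps node → {(parent_states..., state): probability}.  A root
    node's CPT keys are 1-tuples ``(state,)``.  Only joint-probability
    evaluation is supported; structure learning is out of scope.
    """

    nodes: list[str]
    parents: Mapping[str, tuple[str, ...]]
    cpts: Mapping[str, Mapping[tuple, float]]
    _row_tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        order = self.topological_order()  # raises on cycles
        for node in self.nodes:
            if node not in self.cpts:
                raise InputError(f"node {node!r} has no CPT")
        for node, cpt in self.cpts.items():
            rows: dict[tuple, float] = {}
            for key, p in cpt.items():
                if not 0.0 <= p <= 1.0:
                    raise InputError(f"CPT probability out of [0,1] for {node!r}")
                rows[key[:-1]] = rows.get(key[:-1], 0.0) + p
            for cond, s in rows.items():
                if abs(s - 1.0) > self._row_tol:
                    raise InputError(
                        f"CPT row {cond} of node {node!r} sums to {s}, not 1"
                    )
        del order

    def topological_order(self) -> list[str]:
        indeg = {n: 0 for n in self.nodes}
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for node in self.nodes:
            for p in self.parents.get(node, ()):
                if p not in indeg:
                    raise InputError(f"unknown parent {p!r} of node {node!r}")
                indeg[node] += 1
                children[p].append(node)
        queue = sorted(n for n, d in indeg.items() if d == 0)
        out = []
        while queue:
            n = queue.pop(0)
            out.append(n)
            for ch in children[n]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
            queue.sort()
        if len(out) != len(self.nodes):
            raise InputError("parent sets contain a cycle")
        return out

    def node_states(self, node: str) -> list:
        return sorted({key[-1] for key in self.cpts[node]})


def bbn_joint_probability(b: DiscreteBBN, assignment: Mapping[str, Hashable]) -> float:
    """Joint probability of a full assignment by the chain rule Π P(X_i | parents)."""
    missing = [n for n in b.nodes if n not in assignment]
    if missing:
        raise InputError(f"assignment missing node(s): {missing}")
    prob = 1.0
    for node in b.nodes:
        key = tuple(assignment[p] for p in b.parents.get(node, ())) + (
            assignment[node],
        )
        try:
            prob *= b.cpts[node][key]
        except KeyError:
            raise InputError(
                f"no CPT entry for node {node!r} under assignment {key}"
            ) from None
    return prob
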