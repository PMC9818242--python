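"""Centrality metrics, hub calling, and the random-subnetwork permutation test.

Seven centrality notions are supported for prioritizing hub genes in
inferred networks: degree (total / in / out), eigenvector, closeness,
betweenness, and VoteRank.  Degree and eigenvector are local metrics
(only neighbors enter the computation); closeness, betweenness and
VoteRank are global.  Hub genes are nodes ranked within a top percentile
(10th by default) of a metric, and a gene subset's average centrality is
tested against draws of equally many random genes.

Standard metrics are delegated to networkx (degree normalized by N−1,
L2-normalized eigenvector via power iteration, Wasserman–Faust closeness
for disconnected graphs, Brandes betweenness with endpoint exclusion).
VoteRank is implemented here so that every node carries an explicit score:
the vote sum it had at the round it was elected, 0 if never elected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from .errors import InputError

__all__ = [
    "CentralityResult",
    "degree_centrality",
    "eigenvector_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "voterank_centrality",
    "all_centralities",
    "top_percentile_hubs",
    "subnetwork_centrality_test",
]

METRICS = (
    "degree",
    "in_degree",
    "out_degree",
    "eigenvector",
    "closeness",
    "betweenness",
    "voterank",
)


@dataclass
class CentralityResult:
    """node → value mapping for one centrality metric."""

    metric: str
    values: dict[str, float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [n for n, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise InputError(f"non-finite centrality for node(s) {bad[:5]}")

    def top(self, k: int) -> list[tuple[str, float]]:
        return sorted(self.values.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def _check_graph(g: nx.Graph) -> None:
    if any(u == v for u, v in g.edges()):
        raise InputError("graph must not contain self-loops")


def degree_centrality(
    g: nx.Graph, mode: Literal["total", "in", "out"] = "total", normalized: bool = True
) -> CentralityResult:
    """Neighbor counts, optionally divided by N−1."""
    _check_graph(g)
    if mode in ("in", "out") and not g.is_directed():
        raise InputError(f"mode {mode!r} requires a directed graph")
    if normalized and g.number_of_nodes() < 2:
        raise InputError("normalization needs at least 2 nodes")
    if mode == "in":
        deg = dict(g.in_degree())
    elif mode == "out":
        deg = dict(g.out_degree())
    else:
        deg = dict(g.degree())
    if normalized:
        scale = 1.0 / (g.number_of_nodes() - 1)
        values = {n: d * scale for n, d in deg.items()}
    else:
        values = {n: float(d) for n, d in deg.items()}
    name = {"total": "degree", "in": "in_degree", "out": "out_degree"}[mode]
    return CentralityResult(name, values, dict(normalized=normalized))


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-6, max_iter: int = 1000, directed: bool = False
) -> CentralityResult:
    """Principal-eigenvector centrality, L2-normalized, by power iteration.

    Directed inputs are projected to their undirected form by default
    (stable on graphs that are not strongly connected); set ``directed``
    to use the directed adjacency (left eigenvector, in-edge weighting).
    """
    _check_graph(g)
    if g.number_of_nodes() == 0:
        raise InputError("empty graph")
    h = g if (directed or not g.is_directed()) else g.to_undirected(as_view=False)
    try:
        values = nx.eigenvector_centrality(h, max_iter=max_iter, tol=tol)
    except nx.PowerIterationFailedConvergence as exc:
        raise InputError(
            f"eigenvector power iteration failed to converge in {max_iter} "
            f"iterations (tol {tol})"
        ) from exc
    return CentralityResult(
        "eigenvector",
        {n: float(v) for n, v in values.items()},
        dict(tol=tol, max_iter=max_iter, directed=directed),
    )


def closeness_centrality(g: nx.Graph) -> CentralityResult:
    """Wasserman–Faust closeness: ((r−1)/(N−1)) · ((r−1)/Σd) per node.

    r counts nodes reachable from the node (itself included), Σd sums the
    shortest-path distances to them; an isolated node scores 0, and the
    component scaling keeps disconnected graphs comparable.
    """
    _check_graph(g)
    values = nx.closeness_centrality(g, wf_improved=True)
    return CentralityResult(
        "closeness", {n: float(v) for n, v in values.items()}, dict(wf_improved=True)
    )


def betweenness_centrality(g: nx.Graph, normalized: bool = True) -> CentralityResult:
    """Shortest-path betweenness (Brandes accumulation, endpoints excluded)."""
    _check_graph(g)
    values = nx.betweenness_centrality(g, normalized=normalized)
    return CentralityResult(
        "betweenness", {n: float(v) for n, v in values.items()}, dict(normalized=normalized)
    )


def voterank_centrality(g: nx.Graph, r: int | None = None) -> CentralityResult:
    """VoteRank influence scores.

    All nodes start with voting ability 1.  Each round, every node's vote
    sum is the total ability of its neighbors; the node with the largest
    vote sum (ties: lexicographically smallest id) is elected, its vote sum
    at election becomes its score, its own ability drops to 0, and each of
    its neighbors loses 1/⟨k⟩ ability (floored at 0), ⟨k⟩ being the mean
    degree of the graph.  Elections stop after ``r`` rounds (default: as
    many as remain electable) or when no positive vote sum remains; nodes
    never elected score 0.
    """
    _check_graph(g)
    nodes = sorted(g.nodes())
    scores = {n: 0.0 for n in nodes}
    if not nodes:
        return CentralityResult("voterank", scores, dict(r=r))
    und = g.to_undirected(as_view=False) if g.is_directed() else g
    n_edges = und.number_of_edges()
    if n_edges == 0:
        return CentralityResult("voterank", scores, dict(r=r))
    avg_k = 2.0 * n_edges / len(nodes)
    ability = {n: 1.0 for n in nodes}
    elected: set[str] = set()
    rounds = len(nodes) if r is None else min(r, len(nodes))
    for _ in range(rounds):
        votes = {
            n: sum(ability[nb] for nb in und.neighbors(n))
            for n in nodes
            if n not in elected
        }
        if not votes:
            break
        winner = min(votes, key=lambda n: (-votes[n], n))
        if votes[winner] <= 0.0:
            break
        scores[winner] = votes[winner]
        elected.add(winner)
        ability[winner] = 0.0
        for nb in und.neighbors(winner):
            ability[nb] = max(ability[nb] - 1.0 / avg_k, 0.0)
    return CentralityResult("voterank", scores, dict(r=r, mean_degree=avg_k))


def all_centralities(g: nx.Graph) -> dict[str, CentralityResult]:
    """Every applicable metric for a graph (in/out degree only if directed)."""
    out = {
        "degree": degree_centrality(g),
        "eigenvector": eigenvector_centrality(g),
        "closeness": closeness_centrality(g),
        "betweenness": betweenness_centrality(g),
        "voterank": voterank_centrality(g),
    }
    if g.is_directed():
        out["in_degree"] = degree_centrality(g, mode="in")
        out["out_degree"] = degree_centrality(g, mode="out")
    return out


def top_percentile_hubs(c: CentralityResult, pct: float = 10.0) -> set[str]:
    """Nodes ranked within the top ``pct`` percentile of the metric, ties included.

    The cutoff is the k-th largest value with k = ceil(pct/100 · n); every
    node at or above the cutoff is a hub, so ties at the cutoff are all
    included.
    """
    if not 0.0 < pct < 100.0:
        raise InputError("pct must lie in (0, 100)")
    if not c.values:
        return set()
    vals = np.array(sorted(c.values.values(), reverse=True))
    k = int(np.ceil(pct / 100.0 * vals.size))
    cutoff = vals[k - 1]
    return {n for n, v in c.values.items() if v >= cutoff}


def subnetwork_centrality_test(
    c: CentralityResult,
    subset: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Permutation test: is the subset's mean centrality high for its size?

    Draws ``n_perm`` random node subsets of the same size (uniformly,
    without replacement, seeded) and reports the fraction whose mean
    centrality is ≥ the observed mean — ties favor the null, and the plain
    fraction is used without smoothing.  Returns
    ``(p_value, observed_mean, null_means)``.
    """
    subset = list(dict.fromkeys(subset))
    if not subset:
        raise InputError("subset must be non-empty")
    missing = [n for n in subset if n not in c.values]
    if missing:
        raise InputError(f"subset node(s) not in centrality result: {missing[:5]}")
    nodes = sorted(c.values)
    vals = np.array([c.values[n] for n in nodes])
    observed = float(np.mean([c.values[n] for n in subset]))
    rng = np.random.default_rng(seed)
    k = len(subset)
    null_means = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(vals.size, size=k, replace=False)
        null_means[i] = vals[idx].mean()
    p = float(np.mean(null_means >= observed)) if n_perm > 0 else float("nan")
    return p, observed, null_means
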