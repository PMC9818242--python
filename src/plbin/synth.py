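"""Seeded synthetic-data generators for every input class the toolkit consumes.

The generators are pure functions of their parameters and seed, and carry
plantable structure so that categorization, network induction, centrality
and validation can all be exercised without downloading any accession:

* iid null categorical matrices (ternary state proportions default to
  0.15/0.70/0.15, mirroring a 30% outside-normal mass);
* matrices with planted implication rules at a chosen contamination rate;
* Gaussian expression matrices with a housekeeping panel of known spread;
* sparse single-cell count matrices with a dropout-controlled zero fraction;
* small named graph topologies for centrality checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .errors import InputError
from .implication import TEMPLATE_ORDER, default_templates
from .matrix import CategorizedMatrix, ExpressionMatrix

__all__ = [
    "PlantedRuleSpec",
    "gen_null_categorical",
    "gen_planted_implications",
    "gen_expression_with_housekeeping",
    "gen_single_cell_counts",
    "gen_toy_graph",
]

DEFAULT_TERNARY_PROBS = (0.15, 0.70, 0.15)  # P(down), P(normal), P(up)


@dataclass(frozen=True)
class PlantedRuleSpec:
    """One implication rule to plant between two gene indices.

    ``contamination`` ε is the per-sample probability that the target state
    is drawn from the unconstrained null instead of the rule-consistent
    conditional, so error cells fill at rate ≈ ε × (null error mass).
    ``source_probs`` are the source gene's state probabilities (null
    proportions by default).
    """

    source_id: int
    target_id: int
    template: str
    contamination: float = 0.0
    source_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination < 0.5:
            raise InputError("contamination must lie in [0, 0.5)")
        if self.template not in TEMPLATE_ORDER:
            raise InputError(f"unknown template {self.template!r}")
        if self.source_probs is not None and abs(sum(self.source_probs) - 1.0) > 1e-9:
            raise InputError("source_probs must sum to 1")


def _check_probs(probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size not in (2, 3) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
        raise InputError("state_probs must be 2 or 3 non-negative values summing to 1")
    return p


def gen_null_categorical(
    n_genes: int,
    n_samples: int,
    state_probs: Sequence[float] = DEFAULT_TERNARY_PROBS,
    seed: int | None = None,
) -> CategorizedMatrix:
    """iid categorical states per gene and sample (no dependence structure).

    Three probabilities (down, normal, up order) give a ternary matrix, two
    (low, high) a binary one.
    """
    p = _check_probs(state_probs)
    arity = p.size
    states_set = (-1, 0, 1) if arity == 3 else (0, 1)
    rng = np.random.default_rng(seed)
    draws = rng.choice(states_set, size=(n_genes, n_samples), p=p)
    return CategorizedMatrix(
        gene_ids=[f"G{i}" for i in range(n_genes)],
        sample_ids=[f"S{j}" for j in range(n_samples)],
        states=draws.astype(float),
        arity=int(arity),
        provenance=f"null iid categorical, probs={tuple(p.tolist())}, seed={seed}",
    )


def gen_planted_implications(
    specs: Sequence[PlantedRuleSpec],
    n_genes: int,
    n_samples: int,
    state_probs: Sequence[float] = DEFAULT_TERNARY_PROBS,
    seed: int | None = None,
) -> CategorizedMatrix:
    """Null matrix with implication rules planted between chosen gene pairs.

    For each spec, the source gene is drawn iid from its state
    probabilities; each target state is, with probability 1 − ε, drawn from
    the null distribution restricted (and renormalized) to the states that
    do not contradict the planted rule given the source state, and with
    probability ε from the unrestricted null.  At ε = 0 the rule's strict
    error cells are therefore exactly empty.
    """
    p = _check_probs(state_probs)
    arity = int(p.size)
    states_set = np.array((-1, 0, 1) if arity == 3 else (0, 1), dtype=float)
    m = gen_null_categorical(n_genes, n_samples, state_probs, seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    templates = {t.name: t for t in default_templates(arity, arity, "strict")}

    targets_seen: set[int] = set()
    for spec in specs:
        for idx in (spec.source_id, spec.target_id):
            if not 0 <= idx < n_genes:
                raise InputError(f"gene index {idx} out of range [0, {n_genes})")
        if spec.source_id == spec.target_id:
            raise InputError("source and target must differ")
        if spec.target_id in targets_seen:
            raise InputError(
                f"overlapping specs: target index {spec.target_id} planted twice"
            )
        targets_seen.add(spec.target_id)

        src_p = np.asarray(spec.source_probs, dtype=float) if spec.source_probs else p
        if src_p.size != arity:
            raise InputError("source_probs arity mismatch")
        src = rng.choice(states_set, size=n_samples, p=src_p)
        error_cells = templates[spec.template].error_cells
        # rule-consistent conditional per source state
        allowed_p = {}
        for s in states_set:
            allowed = np.array(
                [t for t in states_set if (int(s), int(t)) not in error_cells]
            )
            mass = p[np.isin(states_set, allowed)]
            allowed_p[float(s)] = (allowed, mass / mass.sum())
        tgt = np.empty(n_samples)
        contaminate = rng.random(n_samples) < spec.contamination
        for i in range(n_samples):
            if contaminate[i]:
                tgt[i] = rng.choice(states_set, p=p)
            else:
                allowed, ap = allowed_p[float(src[i])]
                tgt[i] = rng.choice(allowed, p=ap)
        m.states[spec.source_id] = src
        m.states[spec.target_id] = tgt
    m.provenance += f"; planted {len(specs)} rule(s)"
    return m


def gen_expression_with_housekeeping(
    n_genes: int,
    n_samples: int,
    n_hk: int,
    hk_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Gaussian log-scale expression with a stable housekeeping panel.

    Every gene is Gaussian with its own mean (uniform on [4, 12], a typical
    log2 microarray range); the first ``n_hk`` genes form the housekeeping
    panel and share the standard deviation ``hk_sd``, the rest draw their
    SD uniformly from [0.5, 2.5].
    """
    if n_hk > n_genes:
        raise InputError("n_hk cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    means = rng.uniform(4.0, 12.0, size=n_genes)
    sds = rng.uniform(0.5, 2.5, size=n_genes)
    sds[:n_hk] = hk_sd
    values = rng.normal(means[:, None], sds[:, None], size=(n_genes, n_samples))
    gene_ids = [f"HK{i}" if i < n_hk else f"G{i}" for i in range(n_genes)]
    expr = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"S{j}" for j in range(n_samples)],
        values=values,
        omics_kind="mrna",
    )
    return expr, gene_ids[:n_hk]


def gen_single_cell_counts(
    n_genes: int,
    n_cells: int,
    dropout: float = 0.8,
    mean_count: float = 2.0,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Sparse single-cell feature counts with a controlled zero fraction.

    Each entry is Bernoulli(1 − dropout) × a zero-truncated Poisson with
    rate ``mean_count``, so the expected zero fraction equals ``dropout``
    exactly (all zeros come from dropout).
    """
    if not 0.0 <= dropout < 1.0:
        raise InputError("dropout must lie in [0, 1)")
    if mean_count <= 0:
        raise InputError("mean_count must be positive")
    rng = np.random.default_rng(seed)
    detected = rng.random((n_genes, n_cells)) >= dropout
    # zero-truncated Poisson via inverse CDF restricted above P(X=0)
    p0 = float(np.exp(-mean_count))
    u = rng.uniform(p0, 1.0, size=(n_genes, n_cells))
    counts = stats.poisson.ppf(u, mean_count)
    values = np.where(detected, counts, 0.0)
    return ExpressionMatrix(
        gene_ids=[f"G{i}" for i in range(n_genes)],
        sample_ids=[f"C{j}" for j in range(n_cells)],
        values=values,
        omics_kind="sc_counts",
    )


def gen_toy_graph(
    kind: str,
    n: int,
    p: float | None = None,
    seed: int | None = None,
    directed: bool = False,
) -> nx.Graph:
    """Named toy topologies: star, path, complete, or a seeded Erdős–Rényi graph.

    ``n`` is the total node count (a star with n nodes has one center and
    n − 1 leaves).  Nodes are labeled ``n0..n{n-1}``; for a star, ``n0`` is
    the center.
    """
    if n < 1:
        raise InputError("n must be positive")
    if kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "erdos_renyi":
        if p is None:
            raise InputError("erdos_renyi requires an edge probability p")
        g = nx.gnp_random_graph(n, p, seed=seed, directed=directed)
    else:
        raise InputError(f"unknown graph kind {kind!r}")
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
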