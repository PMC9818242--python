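"""Gene-set-based validation of inferred networks.

An inferred co-expression edge is a true positive (TP) if its two genes
co-occur in at least one gene set of any examined collection, a false
positive (FP) if both genes are annotated somewhere but never share a set,
and non-discriminatory (ND) if either gene is absent from the annotated
universe.  Network precision is TP/(TP+FP); ND edges are not confirmatory
and are excluded.  Statistical significance and an FDR come from
re-deriving the network under permuted class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError
from .matrix import ExpressionMatrix

__all__ = [
    "GeneSetCollection",
    "PrecisionReport",
    "PermutationReport",
    "label_edges",
    "network_precision",
    "permutation_fdr",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): set name → gene-id set."""

    name: str
    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise InputError(f"empty gene set(s): {empty[:5]}")

    @property
    def universe(self) -> frozenset[str]:
        """All genes annotated anywhere in this collection."""
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)


@dataclass
class PrecisionReport:
    tp: int
    fp: int
    nd: int
    precision: float  # NaN when tp + fp == 0

    @property
    def defined(self) -> bool:
        return self.tp + self.fp > 0


@dataclass
class PermutationReport:
    observed_precision: float
    null_precisions: list[float]
    fdr: float
    p_value: float
    n_perm: int
    seed: int | None
    n_undefined_permutations: int


def label_edges(
    edges: Sequence[tuple[str, str]], collections: Sequence[GeneSetCollection]
) -> list[str]:
    """Label each gene pair TP / FP / ND against the collections.

    TP: the pair shares ≥1 set in ≥1 collection.  ND: either gene is
    unannotated in the union of all collections.  FP otherwise.  Labels are
    symmetric in the pair.
    """
    if not collections:
        raise InputError("at least one gene-set collection is required")
    universe: set[str] = set()
    membership: dict[str, set[tuple[str, str]]] = {}
    for coll in collections:
        for set_name, genes in coll.sets.items():
            key = (coll.name, set_name)
            for gene in genes:
                membership.setdefault(gene, set()).add(key)
        universe |= coll.universe
    labels = []
    for a, b in edges:
        if a not in universe or b not in universe:
            labels.append("ND")
        elif membership.get(a, set()) & membership.get(b, set()):
            labels.append("TP")
        else:
            labels.append("FP")
    return labels


def network_precision(labels: Iterable[str]) -> PrecisionReport:
    """Precision TP/(TP+FP) of a labeled edge list; ND edges are excluded."""
    counts = {"TP": 0, "FP": 0, "ND": 0}
    for lab in labels:
        if lab not in counts:
            raise InputError(f"unknown edge label {lab!r}")
        counts[lab] += 1
    tp, fp, nd = counts["TP"], counts["FP"], counts["ND"]
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    return PrecisionReport(tp=tp, fp=fp, nd=nd, precision=precision)


def permutation_fdr(
    expr: ExpressionMatrix,
    class_labels: Sequence,
    derive_fn: Callable[[ExpressionMatrix, Sequence], Sequence[tuple[str, str]]],
    collections: Sequence[GeneSetCollection],
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationReport:
    """Permutation FDR and significance for a class-label-derived network.

    ``derive_fn(matrix, labels)`` must deterministically return the edge
    list for a labeling.  The null distribution shuffles the class labels
    ``n_perm`` times (seeded); each permutation's FP/(TP+FP) enters the FDR
    mean (permutations with no TP+FP edges are counted separately and
    excluded), and the p-value is the fraction of permutations whose
    precision is ≥ the observed precision.
    """
    labels = list(class_labels)
    if len(labels) != expr.n_samples:
        raise InputError("class_labels length must equal the number of samples")
    if len(set(labels)) < 2:
        raise InputError("need at least 2 distinct classes")
    observed_edges = list(derive_fn(expr, labels))
    observed = network_precision(label_edges(observed_edges, collections)).precision

    rng = np.random.default_rng(seed)
    null_precisions: list[float] = []
    fp_rates: list[float] = []
    n_undef = 0
    arr = np.asarray(labels, dtype=object)
    for i in range(n_perm):
        perm = arr[rng.permutation(arr.size)]
        try:
            edges = list(derive_fn(expr, perm.tolist()))
        except Exception as exc:
            raise InputError(f"derive_fn failed on permutation {i}: {exc}") from exc
        rep = network_precision(label_edges(edges, collections))
        if rep.defined:
            null_precisions.append(rep.precision)
            fp_rates.append(rep.fp / (rep.tp + rep.fp))
        else:
            n_undef += 1
    fdr = float(np.mean(fp_rates)) if fp_rates else 0.0
    if n_perm > 0 and not np.isnan(observed):
        p_value = sum(p >= observed for p in null_precisions) / n_perm
    else:
        p_value = float("nan")
    return PermutationReport(
        observed_precision=observed,
        null_precisions=null_precisions,
        fdr=fdr,
        p_value=float(p_value),
        n_perm=n_perm,
        seed=seed,
        n_undefined_permutations=n_undef,
    )
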