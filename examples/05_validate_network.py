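"""Gene-set validation: TP/FP/ND labels, network precision, permutation FDR.

Labels inferred edges against two toy gene-set collections, then runs the
class-label permutation test with a derivation callback that only finds its
edge under the true sample classes.
"""

import numpy as np

from plbin import (
    ExpressionMatrix,
    GeneSetCollection,
    label_edges,
    network_precision,
    permutation_fdr,
)

collections = [
    GeneSetCollection("pathways", {"P1": {"A", "B", "C"}, "P2": {"C", "D"}}),
    GeneSetCollection("motifs", {"M1": {"B", "D"}}),
]
edges = [("A", "B"), ("A", "D"), ("B", "E")]
labels = label_edges(edges, collections)
rep = network_precision(labels)
print("edge labels:", dict(zip(edges, labels)))
print(f"precision = TP/(TP+FP) = {rep.tp}/{rep.tp + rep.fp} = {rep.precision}")

rng = np.random.default_rng(0)
expr = ExpressionMatrix(
    ["A", "B", "C", "D"], [f"s{i}" for i in range(12)], rng.normal(size=(4, 12))
)
truth = ["tumor"] * 6 + ["normal"] * 6

def derive(_matrix, class_labels):
    # stand-in for a class-conditional network derivation: the signal edge
    # only appears under the true tumor/normal split
    return [("A", "B")] if list(class_labels) == truth else []

perm = permutation_fdr(expr, truth, derive, collections, n_perm=200, seed=1)
print(f"\nobserved precision: {perm.observed_precision}")
print(f"permutation p = {perm.p_value}, FDR = {perm.fdr} "
      f"({perm.n_undefined_permutations}/200 permutations produced no edges)")
# ND edges never enter precision; permutations with no TP+FP edges are
# reported but excluded from the FDR mean.
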