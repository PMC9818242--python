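"""Prediction-logic Boolean implication networks.

An implication rule between two categorized genes ("A up implies B up") is
scored on their pairwise contingency table through its *error cells* — the
cells whose occupancy contradicts the rule.  With ``N`` retained samples,
row margins ``N_i.``, column margins ``N_.j`` and error-cell indicator
``ω_ij``, the rule's

* scope is the independence-expected error mass
  ``U_p = Σ_ω N_i. N_.j / N²`` — how much of the table the rule bets on;
* precision is the proportional reduction of error
  ``∇_p = 1 − (K/N) / U_p`` with ``K = Σ_ω N_ij`` the observed error count
  (1 = perfect rule, 0 = independence, negative = worse than chance).

Under independence K is Binomial(N, U_p), giving the one-tailed selection
test ``z = (N·U_p − K) / sqrt(N·U_p·(1−U_p)) ≥ z_preset`` (default 1.645,
α = 0.05).  Six rule templates are evaluated per ordered gene pair — four
asymmetric (UP_UP, DOWN_DOWN, UP_DOWN, DOWN_UP) and two symmetric
(EQUIVALENT, OPPOSITE) — and one winning rule per pair is kept.  Unlike
binary-only Boolean implication methods, the error-cell formulation applies
unchanged to ternary (down/normal/up) states, so categorized CNV and
expression data need no information-losing binarization.

Genome-scale induction evaluates all ordered pairs in O(n²) via blocked
indicator-matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .matrix import CategorizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "StateVector",
    "ContingencyTable",
    "RuleTemplate",
    "RuleStats",
    "ImplicationEdge",
    "ImplicationNetwork",
    "TEMPLATE_ORDER",
    "SYMMETRIC_TEMPLATES",
    "build_contingency",
    "default_templates",
    "rule_stats",
    "precision_weighted_form",
    "select_rule",
    "induce_network",
]

#: fixed template evaluation / tie-break order
TEMPLATE_ORDER = ("UP_UP", "DOWN_DOWN", "UP_DOWN", "DOWN_UP", "EQUIVALENT", "OPPOSITE")
SYMMETRIC_TEMPLATES = frozenset({"EQUIVALENT", "OPPOSITE"})

_DEFAULT_Z = 1.645


@dataclass
class StateVector:
    """Discrete states of one variable across samples (NaN = missing)."""

    variable_id: str
    states: np.ndarray
    arity: int = 3

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        allowed = (-1, 0, 1) if self.arity == 3 else (0, 1)
        obs = self.states[~np.isnan(self.states)]
        if obs.size and not np.isin(obs, allowed).all():
            raise InputError(f"states of {self.variable_id!r} outside {allowed}")

    @property
    def state_set(self) -> tuple[int, ...]:
        return (-1, 0, 1) if self.arity == 3 else (0, 1)


@dataclass
class ContingencyTable:
    """Joint state counts of an ordered variable pair (rows = A, cols = B)."""

    row_states: tuple[int, ...]
    col_states: tuple[int, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_states), len(self.col_states)):
            raise InputError("counts shape does not match state lists")
        if (self.counts < 0).any():
            raise InputError("counts must be non-negative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.col_states, self.row_states, self.counts.T)


@dataclass(frozen=True)
class RuleTemplate:
    """An implication rule as its set of contradicting (error) cells.

    ``error_cells`` holds (row_state, col_state) pairs; ω_ij = 1 inside the
    set, 0 outside.
    """

    name: str
    error_cells: frozenset[tuple[int, int]]
    semantics: Literal["strict", "lenient"] = "strict"

    def __post_init__(self) -> None:
        if not self.error_cells:
            raise InputError(f"template {self.name} has no error cells")

    def transpose(self) -> "RuleTemplate":
        return RuleTemplate(
            self.name, frozenset((j, i) for i, j in self.error_cells), self.semantics
        )


@dataclass(slots=True)
class RuleStats:
    """Scope, precision and selection test for one rule on one table."""

    scope: float
    precision: float  # NaN when scope == 0 (undefined)
    error_count: int
    z_stat: float
    scope_feasible: bool
    significant: bool
    n: int


@dataclass(slots=True)
class ImplicationEdge:
    source_id: str
    target_id: str
    template: str
    stats: RuleStats


@dataclass
class ImplicationNetwork:
    """Directed multigraph of selected implication rules."""

    node_ids: list[str]
    edges: list[ImplicationEdge]
    params: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                e.source_id,
                e.target_id,
                e.template,
                e.stats.scope,
                e.stats.precision,
                e.stats.z_stat,
                e.stats.n,
            )
            for e in self.edges
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "rule", "scope", "precision", "z", "n"]
        )

    def to_networkx(self):
        """Directed multigraph view (symmetric rules appear once, canonical direction)."""
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(self.node_ids)
        for e in self.edges:
            g.add_edge(
                e.source_id,
                e.target_id,
                rule=e.template,
                scope=e.stats.scope,
                precision=e.stats.precision,
                z=e.stats.z_stat,
                n=e.stats.n,
            )
        return g


# ---------------------------------------------------------------------------
# contingency tables and rule templates


def build_contingency(a: StateVector, b: StateVector) -> ContingencyTable:
    """Cross-tabulate two state vectors with pairwise deletion of missing samples."""
    if a.states.shape != b.states.shape:
        raise InputError("state vectors differ in length")
    keep = ~np.isnan(a.states) & ~np.isnan(b.states)
    if not keep.any():
        raise InputError(
            f"no samples retained for pair ({a.variable_id}, {b.variable_id})"
        )
    row_states, col_states = a.state_set, b.state_set
    av, bv = a.states[keep], b.states[keep]
    counts = np.zeros((len(row_states), len(col_states)), dtype=np.int64)
    for i, s in enumerate(row_states):
        mask = av == s
        for j, t in enumerate(col_states):
            counts[i, j] = int(np.sum(mask & (bv == t)))
    return ContingencyTable(tuple(row_states), tuple(col_states), counts)


def _up_down(arity: int) -> tuple[int, int]:
    # UP/HIGH is always state 1; DOWN is -1 for ternary, LOW=0 for binary
    return (1, -1) if arity == 3 else (1, 0)


def default_templates(
    arity_a: int, arity_b: int, semantics: Literal["strict", "lenient"] = "strict"
) -> list[RuleTemplate]:
    """The six implication rule templates for a variable pair.

    Strict semantics counts a cell as an error when the antecedent holds and
    the consequent fails ("A up ⇒ B up" is contradicted by any A-up sample
    that is not B-up).  Lenient semantics only counts outright contradictions,
    dropping error cells that involve the NORMAL state of a ternary variable.
    For binary variables the two coincide with the classical quadrant rules.
    """
    if arity_a not in (2, 3) or arity_b not in (2, 3):
        raise InputError("arities must be 2 or 3")
    if semantics not in ("strict", "lenient"):
        raise InputError(f"unknown semantics {semantics!r}")
    states_a = (-1, 0, 1) if arity_a == 3 else (0, 1)
    states_b = (-1, 0, 1) if arity_b == 3 else (0, 1)
    up_a, down_a = _up_down(arity_a)
    up_b, down_b = _up_down(arity_b)

    def fwd(antecedent: int, consequent: int) -> set[tuple[int, int]]:
        return {(antecedent, s) for s in states_b if s != consequent}

    def rev(antecedent: int, consequent: int) -> set[tuple[int, int]]:
        # antecedent on B, consequent on A: error cells (a, antecedent), a != consequent
        return {(s, antecedent) for s in states_a if s != consequent}

    # OPPOSITE pairs "A up ⇒ B down" with "B up ⇒ A down"; for two binary
    # variables the second is the contrapositive of the first, so the
    # classical quadrant rule (high/high and low/low both forbidden) is used
    # instead of the degenerate single-cell union
    if arity_a == 2 and arity_b == 2:
        opposite = fwd(up_a, down_b) | fwd(down_a, up_b)
    else:
        opposite = fwd(up_a, down_b) | rev(up_b, down_a)
    cells = {
        "UP_UP": fwd(up_a, up_b),
        "DOWN_DOWN": fwd(down_a, down_b),
        "UP_DOWN": fwd(up_a, down_b),
        "DOWN_UP": fwd(down_a, up_b),
        "EQUIVALENT": fwd(up_a, up_b) | rev(up_b, up_a),
        "OPPOSITE": opposite,
    }
    if semantics == "lenient":
        for name, cc in cells.items():
            cells[name] = {
                (i, j)
                for (i, j) in cc
                if not ((arity_a == 3 and i == 0) or (arity_b == 3 and j == 0))
            }
    return [
        RuleTemplate(name, frozenset(cells[name]), semantics) for name in TEMPLATE_ORDER
    ]


# ---------------------------------------------------------------------------
# scope / precision / z


def _cell_indices(
    t: ContingencyTable, r: RuleTemplate
) -> tuple[np.ndarray, np.ndarray]:
    ri = {s: i for i, s in enumerate(t.row_states)}
    ci = {s: j for j, s in enumerate(t.col_states)}
    try:
        idx = [(ri[i], ci[j]) for i, j in sorted(r.error_cells)]
    except KeyError as exc:
        raise InputError(
            f"template {r.name} error cell uses state {exc.args[0]} "
            "absent from the table's state grid"
        ) from None
    rows, cols = zip(*idx)
    return np.asarray(rows), np.asarray(cols)


def rule_stats(
    t: ContingencyTable,
    r: RuleTemplate,
    z_preset: float = _DEFAULT_Z,
    min_expected_errors: float | None = None,
) -> RuleStats:
    """Scope U_p, precision ∇_p, error count K and one-tailed z for one rule.

    ``scope_feasible`` requires U_p ≥ z²/(N + z²), the smallest scope at
    which even a perfect rule (K = 0) can reach the preset z.
    ``min_expected_errors`` optionally also requires N·U_p to reach a floor
    before the normal approximation is trusted (off by default).
    A degenerate rule with U_p = 0 is returned with NaN precision and
    ``significant = False``.
    """
    n = t.total
    if n < 1:
        raise InputError("empty contingency table")
    rows, cols = _cell_indices(t, r)
    rm, cm = t.row_margins, t.col_margins
    scope = float(np.sum(rm[rows] * cm[cols])) / (n * n)
    k = int(np.sum(t.counts[rows, cols]))
    if scope <= 0.0:
        return RuleStats(0.0, float("nan"), k, float("nan"), False, False, n)
    precision = 1.0 - (k / n) / scope
    denom = np.sqrt(n * scope * (1.0 - scope))
    num = n * scope - k
    if denom == 0.0:
        z = 0.0 if num == 0 else float(np.sign(num)) * float("inf")
    else:
        z = float(num / denom)
    feasible = scope >= z_preset**2 / (n + z_preset**2)
    if min_expected_errors is not None and n * scope < min_expected_errors:
        feasible = False
    significant = bool(z >= z_preset and feasible and precision > 0.0)
    return RuleStats(scope, precision, k, z, feasible, significant, n)


def precision_weighted_form(t: ContingencyTable, r: RuleTemplate) -> float:
    """Precision as the error-cell-weighted sum ``Σ ω_ij (U_ij/U_p) ∇_ij``.

    Per-cell scope is ``U_ij = N_i. N_.j / N²`` and per-cell precision
    ``∇_ij = 1 − (N_ij/N)/U_ij``; cells with zero margin product contribute
    nothing.  Algebraically identical to the closed form used by
    :func:`rule_stats`; kept as an independently-coded route for
    verification.
    """
    n = t.total
    rows, cols = _cell_indices(t, r)
    rm, cm = t.row_margins, t.col_margins
    u_cells = rm[rows] * cm[cols] / (n * n)
    u_p = float(u_cells.sum())
    if u_p <= 0.0:
        return float("nan")
    acc = 0.0
    for u_ij, cnt in zip(u_cells, t.counts[rows, cols]):
        if u_ij > 0:
            nabla_ij = 1.0 - (cnt / n) / u_ij
            acc += (u_ij / u_p) * nabla_ij
    return acc


def select_rule(
    t: ContingencyTable,
    templates: Sequence[RuleTemplate],
    z_preset: float = _DEFAULT_Z,
    policy: Literal["precision_first", "strict_dominance"] = "precision_first",
    min_expected_errors: float | None = None,
) -> tuple[RuleTemplate, RuleStats] | None:
    """Pick the winning rule for one pair, or None if no template is significant.

    ``precision_first`` returns the significant template with maximal
    precision, ties broken by larger scope, then by the fixed template order.
    ``strict_dominance`` returns a significant template only if it
    simultaneously attains the maximal precision *and* maximal scope over
    all evaluated templates.
    """
    if not templates:
        raise InputError("no templates given")
    stats = [rule_stats(t, r, z_preset, min_expected_errors) for r in templates]
    if policy == "precision_first":
        best: tuple[RuleTemplate, RuleStats] | None = None
        for r, s in zip(templates, stats):
            if not s.significant:
                continue
            if best is None:
                best = (r, s)
            else:
                bs = best[1]
                if s.precision > bs.precision or (
                    s.precision == bs.precision and s.scope > bs.scope
                ):
                    best = (r, s)
        return best
    if policy == "strict_dominance":
        eps = 1e-12
        max_prec = max(
            (s.precision for s in stats if not np.isnan(s.precision)),
            default=float("nan"),
        )
        max_scope = max(s.scope for s in stats)
        for r, s in zip(templates, stats):
            if (
                s.significant
                and s.precision >= max_prec - eps
                and s.scope >= max_scope - eps
            ):
                return (r, s)
        return None
    raise InputError(f"unknown selection policy {policy!r}")


# ---------------------------------------------------------------------------
# genome-scale induction


def _state_indicators(m: CategorizedMatrix):
    x = m.states
    valid = ~np.isnan(x)
    states = m.state_set
    ind = {s: ((x == s) & valid).astype(np.float32) for s in states}
    return ind, valid.astype(np.float32)


def induce_network(
    m: CategorizedMatrix,
    z_preset: float = _DEFAULT_Z,
    semantics: Literal["strict", "lenient"] = "strict",
    policy: Literal["precision_first", "strict_dominance"] = "precision_first",
    chunk_size: int = 256,
    min_samples: int = 10,
    min_expected_errors: float | None = None,
) -> ImplicationNetwork:
    """Induce the implication network over all ordered gene pairs of ``m``.

    Every ordered pair (A, B), A ≠ B, is scored on all six templates and at
    most one rule per pair is selected (see :func:`select_rule`).  Genes
    with fewer than two observed states are skipped (their margins make
    every directed template degenerate); pairs retaining fewer than
    ``min_samples`` samples after pairwise deletion are skipped.  Edges with
    a symmetric rule (EQUIVALENT/OPPOSITE) are emitted once per unordered
    pair, in lexicographic direction.  Pair evaluation is blocked and
    vectorized (indicator-matrix products), so induction over all n² pairs
    of a few thousand genes takes seconds to minutes on one CPU; output is
    deterministic given inputs.
    """
    states = m.state_set
    x = m.states
    n_genes, n_samp = x.shape
    observed = ~np.isnan(x)
    n_states_per_gene = sum(
        ((x == s) & observed).any(axis=1).astype(int) for s in states
    )
    usable = n_states_per_gene >= 2
    n_skipped = int(n_genes - usable.sum())
    if n_skipped:
        logger.info("induce_network: skipped %d single-state gene(s)", n_skipped)
    usable_idx = np.flatnonzero(usable)
    if usable_idx.size < 2:
        if n_genes < 2 or n_samp < 2:
            raise InputError("need at least 2 genes and 2 samples")
        # all-constant matrix: a valid, empty network
        return ImplicationNetwork(
            node_ids=list(m.gene_ids),
            edges=[],
            params=dict(
                z_preset=z_preset, semantics=semantics, policy=policy,
                min_samples=min_samples, skipped_single_state=n_skipped,
            ),
        )
    if n_samp < 2:
        raise InputError("need at least 2 samples")

    sub = CategorizedMatrix(
        [m.gene_ids[i] for i in usable_idx],
        list(m.sample_ids),
        x[usable_idx],
        arity=m.arity,
        _skip_validation=True,
    )
    templates = default_templates(m.arity, m.arity, semantics)
    tpl_cells = []
    s_index = {s: i for i, s in enumerate(states)}
    for r in templates:
        rows, cols = zip(*sorted(r.error_cells))
        tpl_cells.append((tuple(s_index[s] for s in rows), tuple(s_index[s] for s in cols)))

    ind, valid = _state_indicators(sub)
    ind_list = [ind[s] for s in states]
    g = sub.n_genes
    valid_t = valid.T.copy()
    ind_t = [a.T.copy() for a in ind_list]

    needed_cells = sorted({c for rc, cc in tpl_cells for c in zip(rc, cc)})
    z2 = z_preset * z_preset

    records: list[tuple[int, int, int, float, float, float, int]] = []
    n_templates = len(templates)
    for start in range(0, g, chunk_size):
        stop = min(start + chunk_size, g)
        c = stop - start
        va = valid[start:stop]
        n_mat = va @ valid_t  # retained samples per pair
        row_marg = [ind_list[i][start:stop] @ valid_t for i in range(len(states))]
        col_marg = [va @ ind_t[j] for j in range(len(states))]
        cell_counts = {
            (i, j): ind_list[i][start:stop] @ ind_t[j] for (i, j) in needed_cells
        }
        with np.errstate(divide="ignore", invalid="ignore"):
            n64 = n_mat.astype(np.float64)
            u_all = np.empty((n_templates, c, g))
            k_all = np.empty((n_templates, c, g))
            nabla_all = np.empty((n_templates, c, g))
            sig_all = np.empty((n_templates, c, g), dtype=bool)
            z_all = np.empty((n_templates, c, g))
            base_ok = n64 >= max(min_samples, 1)
            # exclude self-pairs
            cols_idx = np.arange(g)[None, :]
            rows_idx = (np.arange(start, stop))[:, None]
            base_ok &= cols_idx != rows_idx
            for k_t, (rc, cc) in enumerate(tpl_cells):
                u = np.zeros((c, g))
                kk = np.zeros((c, g))
                for i, j in zip(rc, cc):
                    u += row_marg[i].astype(np.float64) * col_marg[j].astype(np.float64)
                    kk += cell_counts[(i, j)].astype(np.float64)
                u /= n64 * n64
                nabla = 1.0 - (kk / n64) / u
                z = (n64 * u - kk) / np.sqrt(n64 * u * (1.0 - u))
                feasible = u >= z2 / (n64 + z2)
                if min_expected_errors is not None:
                    feasible &= n64 * u >= min_expected_errors
                sig = (
                    base_ok
                    & (u > 0)
                    & feasible
                    & (z >= z_preset)
                    & (nabla > 0)
                )
                u_all[k_t], k_all[k_t], nabla_all[k_t] = u, kk, nabla
                z_all[k_t], sig_all[k_t] = z, sig

        if policy == "precision_first":
            best_t = np.full((c, g), -1, dtype=np.int8)
            best_nabla = np.full((c, g), -np.inf)
            best_u = np.full((c, g), -np.inf)
            for k_t in range(n_templates):
                nab, uu, sig = nabla_all[k_t], u_all[k_t], sig_all[k_t]
                improve = sig & (
                    (nab > best_nabla) | ((nab == best_nabla) & (uu > best_u))
                )
                best_t[improve] = k_t
                best_nabla[improve] = nab[improve]
                best_u[improve] = uu[improve]
        elif policy == "strict_dominance":
            with np.errstate(invalid="ignore"):
                finite_nabla = np.where(np.isnan(nabla_all), -np.inf, nabla_all)
                max_nabla = finite_nabla.max(axis=0)
                max_u = u_all.max(axis=0)
            eps = 1e-12
            best_t = np.full((c, g), -1, dtype=np.int8)
            for k_t in reversed(range(n_templates)):  # earlier templates overwrite
                dom = (
                    sig_all[k_t]
                    & (nabla_all[k_t] >= max_nabla - eps)
                    & (u_all[k_t] >= max_u - eps)
                )
                best_t[dom] = k_t
        else:
            raise InputError(f"unknown selection policy {policy!r}")

        sel_r, sel_c = np.nonzero(best_t >= 0)
        if sel_r.size:
            kt = best_t[sel_r, sel_c].astype(int)
            records.extend(
                zip(
                    (sel_r + start).tolist(),
                    sel_c.tolist(),
                    kt.tolist(),
                    u_all[kt, sel_r, sel_c].tolist(),
                    nabla_all[kt, sel_r, sel_c].tolist(),
                    z_all[kt, sel_r, sel_c].tolist(),
                    n_mat[sel_r, sel_c].astype(int).tolist(),
                    k_all[kt, sel_r, sel_c].astype(int).tolist(),
                )
            )

    gene_ids = sub.gene_ids
    seen_sym: set[tuple[str, str, int]] = set()
    rows_out = []
    for src, tgt, kt, u, nab, z, n_pair, kk in records:
        a, b = gene_ids[src], gene_ids[tgt]
        if templates[kt].name in SYMMETRIC_TEMPLATES:
            if a > b:
                a, b = b, a
            key = (a, b, kt)
            if key in seen_sym:
                continue
            seen_sym.add(key)
        rows_out.append((a, b, kt, u, nab, z, n_pair, kk))
    rows_out.sort(key=lambda r: (r[0], r[1], TEMPLATE_ORDER.index(templates[r[2]].name)))

    edges = [
        ImplicationEdge(
            a,
            b,
            templates[kt].name,
            RuleStats(
                scope=u,
                precision=nab,
                error_count=kk,
                z_stat=z,
                scope_feasible=True,
                significant=True,
                n=n_pair,
            ),
        )
        for a, b, kt, u, nab, z, n_pair, kk in rows_out
    ]
    return ImplicationNetwork(
        node_ids=list(m.gene_ids),
        edges=edges,
        params=dict(
            z_preset=z_preset,
            semantics=semantics,
            policy=policy,
            min_samples=min_samples,
            min_expected_errors=min_expected_errors,
            skipped_single_state=n_skipped,
        ),
    )
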