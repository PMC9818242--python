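"""Readers and writers for the plain-text formats the toolkit touches.

Matrices are genes × samples everywhere: TSV/CSV with the gene id in the
first column and a header row of sample ids ("NA" or empty = missing).
Single-cell counts may instead arrive as a MatrixMarket coordinate triplet
(matrix + features + barcodes, features as rows).  Gene-set collections use
GMT (set name, description, gene ids, tab-separated).  Networks round-trip
through an edge-list TSV with the schema
``source  target  rule  scope  precision  z  n`` (floats at 6 significant
digits, rows sorted by source/target/rule).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from .errors import FormatError, IdentifierError
from .implication import (
    TEMPLATE_ORDER,
    ImplicationEdge,
    ImplicationNetwork,
    RuleStats,
)
from .matrix import CategorizedMatrix, ExpressionMatrix
from .validate import GeneSetCollection

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_categorized_table",
    "write_categorized_table",
    "read_mtx_triplet",
    "read_gmt",
    "read_network",
    "write_network",
    "read_gene_list",
]

_NETWORK_COLUMNS = ("source", "target", "rule", "scope", "precision", "z", "n")


def _read_table(path, dialect: str) -> pd.DataFrame:
    if dialect not in ("tsv", "csv"):
        raise FormatError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    try:
        frame = pd.read_csv(
            path, sep=sep, index_col=0, na_values=["NA"], keep_default_na=False
        )
    except ValueError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise IdentifierError(f"duplicate gene ids in {path}: {dupes[:5]}")
    non_numeric = frame.columns[
        [not np.issubdtype(dt, np.number) for dt in frame.dtypes]
    ].tolist()
    if non_numeric:
        raise FormatError(f"non-numeric cells in column(s) {non_numeric[:5]} of {path}")
    return frame


def read_expression_table(
    path, dialect: str = "tsv", omics_kind: str = "generic"
) -> ExpressionMatrix:
    """Read a genes × samples matrix (first column gene ids, header sample ids)."""
    return ExpressionMatrix.from_frame(_read_table(path, dialect), omics_kind)


def write_expression_table(expr: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    expr.to_frame().to_csv(path, sep=sep, na_rep="NA")


def read_categorized_table(path, dialect: str = "tsv", arity: int = 3) -> CategorizedMatrix:
    """Read an integer-state matrix written by :func:`write_categorized_table`."""
    frame = _read_table(path, dialect)
    return CategorizedMatrix(
        gene_ids=list(map(str, frame.index)),
        sample_ids=list(map(str, frame.columns)),
        states=frame.to_numpy(dtype=float),
        arity=arity,
        provenance=f"read from {path}",
    )


def write_categorized_table(m: CategorizedMatrix, path, dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    frame = m.to_frame()
    # integer states, NA for missing
    out = frame.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep=sep)


def read_mtx_triplet(matrix_path, features_path, barcodes_path) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate triplet as a genes × cells count matrix."""
    try:
        mat = mmread(str(matrix_path))
    except Exception as exc:
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    features = read_gene_list(features_path)
    barcodes = read_gene_list(barcodes_path)
    if dense.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix is {dense.shape[0]}x{dense.shape[1]} but {len(features)} "
            f"features and {len(barcodes)} barcodes were given"
        )
    if (dense < 0).any():
        raise FormatError("negative entries in count matrix")
    return ExpressionMatrix(
        gene_ids=features, sample_ids=barcodes, values=dense, omics_kind="sc_counts"
    )


def read_gene_list(path) -> list[str]:
    """One identifier per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path, collection_name: str | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file (set name, description, gene ids per line)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(
        name=collection_name or Path(str(path)).stem, sets=sets
    )


def write_network(net: ImplicationNetwork, path, comments: Sequence[str] = ()) -> None:
    """Write an edge-list TSV (6 significant digits, deterministic row order)."""
    frame = net.to_frame()
    order = frame["rule"].map(
        {name: i for i, name in enumerate(TEMPLATE_ORDER)}
    ).fillna(len(TEMPLATE_ORDER))
    frame = frame.assign(_o=order).sort_values(["source", "target", "_o"]).drop(columns="_o")
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(_NETWORK_COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.source}\t{row.target}\t{row.rule}\t"
                f"{row.scope:.6g}\t{row.precision:.6g}\t{row.z:.6g}\t{row.n}\n"
            )


def read_network(path) -> ImplicationNetwork:
    """Read an edge-list TSV written by :func:`write_network`."""
    edges: list[ImplicationEdge] = []
    nodes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty network file")
    header = tuple(lines[0].split("\t"))
    if header != _NETWORK_COLUMNS:
        raise FormatError(f"{path}: unexpected header {header}")
    known_rules = set(TEMPLATE_ORDER) | {"pcc", "mi", "sahoo"}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_NETWORK_COLUMNS):
            raise FormatError(f"{path}:{lineno}: expected {len(_NETWORK_COLUMNS)} fields")
        src, tgt, rule = fields[0], fields[1], fields[2]
        if rule not in known_rules:
            raise FormatError(f"{path}:{lineno}: unknown rule {rule!r}")
        try:
            scope, precision, z = (float(x) for x in fields[3:6])
            n = int(fields[6])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed number: {exc}") from exc
        for g in (src, tgt):
            if g not in seen:
                seen.add(g)
                nodes.append(g)
        edges.append(
            ImplicationEdge(
                src,
                tgt,
                rule,
                RuleStats(
                    scope=scope,
                    precision=precision,
                    error_count=-1,  # not serialized
                    z_stat=z,
                    scope_feasible=True,
                    significant=True,
                    n=n,
                ),
            )
        )
    return ImplicationNetwork(node_ids=nodes, edges=edges, params={"source": str(path)})
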