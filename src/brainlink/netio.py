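"""Typed network and feature-matrix containers with TSV/CSV/MatrixMarket I/O.

Eleven network kinds are supported, mirroring the data layers the framework
integrates: gene–TF regulation (G-T), TF–TF similarity (T-T), TF–region
activity (T-R), gene–gene co-regulation (G-G), gene–region expression (G-R),
region–region connectivity (R-R), parcel–region membership (P-R),
parcel–parcel connectivity (P-P), gene–parcel expression (G-P),
disease–disease similarity (D-D) and gene–disease associations (G-D).

Unipartite kinds (T-T, G-G, R-R, P-P, D-D) are stored symmetrically: the
mirrored entry of every edge is always present.  Edge lists are tab-separated
with an optional weight column (default 1.0) and ``#``-prefixed comment
lines.  Vocabularies are the lexicographically sorted union of identifiers
seen, giving a deterministic matrix layout across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

NETWORK_KINDS = (
    "G-T", "T-T", "T-R", "G-G", "G-R", "R-R",
    "P-R", "P-P", "G-P", "D-D", "G-D",
)
UNIPARTITE_KINDS = frozenset({"T-T", "G-G", "R-R", "P-P", "D-D"})
BINARY_KINDS = frozenset({"P-R", "G-D"})


class NetworkError(ValueError):
    """Raised on malformed edge lists or invariant violations."""


@dataclass
class Network:
    """A typed weighted network with ordered node vocabularies.

    ``edges`` maps (row_id, col_id) -> weight; unipartite kinds hold both
    orientations of every edge.
    """

    kind: str
    row_nodes: list[str]
    col_nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def unipartite(self) -> bool:
        return self.kind in UNIPARTITE_KINDS

    def validate(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise NetworkError(f"unknown network kind {self.kind!r}")
        rows, cols = set(self.row_nodes), set(self.col_nodes)
        if len(rows) != len(self.row_nodes) or len(cols) != len(self.col_nodes):
            raise NetworkError("duplicate identifiers in vocabulary")
        if self.unipartite and self.row_nodes != self.col_nodes:
            raise NetworkError(f"{self.kind} is unipartite; vocabularies must match")
        for (u, v), w in self.edges.items():
            if u not in rows or v not in cols:
                raise NetworkError(f"edge endpoint ({u!r},{v!r}) not in vocabulary")
            if not math.isfinite(w):
                raise NetworkError(f"non-finite weight on edge ({u!r},{v!r})")
            if self.kind in BINARY_KINDS and w not in (0.0, 1.0):
                raise NetworkError(
                    f"{self.kind} weights must be 0/1, got {w} on ({u!r},{v!r})"
                )
            if self.unipartite and self.edges.get((v, u)) != w:
                raise NetworkError(
                    f"unipartite {self.kind} not symmetric at ({u!r},{v!r})"
                )

    def n_edges(self, undirected: bool = False) -> int:
        """Stored entry count; ``undirected=True`` halves off-diagonal
        unipartite entries (pair-count convention)."""
        if not (undirected and self.unipartite):
            return len(self.edges)
        diag = sum(1 for (u, v) in self.edges if u == v)
        return diag + (len(self.edges) - diag) // 2


def _symmetrize(edges: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    out = dict(edges)
    for (u, v), w in edges.items():
        prev = out.get((v, u))
        if prev is not None and prev != w:
            raise NetworkError(
                f"conflicting weights for symmetric pair ({u!r},{v!r}): {prev} vs {w}"
            )
        out[(v, u)] = w
    return out


def build_network(
    kind: str,
    edges: dict[tuple[str, str], float],
    row_nodes: list[str] | None = None,
    col_nodes: list[str] | None = None,
) -> Network:
    """Construct a validated Network, symmetrizing unipartite kinds and
    deriving sorted vocabularies when none are supplied."""
    if kind in UNIPARTITE_KINDS:
        edges = _symmetrize(edges)
        if row_nodes is None:
            ids = sorted({u for u, _ in edges} | {v for _, v in edges})
            row_nodes = ids
        col_nodes = row_nodes
    else:
        if row_nodes is None:
            row_nodes = sorted({u for u, _ in edges})
        if col_nodes is None:
            col_nodes = sorted({v for _, v in edges})
    return Network(kind=kind, row_nodes=row_nodes, col_nodes=col_nodes, edges=edges)


def read_edge_list(path, kind: str, weighted: bool = True) -> Network:
    """Parse a tab-separated edge list into a validated :class:`Network`.

    Lines starting with ``#`` are comments.  The weight column is optional
    (defaults to 1.0).  Duplicate pairs with identical weights deduplicate
    silently; conflicting weights raise.
    """
    edges: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) == 2:
                u, v, w = parts[0], parts[1], 1.0
            elif len(parts) == 3 and weighted:
                u, v = parts[0], parts[1]
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise NetworkError(
                        f"{path}:{lineno}: bad weight {parts[2]!r}"
                    ) from exc
            else:
                raise NetworkError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            if not math.isfinite(w):
                raise NetworkError(f"{path}:{lineno}: non-finite weight {w}")
            key = (u, v)
            if key in edges and edges[key] != w:
                raise NetworkError(
                    f"{path}:{lineno}: duplicate edge ({u},{v}) with "
                    f"conflicting weights {edges[key]} vs {w}"
                )
            edges[key] = w
    return build_network(kind, edges)


def write_edge_list(network: Network, path) -> None:
    """Write a network as a sorted TSV edge list (one orientation per
    unipartite pair); read_edge_list inverts this exactly."""
    lines = []
    for (u, v), w in sorted(network.edges.items()):
        if network.unipartite and u > v:
            continue  # mirror is reconstructed on read
        lines.append(f"{u}\t{v}\t{w:.17g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def to_sparse_matrix(network: Network):
    """Return (csr_matrix, row_index, col_index) with vocabulary order."""
    row_index = {nid: i for i, nid in enumerate(network.row_nodes)}
    col_index = {nid: j for j, nid in enumerate(network.col_nodes)}
    n, m = len(network.row_nodes), len(network.col_nodes)
    if network.edges:
        rows, cols, vals = zip(
            *((row_index[u], col_index[v], w) for (u, v), w in network.edges.items())
        )
        mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, m), dtype=np.float64)
    else:
        mat = sp.csr_matrix((n, m), dtype=np.float64)
    return mat, row_index, col_index


def from_sparse_matrix(kind, mat, row_nodes, col_nodes) -> Network:
    """Inverse of :func:`to_sparse_matrix`."""
    coo = sp.coo_matrix(mat)
    edges = {
        (row_nodes[i], col_nodes[j]): float(w)
        for i, j, w in zip(coo.row, coo.col, coo.data)
        if w != 0.0
    }
    return Network(kind=kind, row_nodes=list(row_nodes),
                   col_nodes=list(col_nodes), edges=edges)


def network_summary(network: Network, undirected: bool = False) -> tuple[int, int, int, float]:
    """(n_row_nodes, n_col_nodes, n_edges, density).

    By default ``n_edges`` counts stored entries (mirrored unipartite entries
    count twice); ``undirected=True`` switches to the pair-count convention.
    Density is n_edges over the number of cells the convention addresses.
    """
    n, m = len(network.row_nodes), len(network.col_nodes)
    e = network.n_edges(undirected=undirected)
    if n == 0 or m == 0:
        return (n, m, 0, 0.0)
    cells = n * m
    if undirected and network.unipartite:
        cells = n * (n + 1) // 2
    return (n, m, e, e / cells)


@dataclass
class FeatureMatrix:
    """Dense node-by-feature matrix with ordered identifiers."""

    node_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.node_ids), len(self.feature_ids)):
            raise NetworkError(
                f"feature matrix shape {self.values.shape} inconsistent with "
                f"{len(self.node_ids)} nodes x {len(self.feature_ids)} features"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise NetworkError("duplicate node id in feature matrix")
        if not np.all(np.isfinite(self.values)):
            raise NetworkError("feature matrix contains missing/non-finite values")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a delimited file (CSV or TSV, sniffed from the header) whose first
    column holds node ids and whose header row holds feature ids."""
    sep = "\t" if "\t" in Path(path).read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isnull().values.any():
        raise NetworkError(f"{path}: missing value in feature matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise NetworkError(f"{path}: duplicate node id {dup!r}")
    values = df.to_numpy(dtype=np.float64)
    return FeatureMatrix(
        node_ids=[str(i) for i in df.index],
        feature_ids=[str(c) for c in df.columns],
        values=values,
    )


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    df = pd.DataFrame(fm.values, index=fm.node_ids, columns=fm.feature_ids)
    sep = "\t" if str(path).endswith(".tsv") else ","
    df.to_csv(path, sep=sep)


def export_mtx(network: Network, prefix) -> None:
    """MatrixMarket export with sidecar row/column id files."""
    mat, _, _ = to_sparse_matrix(network)
    prefix = Path(prefix)
    sio.mmwrite(str(prefix) + ".mtx", mat)
    (prefix.parent / (prefix.name + ".rows.txt")).write_text(
        "\n".join(network.row_nodes) + "\n"
    )
    (prefix.parent / (prefix.name + ".cols.txt")).write_text(
        "\n".join(network.col_nodes) + "\n"
    )


def import_mtx(prefix, kind: str) -> Network:
    prefix = Path(prefix)
    mat = sio.mmread(str(prefix) + ".mtx")
    rows = (prefix.parent / (prefix.name + ".rows.txt")).read_text().split()
    cols = (prefix.parent / (prefix.name + ".cols.txt")).read_text().split()
    return from_sparse_matrix(kind, mat, rows, cols)
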