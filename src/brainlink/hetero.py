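"""Block-structured heterogeneous adjacency matrices.

The framework assembles square symmetric adjacencies over several node
classes at once: A_GPR over [genes, parcels, regions], A_GTR over
[genes, TFs, regions], and the combined gene/disease graph A_eBFC-DD over
[genes, diseases].  Only upper-triangle blocks are supplied; mirrors are
generated by transposition so the result is exactly symmetric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io as sio
import scipy.sparse as sp

from .netio import Network, to_sparse_matrix


class AssemblyError(ValueError):
    """Raised on inconsistent blocks or vocabularies."""


@dataclass
class HeteroAdjacency:
    """Square symmetric sparse adjacency over concatenated node classes."""

    block_order: list[str]
    class_sizes: list[int]
    vocabs: dict[str, list[str]]
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        side = sum(self.class_sizes)
        if self.matrix.shape != (side, side):
            raise AssemblyError(
                f"matrix side {self.matrix.shape} != sum of class sizes {side}"
            )
        if (self.matrix != self.matrix.T).nnz != 0:
            raise AssemblyError("heterogeneous adjacency is not symmetric")

    @property
    def side(self) -> int:
        return int(sum(self.class_sizes))

    def offsets(self) -> dict[str, int]:
        off, total = {}, 0
        for cls, n in zip(self.block_order, self.class_sizes):
            off[cls] = total
            total += n
        return off

    def node_index(self, cls: str, node_id: str) -> int:
        if cls not in self.vocabs:
            raise AssemblyError(f"unknown node class {cls!r}")
        return self.offsets()[cls] + self.vocabs[cls].index(node_id)


def _as_csr(mat) -> sp.csr_matrix:
    if sp.issparse(mat):
        return mat.tocsr().astype(np.float64)
    return sp.csr_matrix(np.asarray(mat, dtype=np.float64))


def assemble_hetero(
    blocks: dict[tuple[str, str], object],
    block_order: list[str],
    vocabs: dict[str, list[str]],
) -> HeteroAdjacency:
    """Assemble a symmetric block adjacency from upper-triangle blocks.

    ``blocks`` maps (class_i, class_j) to a matrix; missing off-diagonal
    blocks are treated as all-zero.  Diagonal blocks must be square and
    exactly symmetric.  The (j,i) block is always the transpose of (i,j).
    """
    sizes = [len(vocabs[c]) for c in block_order]
    pos = {c: k for k, c in enumerate(block_order)}
    grid: list[list[object]] = [
        [None for _ in block_order] for _ in block_order
    ]
    for (ci, cj), raw in blocks.items():
        if ci not in pos or cj not in pos:
            raise AssemblyError(f"block ({ci},{cj}) uses unknown class")
        i, j = pos[ci], pos[cj]
        mat = _as_csr(raw)
        if mat.shape != (sizes[i], sizes[j]):
            raise AssemblyError(
                f"block ({ci},{cj}) has shape {mat.shape}, "
                f"expected ({sizes[i]},{sizes[j]})"
            )
        if i == j and (mat != mat.T).nnz != 0:
            raise AssemblyError(f"diagonal block ({ci},{ci}) is not symmetric")
        if i > j:
            raise AssemblyError(
                f"supply only upper-triangle blocks; got ({ci},{cj})"
            )
        grid[i][j] = mat
        if i != j:
            grid[j][i] = mat.T
    for i in range(len(block_order)):
        for j in range(len(block_order)):
            if grid[i][j] is None:
                grid[i][j] = sp.csr_matrix((sizes[i], sizes[j]))
    matrix = sp.bmat(grid, format="csr")
    return HeteroAdjacency(
        block_order=list(block_order),
        class_sizes=sizes,
        vocabs={c: list(vocabs[c]) for c in block_order},
        matrix=matrix,
    )


def block_slice(H: HeteroAdjacency, class_i: str, class_j: str) -> sp.csr_matrix:
    """Extract one block of the assembled adjacency."""
    off = H.offsets()
    for c in (class_i, class_j):
        if c not in off:
            raise AssemblyError(f"unknown node class {c!r}")
    i0 = off[class_i]
    j0 = off[class_j]
    ni = H.class_sizes[H.block_order.index(class_i)]
    nj = H.class_sizes[H.block_order.index(class_j)]
    return H.matrix[i0 : i0 + ni, j0 : j0 + nj].tocsr()


def hetero_from_networks(
    networks: dict[str, Network], block_order: list[str]
) -> HeteroAdjacency:
    """Assemble a heterograph directly from typed networks.

    ``block_order`` uses single-letter class labels (G, P, R, T, D); the
    network kinds supplying each block are looked up by label pair, e.g.
    order [G,P,R] consumes G-G, G-P, G-R, P-P, P-R, R-R when present.
    """
    vocabs: dict[str, list[str]] = {}
    blocks: dict[tuple[str, str], object] = {}
    for i, ci in enumerate(block_order):
        for cj in block_order[i:]:
            kind = f"{ci}-{cj}"
            net = networks.get(kind)
            if net is None:
                continue
            mat, _, _ = to_sparse_matrix(net)
            blocks[(ci, cj)] = mat
            for cls, vocab in ((ci, net.row_nodes), (cj, net.col_nodes)):
                if cls in vocabs:
                    if vocabs[cls] != list(vocab):
                        raise AssemblyError(
                            f"vocabulary mismatch for class {cls!r} "
                            f"while assembling block {kind}"
                        )
                else:
                    vocabs[cls] = list(vocab)
    missing = [c for c in block_order if c not in vocabs]
    if missing:
        raise AssemblyError(f"no network defines vocabulary for classes {missing}")
    return assemble_hetero(blocks, block_order, vocabs)


def build_ebfc_dd_graph(ebfc, gene_ids, M_DD, M_GD) -> HeteroAdjacency:
    """Combine the fused gene network with disease similarity and known
    gene-disease associations into the [G,D] adjacency the GCN consumes.

    ``ebfc`` is a square gene-by-gene matrix over ``gene_ids``; ``M_DD`` and
    ``M_GD`` are Networks (or matrices paired with matching vocabularies via
    Network only).
    """
    ebfc = _as_csr(ebfc)
    if ebfc.shape[0] != ebfc.shape[1] or ebfc.shape[0] != len(gene_ids):
        raise AssemblyError("ebfc matrix does not match gene vocabulary")
    dd_mat, _, _ = to_sparse_matrix(M_DD)
    gd_mat, _, _ = to_sparse_matrix(M_GD)
    if M_GD.row_nodes != list(gene_ids):
        raise AssemblyError("gene vocabulary mismatch between ebfc and G-D network")
    if M_GD.col_nodes != M_DD.row_nodes:
        raise AssemblyError("disease vocabulary mismatch between D-D and G-D")
    return assemble_hetero(
        {("G", "G"): ebfc, ("G", "D"): gd_mat, ("D", "D"): dd_mat},
        ["G", "D"],
        {"G": list(gene_ids), "D": list(M_DD.row_nodes)},
    )


def save_hetero(H: HeteroAdjacency, prefix) -> None:
    """MatrixMarket matrix plus JSON sidecar with block structure."""
    prefix = Path(prefix)
    sio.mmwrite(str(prefix) + ".mtx", H.matrix)
    sidecar = {
        "block_order": H.block_order,
        "class_sizes": H.class_sizes,
        "vocabs": H.vocabs,
    }
    (prefix.parent / (prefix.name + ".json")).write_text(
        json.dumps(sidecar, indent=1)
    )


def load_hetero(prefix) -> HeteroAdjacency:
    prefix = Path(prefix)
    matrix = sp.csr_matrix(sio.mmread(str(prefix) + ".mtx"))
    sidecar = json.loads((prefix.parent / (prefix.name + ".json")).read_text())
    return HeteroAdjacency(
        block_order=sidecar["block_order"],
        class_sizes=sidecar["class_sizes"],
        vocabs=sidecar["vocabs"],
        matrix=matrix,
    )
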