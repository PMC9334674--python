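"""Bipartite drug-miRNA graph model, edge-list I/O and co-HITS projections.

The interaction network is a weighted bipartite graph G = (D, M, E) whose
edges are known drug-miRNA interactions (weight 1 unless the edge list says
otherwise).  The two homogeneous projections W·Wᵀ (drug-drug) and Wᵀ·W
(miRNA-miRNA) follow the co-HITS construction: the similarity of two
same-type nodes is the weighted count of their shared neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

#: node count per side above which projections are computed sparsely
SPARSE_THRESHOLD = 2000


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list files."""


@dataclass
class BipartiteGraph:
    """Weighted bipartite graph over ordered drug and miRNA identifier lists.

    Edges are stored as a mapping ``(drug_index, mirna_index) -> weight`` with
    strictly positive weights; a zero weight means "no edge" and is never
    stored.
    """

    drug_ids: list[str]
    mirna_ids: list[str]
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nd, nm = len(self.drug_ids), len(self.mirna_ids)
        if len(set(self.drug_ids)) != nd or len(set(self.mirna_ids)) != nm:
            raise ValueError("duplicate node identifiers")
        for (i, j), w in self.edges.items():
            if not (0 <= i < nd and 0 <= j < nm):
                raise ValueError(f"edge ({i},{j}) references an undeclared node")
            if not w > 0:
                raise ValueError(f"edge ({i},{j}) has non-positive weight {w}")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None

    def mirna_index(self, mirna_id: str) -> int:
        try:
            return self.mirna_ids.index(mirna_id)
        except ValueError:
            raise KeyError(f"unknown miRNA id {mirna_id!r}") from None

    def total_weight(self) -> float:
        return float(sum(self.edges.values()))

    def drug_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_drugs)
        for (i, _), w in self.edges.items():
            deg[i] += w
        return deg

    def mirna_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_mirnas)
        for (_, j), w in self.edges.items():
            deg[j] += w
        return deg


@dataclass
class HomogeneousWeights:
    """Square symmetric similarity matrix over one side of the bipartite graph.

    ``matrix`` is a Gram matrix (W·Wᵀ or Wᵀ·W); the diagonal holds node
    self-similarities which downstream random walks ignore.
    """

    side: str  # "drug" | "mirna"
    matrix: np.ndarray | sp.spmatrix

    def __post_init__(self) -> None:
        if self.side not in ("drug", "mirna"):
            raise ValueError(f"side must be 'drug' or 'mirna', got {self.side!r}")
        m, n = self.matrix.shape
        if m != n:
            raise ValueError("homogeneous weight matrix must be square")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense())
        return self.matrix


def load_bipartite_edges(path, *, comment: str = "#", sep: str = "\t") -> BipartiteGraph:
    """Read a TSV edge list ``drug_id<TAB>mirna_id[<TAB>weight]``.

    Duplicate (drug, miRNA) rows collapse to a single edge keeping the first
    weight; a missing weight column defaults to 1.  Node order is order of
    first appearance.
    """
    drug_ids: list[str] = []
    mirna_ids: list[str] = []
    d_index: dict[str, int] = {}
    m_index: dict[str, int] = {}
    edges: dict[tuple[int, int], float] = {}

    with open(path) as fh:
        n_rows = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            parts = line.split(sep) if sep in line else line.split()
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise EdgeListError(f"{path}: malformed row at line {lineno}: {line!r}")
            d, m = parts[0].strip(), parts[1].strip()
            if len(parts) >= 3 and parts[2].strip():
                try:
                    w = float(parts[2])
                except ValueError:
                    raise EdgeListError(
                        f"{path}: non-numeric weight at line {lineno}: {parts[2]!r}"
                    ) from None
            else:
                w = 1.0
            if w <= 0:
                raise EdgeListError(f"{path}: non-positive weight at line {lineno}")
            if d not in d_index:
                d_index[d] = len(drug_ids)
                drug_ids.append(d)
            if m not in m_index:
                m_index[m] = len(mirna_ids)
                mirna_ids.append(m)
            key = (d_index[d], m_index[m])
            edges.setdefault(key, w)  # de-duplication: first row wins
            n_rows += 1
    if n_rows == 0:
        raise EdgeListError(f"{path}: empty edge list")
    return BipartiteGraph(drug_ids, mirna_ids, edges)


def weight_matrix(g: BipartiteGraph, *, sparse: bool | None = None):
    """The |D|x|M| weight matrix W with W[i, j] = w_ij (0 for absent edges)."""
    if sparse is None:
        sparse = max(g.n_drugs, g.n_mirnas) > SPARSE_THRESHOLD
    if sparse:
        if not g.edges:
            return sp.csr_matrix((g.n_drugs, g.n_mirnas))
        rows, cols, vals = zip(*((i, j, w) for (i, j), w in g.edges.items()))
        return sp.csr_matrix((vals, (rows, cols)), shape=(g.n_drugs, g.n_mirnas))
    W = np.zeros((g.n_drugs, g.n_mirnas))
    for (i, j), w in g.edges.items():
        W[i, j] = w
    return W


def cohits_projection(g: BipartiteGraph, side: str) -> HomogeneousWeights:
    """co-HITS homogeneous projection: W·Wᵀ (drug side) or Wᵀ·W (miRNA side)."""
    W = weight_matrix(g)
    if side == "drug":
        mat = W @ W.T
    elif side == "mirna":
        mat = W.T @ W
    else:
        raise ValueError(f"side must be 'drug' or 'mirna', got {side!r}")
    return HomogeneousWeights(side=side, matrix=mat)


def restrict_to_training(g: BipartiteGraph, kept_pairs) -> BipartiteGraph:
    """Subgraph keeping only ``kept_pairs`` edges; node sets are unchanged.

    Nodes that lose all edges stay in the graph as isolated (cold-start)
    nodes, mirroring the cross-validation protocol where test-fold edges are
    removed before topological features are computed.
    """
    kept = set(kept_pairs)
    missing = kept - set(g.edges)
    if missing:
        raise KeyError(f"pairs not present in graph: {sorted(missing)[:5]}")
    edges = {p: g.edges[p] for p in kept}
    return BipartiteGraph(list(g.drug_ids), list(g.mirna_ids), edges)


def export_projection_tsv(h: HomogeneousWeights, node_ids: list[str], path) -> None:
    """Write a projection matrix as TSV with node IDs as header row/column."""
    mat = h.dense()
    if len(node_ids) != h.n_nodes:
        raise ValueError("node id list does not match matrix size")
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(node_ids) + "\n")
        for nid, row in zip(node_ids, mat):
            fh.write(nid + "\t" + "\t".join(format(v, "g") for v in row) + "\n")
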