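"""Prior similarity graphs and their Laplacians.

GRACKLE regularizes the two NMF factors with graph Laplacians built from
prior knowledge: a sample-similarity matrix ``SS`` derived from sample
metadata (annotation dot product) and a gene-similarity matrix ``SG``
derived from a gene regulatory network (GRN).  This module constructs,
validates and characterizes those matrices.

Conventions
-----------
* A GRN is a directed, weighted edge list (TF -> target).  PANDA-style
  regulatory-probability networks are binarized by a strict indicator
  ``w > cutoff`` before use.
* Similarity matrices are symmetric and nonnegative.  The combinatorial
  Laplacian is ``L = D - S`` with ``D = diag(row sums of S)``.
* Graph diagnostics (transitivity, degree entropy) operate on the
  binarized off-diagonal structure; self-loops are ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger("grackle")

SYMMETRY_TOL = 1e-10
LAPLACIAN_ROWSUM_TOL = 1e-8


# ---------------------------------------------------------------------------
# Gene regulatory network
# ---------------------------------------------------------------------------

@dataclass
class GeneRegulatoryNetwork:
    """A directed weighted TF -> gene network.

    Parameters
    ----------
    nodes
        All gene/TF identifiers, including isolated ones.
    edges
        ``(source, target, weight)`` triples; weights are finite and >= 0.
    directed
        Whether edge direction is meaningful (TF -> target).
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    directed: bool = True

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers in network")
        seen: set[tuple[str, str]] = set()
        for src, tgt, w in self.edges:
            if src not in node_set or tgt not in node_set:
                raise ValueError(f"edge endpoint not in node list: ({src}, {tgt})")
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"edge ({src}, {tgt}) has invalid weight {w}")
            if (src, tgt) in seen:
                raise ValueError(f"duplicate edge ({src}, {tgt})")
            seen.add((src, tgt))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def is_binary(self) -> bool:
        return all(w == 1.0 for _, _, w in self.edges)

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


def threshold_grn(grn: GeneRegulatoryNetwork, cutoff: float = 1.0) -> GeneRegulatoryNetwork:
    """Binarize a weighted GRN with the strict indicator ``w > cutoff``.

    Edges with weight strictly above ``cutoff`` are kept with weight 1;
    all others are dropped.  The node set is preserved.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    kept = [(s, t, 1.0) for s, t, w in grn.edges if w > cutoff]
    if not kept:
        warnings.warn(
            f"thresholding at cutoff={cutoff} removed every edge", stacklevel=2
        )
        raise ValueError(f"no edges remain after thresholding at cutoff={cutoff}")
    return GeneRegulatoryNetwork(nodes=list(grn.nodes), edges=kept, directed=grn.directed)


# ---------------------------------------------------------------------------
# Similarity graphs
# ---------------------------------------------------------------------------

@dataclass
class SimilarityGraph:
    """A symmetric nonnegative similarity matrix with its Laplacian pieces.

    ``degree`` is the vector of row sums (the diagonal of ``D``) and
    ``laplacian`` is ``D - S``.  The role records whether the entities
    indexed are samples (``SS``) or genes (``SG``).
    """

    matrix: np.ndarray
    ids: list[str]
    role: str  # "sample" | "gene"
    degree: np.ndarray = field(init=False)
    laplacian: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.matrix, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {S.shape}")
        if len(self.ids) != S.shape[0]:
            raise ValueError("id list length does not match matrix size")
        if self.role not in ("sample", "gene"):
            raise ValueError(f"role must be 'sample' or 'gene', got {self.role!r}")
        if S.size and S.min() < 0:
            raise ValueError("similarity matrix has negative entries")
        if not np.allclose(S, S.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValueError("similarity matrix is not symmetric within 1e-10")
        self.matrix = S
        self.degree = S.sum(axis=1)
        self.laplacian = np.diag(self.degree) - S

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def graph_laplacian(S: SimilarityGraph | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(L, D)`` for a symmetric nonnegative similarity matrix.

    ``D = diag(row sums of S)``, ``L = D - S``; rows of ``L`` sum to zero.
    """
    M = S.matrix if isinstance(S, SimilarityGraph) else np.asarray(S, dtype=float)
    if not np.allclose(M, M.T, atol=SYMMETRY_TOL, rtol=0):
        raise ValueError("matrix is not symmetric within tolerance")
    if M.size and M.min() < 0:
        raise ValueError("matrix has negative entries")
    D = np.diag(M.sum(axis=1))
    L = D - M
    assert np.abs(L.sum(axis=1)).max() <= LAPLACIAN_ROWSUM_TOL * max(1.0, np.abs(M).max() * M.shape[0])
    return L, D


def gene_similarity_from_grn(
    grn: GeneRegulatoryNetwork, gene_ids: list[str]
) -> SimilarityGraph:
    """Build the gene-similarity matrix ``SG`` from a binary GRN.

    ``SG[i, j] = 1`` if an edge exists in either direction between genes
    ``i`` and ``j`` (logical-OR symmetrization of the directed network);
    the diagonal is zero.  Gene ids absent from the network become
    isolated nodes (all-zero rows), logged.
    """
    if not grn.is_binary():
        raise ValueError("GRN must be binarized (threshold_grn) before building SG")
    index = {g: i for i, g in enumerate(gene_ids)}
    if len(index) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    missing = [g for g in gene_ids if g not in set(grn.nodes)]
    if missing:
        logger.info(
            "gene_similarity_from_grn: %d of %d gene ids absent from network "
            "(treated as isolated)", len(missing), len(gene_ids),
        )
    n = len(gene_ids)
    S = np.zeros((n, n))
    for src, tgt, _ in grn.edges:
        i, j = index.get(src), index.get(tgt)
        if i is None or j is None or i == j:
            continue
        S[i, j] = 1.0
        S[j, i] = 1.0
    return SimilarityGraph(matrix=S, ids=list(gene_ids), role="gene")


def sample_similarity_from_metadata(
    metadata: np.ndarray,
    sample_ids: list[str] | None = None,
    zero_diagonal: bool = False,
) -> SimilarityGraph:
    """Build the sample-similarity matrix ``SS = M M^T`` from metadata.

    For one-hot (single-label) metadata this gives ``SS[i, j] = 1`` iff
    samples i and j share the label (diagonal 1).  Multi-label metadata
    yields integer counts of shared annotations.  The self-similarity
    diagonal is kept by default (it enters ``D_S`` and hence the literal
    ``L = D - S``); ``zero_diagonal`` drops it.
    """
    M = np.asarray(metadata, dtype=float)
    if M.ndim != 2:
        raise ValueError("metadata must be a 2-D samples x annotations matrix")
    if M.size and M.min() < 0:
        raise ValueError(
            "metadata contains negative values; SS = M M^T would not support "
            "nonnegative multiplicative updates"
        )
    SS = M @ M.T
    SS = (SS + SS.T) / 2.0  # exact symmetry against fp round-off
    if zero_diagonal:
        np.fill_diagonal(SS, 0.0)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(M.shape[0])]
    return SimilarityGraph(matrix=SS, ids=list(ids), role="sample")


def knn_affinity(
    Y: np.ndarray,
    n_neighbors: int = 5,
    axis: str = "gene",
    ids: list[str] | None = None,
) -> SimilarityGraph:
    """Binary k-nearest-neighbor affinity graph on samples or genes.

    Entities are rows (``axis='sample'``) or columns (``axis='gene'``) of
    the expression matrix; distances are Euclidean.  The directed kNN
    relation is symmetrized by logical OR.  Ties in distance are broken
    by lower index (argsort stability), so the graph is deterministic.
    """
    Y = np.asarray(Y, dtype=float)
    if axis not in ("sample", "gene"):
        raise ValueError("axis must be 'sample' or 'gene'")
    X = Y if axis == "sample" else Y.T
    n = X.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < number of entities {n}")
    # pairwise squared distances; self excluded via +inf on the diagonal
    sq = (X ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")  # stable => lower-index tie-break
    S = np.zeros((n, n))
    rows = np.repeat(np.arange(n), n_neighbors)
    cols = order[:, :n_neighbors].ravel()
    S[rows, cols] = 1.0
    S = np.maximum(S, S.T)  # OR-symmetrization
    role = axis
    if ids is None:
        ids = [str(i) for i in range(n)]
    return SimilarityGraph(matrix=S, ids=list(ids), role=role)


# ---------------------------------------------------------------------------
# Graph diagnostics
# ---------------------------------------------------------------------------

def graph_metrics(S: SimilarityGraph | np.ndarray) -> dict:
    """Transitivity and degree entropy of the binarized similarity graph.

    Transitivity is the global clustering coefficient,
    ``3 x triangles / connected triplets``.  Degree entropy is the Shannon
    entropy (natural log) of the normalized degree distribution — the
    degree sequence divided by its sum.  Nonzero off-diagonal entries
    count as edges; self-loops are ignored.  A graph with no connected
    triplets reports transitivity 0 with ``no_triplets=True``.
    """
    M = S.matrix if isinstance(S, SimilarityGraph) else np.asarray(S, dtype=float)
    A = (M != 0).astype(float)
    np.fill_diagonal(A, 0.0)
    A = np.maximum(A, A.T)
    deg = A.sum(axis=1)
    # connected triplets centered at each node: deg * (deg - 1); closed ones:
    # each triangle contributes 3 closed triplets = trace(A^3) / 2 per node pair
    triplets = float((deg * (deg - 1)).sum())
    closed = float(np.trace(A @ A @ A))  # = 6 * n_triangles = 2 * closed triplets
    no_triplets = triplets == 0
    transitivity = 0.0 if no_triplets else closed / triplets
    total_deg = deg.sum()
    if total_deg == 0:
        entropy = 0.0
    else:
        p = deg[deg > 0] / total_deg
        entropy = float(-(p * np.log(p)).sum())
    return {
        "transitivity": transitivity,
        "degree_entropy": entropy,
        "no_triplets": no_triplets,
    }
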