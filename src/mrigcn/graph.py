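"""Dataset-level similarity-graph construction.

Nodes are whole images (one embedding row each). Edges come from three
sources: self-loops on every node, thresholded cosine-KNN links, and
optional sampled same-class links among training nodes. The adjacency
is binary and symmetrically normalized, D^(-1/2) A D^(-1/2). Test nodes
attach to training nodes by feature similarity only; their labels are
never read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from mrigcn.embeddings import EmbeddingTable

logger = logging.getLogger(__name__)


class SimilarityError(ValueError):
    """Zero-norm vector makes cosine similarity undefined."""


class DegreeError(ValueError):
    """Adjacency row with zero degree cannot be normalized."""


@dataclass
class GraphConfig:
    k: int = 10
    tau: float = 0.75
    class_edges_per_node: int = 3
    use_class_edges: bool = True
    use_knn: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not -1.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [-1, 1]")
        if self.class_edges_per_node < 0:
            raise ValueError("class_edges_per_node must be >= 0")


class EdgeSet:
    """Set of directed (i, j) pairs with per-edge provenance.

    Finalized sets are symmetric and contain all self-loops; provenance
    is one of ``self_loop``, ``knn``, ``class_aware``.
    """

    def __init__(self) -> None:
        self.pairs: set[tuple[int, int]] = set()
        self.provenance: dict[tuple[int, int], str] = {}

    def add(self, i: int, j: int, provenance: str) -> None:
        pair = (int(i), int(j))
        if pair not in self.pairs:
            self.pairs.add(pair)
            self.provenance[pair] = provenance

    def update(self, other: "EdgeSet") -> "EdgeSet":
        for pair in other.pairs:
            self.add(*pair, other.provenance[pair])
        return self

    def symmetrize(self) -> "EdgeSet":
        for i, j in list(self.pairs):
            self.add(j, i, self.provenance[(i, j)])
        return self

    def is_symmetric(self) -> bool:
        return all((j, i) in self.pairs for i, j in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in self.pairs

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
        arr = np.array(sorted(self.pairs), dtype=np.intp)
        return arr[:, 0], arr[:, 1]


@dataclass
class GraphDataset:
    """Finalized transductive graph: features, adjacency, masks, labels."""

    X: np.ndarray
    edges: EdgeSet
    A_norm: sp.csr_matrix
    labels: np.ndarray  # -1 where unknown (test nodes)
    train_mask: np.ndarray
    val_mask: np.ndarray
    test_mask: np.ndarray

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for m in (self.train_mask, self.val_mask, self.test_mask):
            if m.shape != (n,):
                raise ValueError("mask shape mismatch")
        overlap = (
            self.train_mask.astype(int) + self.val_mask.astype(int) + self.test_mask.astype(int)
        )
        if overlap.max() > 1:
            raise ValueError("masks must be disjoint")

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise SimilarityError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _cosine_matrix(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    Y = X if Y is None else Y
    norms_x = np.linalg.norm(X, axis=1)
    norms_y = np.linalg.norm(Y, axis=1)
    if np.any(norms_x == 0) or np.any(norms_y == 0):
        raise SimilarityError("cosine similarity undefined for zero-norm vector")
    S = (X / norms_x[:, None]) @ (Y / norms_y[:, None]).T
    return np.clip(S, -1.0, 1.0)


def _top_k_above_tau(sims: np.ndarray, candidates: np.ndarray, k: int, tau: float) -> np.ndarray:
    """Indices of the <= k most similar candidates with sim > tau.

    Ties at the cut are broken toward the lower node index.
    """
    # sort by (-similarity, index): stable two-key lexsort
    order = np.lexsort((candidates, -sims))
    picked = []
    for pos in order:
        if sims[pos] <= tau:
            continue
        picked.append(candidates[pos])
        if len(picked) == k:
            break
    return np.asarray(picked, dtype=np.intp)


def build_knn_edges(
    X: np.ndarray,
    cfg: GraphConfig,
    candidate_mask: np.ndarray | None = None,
) -> EdgeSet:
    """Thresholded cosine-KNN edges among candidate nodes, symmetrized.

    Each node links to at most ``k`` candidates whose similarity strictly
    exceeds ``tau``. Self-pairs are excluded here; self-loops are added
    separately.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if candidate_mask is None:
        candidate_mask = np.ones(n, dtype=bool)
    cand = np.flatnonzero(candidate_mask)
    if cfg.k >= len(cand):
        logger.warning("k=%d >= %d candidates; capping", cfg.k, len(cand))
    S = _cosine_matrix(X[cand], X)  # candidates x all
    edges = EdgeSet()
    for i in range(n):
        others = cand[cand != i]
        if len(others) == 0:
            continue
        sims = S[np.searchsorted(cand, others), i]
        for j in _top_k_above_tau(sims, others, cfg.k, cfg.tau):
            edges.add(i, j, "knn")
    return edges.symmetrize()


def add_self_loops(edges: EdgeSet, n: int) -> EdgeSet:
    """Ensure (i, i) is present for every node; idempotent."""
    for i in range(n):
        edges.add(i, i, "self_loop")
    return edges


def add_class_edges(
    labels: np.ndarray,
    train_mask: np.ndarray,
    cfg: GraphConfig,
) -> EdgeSet:
    """Sampled same-class links among training nodes only.

    Each training node gets up to ``class_edges_per_node`` seeded uniform
    draws of distinct same-class training peers; the result is
    symmetrized. Single-member classes contribute no edges.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = np.asarray(labels)
    train_idx = np.flatnonzero(train_mask)
    edges = EdgeSet()
    if cfg.class_edges_per_node == 0:
        return edges
    for c in np.unique(labels[train_idx]):
        members = train_idx[labels[train_idx] == c]
        if len(members) < 2:
            logger.warning("class %s has a single training member; no class edges", c)
            continue
        for i in members:
            peers = members[members != i]
            take = min(cfg.class_edges_per_node, len(peers))
            for j in rng.choice(peers, size=take, replace=False):
                edges.add(i, j, "class_aware")
    return edges.symmetrize()


def normalize_adjacency(edges: EdgeSet, n: int) -> sp.csr_matrix:
    """Symmetric normalization D^(-1/2) A D^(-1/2) of the binary adjacency."""
    rows, cols = edges.to_arrays()
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise DegreeError("zero-degree node; add self-loops before normalizing")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return (D @ A @ D).tocsr()


def build_graph(
    X: np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    val_mask: np.ndarray,
    test_mask: np.ndarray,
    cfg: GraphConfig,
) -> GraphDataset:
    """Assemble the full transductive graph over one feature matrix.

    KNN edges are built among the labeled (train + val) nodes; each test
    node attaches only to labeled nodes by similarity (with a top-1
    fallback if nothing clears ``tau``); class-aware edges touch training
    nodes only. Test labels are masked to -1 and never read.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    labeled_mask = train_mask | val_mask
    if not labeled_mask.any():
        raise ValueError("no labeled nodes to build the graph from")
    edges = EdgeSet()
    labeled_idx = np.flatnonzero(labeled_mask)

    # labeled-labeled KNN
    if cfg.use_knn:
        S_ll = _cosine_matrix(X[labeled_idx])
        for a, i in enumerate(labeled_idx):
            others = np.delete(np.arange(len(labeled_idx)), a)
            picked = _top_k_above_tau(S_ll[a, others], others, cfg.k, cfg.tau)
            for b in picked:
                edges.add(i, labeled_idx[b], "knn")
        edges.symmetrize()

    # test nodes attach to labeled nodes only
    test_idx = np.flatnonzero(test_mask)
    if cfg.use_knn and len(test_idx):
        S_tl = _cosine_matrix(X[test_idx], X[labeled_idx])
        for a, i in enumerate(test_idx):
            cand = np.arange(len(labeled_idx))
            picked = _top_k_above_tau(S_tl[a], cand, cfg.k, cfg.tau)
            if len(picked) == 0:
                # isolated test node: fall back to its single best neighbor
                best = cand[np.lexsort((cand, -S_tl[a]))][0]
                picked = np.array([best], dtype=np.intp)
                logger.info("test node %d below tau; fallback to top-1 neighbor", i)
            for b in picked:
                edges.add(i, labeled_idx[b], "knn")
                edges.add(labeled_idx[b], i, "knn")

    if cfg.use_class_edges and cfg.class_edges_per_node > 0:
        edges.update(add_class_edges(labels, train_mask, cfg))

    add_self_loops(edges, n)
    A_norm = normalize_adjacency(edges, n)

    masked_labels = np.asarray(labels, dtype=np.int64).copy()
    masked_labels[test_mask] = -1
    return GraphDataset(
        X=X,
        edges=edges,
        A_norm=A_norm,
        labels=masked_labels,
        train_mask=np.asarray(train_mask, bool),
        val_mask=np.asarray(val_mask, bool),
        test_mask=np.asarray(test_mask, bool),
    )


def attach_test_nodes(
    train_table: EmbeddingTable,
    test_table: EmbeddingTable,
    cfg: GraphConfig,
    val_fraction: float = 0.0,
    seed: int | None = None,
) -> GraphDataset:
    """Combine a labeled training table and an unlabeled test table.

    Test rows are appended after training rows; their labels (if any)
    are discarded before graph assembly. ``val_fraction`` optionally
    carves a stratified validation subset out of the training rows.
    """
    if train_table.labels is None:
        raise ValueError("training table must carry labels")
    if train_table.n == 0:
        raise ValueError("empty training table")
    n_train, n_test = train_table.n, test_table.n
    X = np.vstack([train_table.vectors, test_table.vectors])
    labels = np.concatenate(
        [train_table.labels, np.full(n_test, -1, dtype=np.int64)]
    )
    n = n_train + n_test
    train_mask = np.zeros(n, bool)
    train_mask[:n_train] = True
    val_mask = np.zeros(n, bool)
    if val_fraction > 0:
        from sklearn.model_selection import train_test_split

        tr, va = train_test_split(
            np.arange(n_train),
            test_size=val_fraction,
            stratify=train_table.labels,
            random_state=cfg.seed if seed is None else seed,
        )
        train_mask[:] = False
        train_mask[tr] = True
        val_mask[va] = True
    test_mask = np.zeros(n, bool)
    test_mask[n_train:] = True
    return build_graph(X, labels, train_mask, val_mask, test_mask, cfg)


def export_edges(edges: EdgeSet, path) -> None:
    """Write the edge list as TSV (src, dst, provenance), 0-based."""
    import csv

    with open(path, "w", newline="") as f:
        w = csv.writer(f, delimiter="\t")
        w.writerow(["src", "dst", "provenance"])
        for i, j in sorted(edges.pairs):
            w.writerow([i, j, edges.provenance[(i, j)]])
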