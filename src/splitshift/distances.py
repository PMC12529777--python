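"""Model-agnostic distribution-shift quantification.

Two complementary set distances between an OOD test set and a training set:

* a Sheridan-style k-nearest-neighbor distance — for each OOD molecule, the
  mean Tanimoto distance (1 − similarity on ECFP4 fingerprints) to its k
  closest training molecules;
* the Tree Mover Distance (TMD) — a hierarchical optimal-transport metric
  between node-attributed graphs that compares the multisets of depth-L
  message-passing computation trees, padding unequal multisets with blank
  (zero-feature) trees.

The median of the per-molecule k-NN values is the hardness score of a split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .chem import (
    MolecularGraph,
    MoleculeRecord,
    ecfp_matrix,
    tanimoto_matrix,
    to_graph,
)

__all__ = [
    "ShiftProfile",
    "TMDParams",
    "knn_set_distance",
    "tree_mover_distance",
    "hardness_score",
]


@dataclass(frozen=True)
class ShiftProfile:
    """Per-OOD-molecule mean distance to the k nearest training molecules."""

    per_molecule: tuple[tuple[str, float], ...]
    k: int
    metric_name: str
    summary: dict

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.per_molecule])


@dataclass
class TMDParams:
    """Tree Mover Distance hyperparameters.

    ``depth`` is the computation-tree depth L (1 compares bare node
    features); ``level_weights`` scales the child-transport term at each
    depth, a scalar broadcasting to all levels. Feature differences use the
    L1 norm.
    """

    depth: int = 3
    level_weights: "float | Sequence[float]" = 1.0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        ws = self.resolved_weights()
        if any(w <= 0 for w in ws):
            raise ValueError("level weights must be positive")

    def resolved_weights(self) -> list[float]:
        """One weight per tree depth 2..L (combining children into parents)."""
        n = max(self.depth - 1, 0)
        if np.isscalar(self.level_weights):
            return [float(self.level_weights)] * n
        ws = [float(w) for w in self.level_weights]  # type: ignore[union-attr]
        if len(ws) != n:
            raise ValueError(f"need {n} level weights for depth {self.depth}")
        return ws


# ---------------------------------------------------------------------------
# k-NN set distance


def knn_set_distance(
    ood_items: Sequence,
    train_items: Sequence,
    k: int = 5,
    pairwise_metric: "str | Callable" = "tanimoto_ecfp4",
    tmd_params: TMDParams | None = None,
) -> ShiftProfile:
    """Mean distance from each OOD item to its k nearest training items.

    ``pairwise_metric`` is ``"tanimoto_ecfp4"`` (items are
    :class:`MoleculeRecord`; vectorized), ``"tmd"`` (records or
    :class:`MolecularGraph`), or any callable ``(a, b) -> float``. ``k`` is
    clipped to the training-set size with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ood_items) == 0 or len(train_items) == 0:
        raise ValueError("OOD and train sets must be non-empty")
    if k > len(train_items):
        warnings.warn(
            f"k={k} exceeds training size {len(train_items)}; clipping"
        )
        k = len(train_items)

    if pairwise_metric == "tanimoto_ecfp4":
        D = 1.0 - tanimoto_matrix(
            ecfp_matrix(list(ood_items)), ecfp_matrix(list(train_items))
        )
        metric_name = "tanimoto_ecfp4"
    else:
        if pairwise_metric == "tmd":
            params = tmd_params or TMDParams()
            graphs_o = [
                g if isinstance(g, MolecularGraph) else to_graph(g)
                for g in ood_items
            ]
            graphs_t = [
                g if isinstance(g, MolecularGraph) else to_graph(g)
                for g in train_items
            ]
            fn = lambda a, b: tree_mover_distance(a, b, params)
            pairs_o, pairs_t = graphs_o, graphs_t
            metric_name = "tmd"
        else:
            fn = pairwise_metric
            pairs_o, pairs_t = list(ood_items), list(train_items)
            metric_name = getattr(pairwise_metric, "__name__", "custom")
        D = np.array([[fn(a, b) for b in pairs_t] for a in pairs_o])

    nearest = np.sort(D, axis=1)[:, :k]
    means = nearest.mean(axis=1)
    ids = [
        item.id if isinstance(item, MoleculeRecord) else str(i)
        for i, item in enumerate(ood_items)
    ]
    per_molecule = tuple(zip(ids, means.tolist()))
    q1, med, q3 = np.percentile(means, [25, 50, 75])
    return ShiftProfile(
        per_molecule=per_molecule,
        k=k,
        metric_name=metric_name,
        summary={"median": float(med), "q1": float(q1), "q3": float(q3)},
    )


def hardness_score(profile: ShiftProfile) -> float:
    """Median per-molecule distance — the scalar hardness of a split."""
    if not profile.per_molecule:
        raise ValueError("empty shift profile")
    return float(np.median(profile.values()))


# ---------------------------------------------------------------------------
# Tree Mover Distance


def _context_tables(
    g: MolecularGraph,
) -> tuple[list[list[int]], np.ndarray, np.ndarray]:
    """Unroll a graph into directed-edge contexts.

    Returns (children, ctx_features, root_children_idx) where ``children[c]``
    lists the contexts reachable from context c's head node, ``ctx_features``
    holds the context feature vectors (node features, with the incoming
    bond's features appended when the graph carries them), and contexts are
    indexed 0..2m−1 (directed edges). Root nodes' children are given by
    ``children_of_node``.
    """
    n = g.n_nodes
    has_edge_feats = g.edge_features is not None
    node_dim = g.node_features.shape[1]
    edge_dim = g.edge_features.shape[1] if has_edge_feats else 0
    # directed edge contexts: context id for (p -> v)
    ctx_id: dict[tuple[int, int], int] = {}
    feats: list[np.ndarray] = []
    for e, (i, j) in enumerate(g.edge_list):
        for p, v in ((int(i), int(j)), (int(j), int(i))):
            ctx_id[(p, v)] = len(feats)
            f = g.node_features[v]
            if has_edge_feats:
                f = np.concatenate([f, g.edge_features[e]])
            feats.append(f)
    ctx_features = (
        np.array(feats) if feats else np.zeros((0, node_dim + edge_dim))
    )
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for i, j in g.edge_list:
        nbrs[int(i)].append(int(j))
        nbrs[int(j)].append(int(i))
    # children of context (p -> v): every neighbor u of v, via (v -> u)
    children = [
        [ctx_id[(v, u)] for u in nbrs[v]] for (_, v) in sorted(ctx_id, key=ctx_id.get)
    ]
    node_children = [[ctx_id[(v, u)] for u in nbrs[v]] for v in range(n)]
    return children, ctx_features, node_children


_PERM_CACHE: dict[int, np.ndarray] = {}


def _perms(m: int) -> np.ndarray:
    if m not in _PERM_CACHE:
        from itertools import permutations

        _PERM_CACHE[m] = np.array(list(permutations(range(m))))
    return _PERM_CACHE[m]


def _padded_transport(
    cost: np.ndarray, blank_rows: np.ndarray, blank_cols: np.ndarray
) -> float:
    """Unnormalized OT between two multisets after blank padding: a balanced
    assignment on the padded cost matrix.

    Molecular degrees are tiny, so small assignments are solved by direct
    permutation enumeration (faster than the Hungarian call overhead);
    larger ones fall back to the exact Hungarian algorithm.
    """
    na, nb = cost.shape
    m = max(na, nb)
    if m == 0:
        return 0.0
    C = np.zeros((m, m))
    C[:na, :nb] = cost
    if na < m:
        C[na:, :nb] = blank_cols[None, :]
    if nb < m:
        C[:na, nb:] = blank_rows[:, None]
    if m <= 5:
        perms = _perms(m)
        totals = C[np.arange(m)[None, :], perms].sum(axis=1)
        return float(totals.min())
    rows, cols = linear_sum_assignment(C)
    return float(C[rows, cols].sum())


def tree_mover_distance(
    g1: MolecularGraph, g2: MolecularGraph, params: TMDParams | None = None
) -> float:
    """Tree Mover Distance between two node-attributed graphs.

    The distance between two depth-l computation trees is the L1 difference
    of their root features plus a weighted optimal transport between their
    child-subtree multisets (padded with blank, zero-feature trees to equal
    size). The graph-level value is the optimal transport between the two
    graphs' multisets of depth-L node trees, padded with blank trees when
    node counts differ. All transports are solved exactly as balanced
    assignments. Bond features, when present on both graphs, are appended to
    the child node's features during unrolling.
    """
    params = params or TMDParams()
    if (g1.edge_features is None) != (g2.edge_features is None):
        raise ValueError("both graphs must carry bond features, or neither")
    if g1.node_features.shape[1] != g2.node_features.shape[1]:
        raise ValueError("node feature dimensions differ")
    if g1.edge_features is not None and g2.edge_features is not None:
        if g1.edge_features.shape[1] != g2.edge_features.shape[1]:
            raise ValueError("bond feature dimensions differ")

    ch1, cf1, root_ch1 = _context_tables(g1)
    ch2, cf2, root_ch2 = _context_tables(g2)
    weights = params.resolved_weights()
    L = params.depth

    # DP over directed-edge context pairs, bottom-up from depth 1
    if L > 1:
        D = cdist(cf1, cf2, metric="cityblock") if len(cf1) and len(cf2) else (
            np.zeros((len(cf1), len(cf2)))
        )
        b1 = np.abs(cf1).sum(axis=1) if len(cf1) else np.zeros(0)
        b2 = np.abs(cf2).sum(axis=1) if len(cf2) else np.zeros(0)
        for depth in range(2, L):  # contexts as roots of depth 2..L-1 trees
            w = weights[depth - 2]
            D_new = np.empty_like(D)
            b1_new = np.empty_like(b1)
            b2_new = np.empty_like(b2)
            for a in range(len(ch1)):
                for b in range(len(ch2)):
                    D_new[a, b] = cdist(
                        cf1[a : a + 1], cf2[b : b + 1], metric="cityblock"
                    )[0, 0] + w * _padded_transport(
                        D[np.ix_(ch1[a], ch2[b])], b1[ch1[a]], b2[ch2[b]]
                    )
            for a in range(len(ch1)):
                b1_new[a] = np.abs(cf1[a]).sum() + w * b1[ch1[a]].sum()
            for b in range(len(ch2)):
                b2_new[b] = np.abs(cf2[b]).sum() + w * b2[ch2[b]].sum()
            D, b1, b2 = D_new, b1_new, b2_new

    # root (node) level: depth-L trees headed by bare node features
    n1, n2 = g1.n_nodes, g2.n_nodes
    root_cost = cdist(g1.node_features, g2.node_features, metric="cityblock")
    root_blank1 = np.abs(g1.node_features).sum(axis=1)
    root_blank2 = np.abs(g2.node_features).sum(axis=1)
    if L > 1:
        w = weights[L - 2]
        for v1 in range(n1):
            for v2 in range(n2):
                root_cost[v1, v2] += w * _padded_transport(
                    D[np.ix_(root_ch1[v1], root_ch2[v2])],
                    b1[root_ch1[v1]],
                    b2[root_ch2[v2]],
                )
        root_blank1 = root_blank1 + w * np.array(
            [b1[root_ch1[v]].sum() for v in range(n1)]
        )
        root_blank2 = root_blank2 + w * np.array(
            [b2[root_ch2[v]].sum() for v in range(n2)]
        )
    return _padded_transport(root_cost, root_blank1, root_blank2)
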