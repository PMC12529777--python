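"""Split-generation strategies: one random reference plus ten OOD splitters.

Every splitter maps a data set to a :class:`SplitAssignment` — a disjoint
partition of record ids into an in-distribution (ID) pool and an
out-of-distribution (OOD) test set. Only the Lo-Hi splitter may additionally
*remove* molecules (the minimum set whose deletion disconnects the two
partitions in the similarity graph).

Determinism: the property splitters (molecular weight, reverse molecular
weight, logP) and Lo-Hi produce identical splits on repeated calls; all
other splitters vary with ``seed``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering

from .chem import (
    MoleculeRecord,
    clogp,
    ecfp_matrix,
    generic_scaffold,
    mol_weight,
    murcko_scaffold,
    tanimoto_matrix,
)

__all__ = [
    "SplitAssignment",
    "SplitterConfig",
    "SPLITTERS",
    "DETERMINISTIC_SPLITTERS",
    "get_splitter",
    "split_random",
    "split_scaffold",
    "split_property",
    "split_kmeans",
    "split_max_dissimilarity",
    "split_umap",
    "split_lohi",
    "split_datasail_s1",
]


@dataclass(frozen=True)
class SplitAssignment:
    """A disjoint ID-pool / OOD-test partition with provenance.

    ``removed`` is non-empty only for Lo-Hi; all other splitters cover the
    full data set.
    """

    id_pool: frozenset[str]
    ood_test: frozenset[str]
    splitter_name: str
    seed: int | None
    params: dict = field(default_factory=dict)
    removed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.id_pool & self.ood_test:
            raise ValueError("id_pool and ood_test overlap")
        if self.removed & (self.id_pool | self.ood_test):
            raise ValueError("removed ids overlap the partition")


@dataclass
class SplitterConfig:
    """Shared splitter settings.

    ``n_bits`` feeds the cluster/property splitters; the similarity-graph
    splitters (Lo-Hi, DataSAIL-S1) use ``n_bits_ilp``. ``ilp_size_tolerance``
    is relative to the OOD target (0.10 means the OOD share may land within
    ±10% of ``ood_fraction``), relaxed by ``ilp_relax_step`` on infeasibility.
    """

    ood_fraction: float = 0.2
    n_bits: int = 2048
    n_bits_ilp: int = 1024
    radius: int = 2
    n_reference: int = 512
    n_clusters: int = 10
    similarity_threshold: float = 0.4
    n_preclusters: int = 50
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    butina_above: int = 500
    ilp_size_tolerance: float = 0.10
    ilp_relax_step: float = 0.05
    max_pairwise_n: int = 25_000

    def __post_init__(self) -> None:
        if not 0.0 < self.ood_fraction < 1.0:
            raise ValueError("ood_fraction must lie in (0, 1)")
        if not 0.0 < self.similarity_threshold < 1.0:
            raise ValueError("similarity_threshold must lie in (0, 1)")


def _ids(records: Sequence[MoleculeRecord]) -> list[str]:
    return [r.id for r in records]


def _ood_target(n: int, frac: float) -> int:
    return int(math.ceil(frac * n))


def _assignment(
    records: Sequence[MoleculeRecord],
    ood_ids: set[str],
    name: str,
    seed: int | None,
    params: dict,
    removed: set[str] | None = None,
) -> SplitAssignment:
    removed = removed or set()
    id_pool = {r.id for r in records} - ood_ids - removed
    return SplitAssignment(
        id_pool=frozenset(id_pool),
        ood_test=frozenset(ood_ids),
        splitter_name=name,
        seed=seed,
        params=params,
        removed=frozenset(removed),
    )


# ---------------------------------------------------------------------------
# record- and group-level splitters


def split_random(
    records: Sequence[MoleculeRecord], cfg: SplitterConfig, seed: int
) -> SplitAssignment:
    """Uniform random OOD selection (the reference splitter)."""
    ids = _ids(records)
    rng = np.random.default_rng(seed)
    n_ood = _ood_target(len(ids), cfg.ood_fraction)
    ood = set(rng.choice(len(ids), size=n_ood, replace=False).tolist())
    ood_ids = {ids[i] for i in ood}
    return _assignment(
        records, ood_ids, "random", seed, {"ood_fraction": cfg.ood_fraction}
    )


def _groups_to_ood(
    groups: list[list[str]], target: int, total: int
) -> set[str]:
    """Assign whole groups (in the given order) to OOD until its size first
    reaches the target."""
    ood: set[str] = set()
    for grp in groups:
        if len(ood) >= target:
            break
        ood.update(grp)
    if len(ood) >= total:
        warnings.warn("a single group spans the data set; degenerate split")
    return ood


def split_scaffold(
    records: Sequence[MoleculeRecord],
    cfg: SplitterConfig,
    seed: int,
    generic: bool = False,
) -> SplitAssignment:
    """Bemis-Murcko scaffold split: molecules sharing a scaffold stay in the
    same subset; scaffold groups are drawn in seed-randomized order into the
    OOD test set until it first reaches the target size."""
    scaffold_fn = generic_scaffold if generic else murcko_scaffold
    by_scaffold: dict[str, list[str]] = {}
    for rec in records:
        by_scaffold.setdefault(scaffold_fn(rec), []).append(rec.id)
    groups = [by_scaffold[k] for k in sorted(by_scaffold)]
    rng = np.random.default_rng(seed)
    rng.shuffle(groups)
    target = _ood_target(len(records), cfg.ood_fraction)
    ood_ids = _groups_to_ood(groups, target, len(records))
    name = "scaffold-generic" if generic else "scaffold"
    return _assignment(
        records, ood_ids, name, seed, {"ood_fraction": cfg.ood_fraction}
    )


_PROPERTY_FNS: dict[str, Callable[[MoleculeRecord], float]] = {
    "mol_weight": mol_weight,
    "mol_weight_reverse": mol_weight,
    "clogp": clogp,
}


def split_property(
    records: Sequence[MoleculeRecord],
    cfg: SplitterConfig,
    property: str = "mol_weight",
) -> SplitAssignment:
    """Deterministic descriptor-sorted split.

    ``mol_weight`` and ``clogp`` put the *highest*-valued fraction in the
    OOD test set; ``mol_weight_reverse`` puts the lowest. Ties break by
    record id.
    """
    if property not in _PROPERTY_FNS:
        raise ValueError(f"unknown property {property!r}")
    fn = _PROPERTY_FNS[property]
    keyed = sorted(((fn(r), r.id) for r in records))
    n_ood = _ood_target(len(records), cfg.ood_fraction)
    if property == "mol_weight_reverse":
        ood_ids = {rid for _, rid in keyed[:n_ood]}
    else:
        ood_ids = {rid for _, rid in keyed[-n_ood:]}
    name = {
        "mol_weight": "molweight",
        "mol_weight_reverse": "molweight-reverse",
        "clogp": "logp",
    }[property]
    return _assignment(
        records, ood_ids, name, None, {"ood_fraction": cfg.ood_fraction}
    )


# ---------------------------------------------------------------------------
# cluster-based splitters


def _reference_distance_matrix(
    records: Sequence[MoleculeRecord], cfg: SplitterConfig, rng: np.random.Generator
) -> np.ndarray:
    """N x min(n_reference, N) matrix of Tanimoto distances to randomly
    chosen reference molecules — a continuous embedding of the binary
    fingerprints."""
    fps = ecfp_matrix(list(records), radius=cfg.radius, n_bits=cfg.n_bits)
    n_ref = min(cfg.n_reference, len(records))
    if n_ref < cfg.n_reference:
        warnings.warn(
            f"n_reference lowered to {n_ref} (data set smaller than requested)"
        )
    ref_idx = rng.choice(len(records), size=n_ref, replace=False)
    return 1.0 - tanimoto_matrix(fps, fps[ref_idx])


def _kmeans_clusters(
    records: Sequence[MoleculeRecord], cfg: SplitterConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """K-means in reference-distance space; returns (labels, centroids)."""
    if cfg.n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    rng = np.random.default_rng(seed)
    X = _reference_distance_matrix(records, cfg, rng)
    km = KMeans(n_clusters=cfg.n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_


def split_kmeans(
    records: Sequence[MoleculeRecord], cfg: SplitterConfig, seed: int
) -> SplitAssignment:
    """K-means clusters in Tanimoto-to-reference space, whole clusters
    assigned to OOD in random order until the target size is reached."""
    labels, _ = _kmeans_clusters(records, cfg, seed)
    ids = np.array(_ids(records))
    rng = np.random.default_rng(seed)
    order = rng.permutation(cfg.n_clusters)
    groups = [ids[labels == c].tolist() for c in order]
    target = _ood_target(len(records), cfg.ood_fraction)
    ood_ids = _groups_to_ood([g for g in groups if g], target, len(records))
    return _assignment(
        records,
        ood_ids,
        "kmeans",
        seed,
        {"ood_fraction": cfg.ood_fraction, "n_clusters": cfg.n_clusters},
    )


def split_max_dissimilarity(
    records: Sequence[MoleculeRecord], cfg: SplitterConfig, seed: int
) -> SplitAssignment:
    """Max-dissimilarity split over K-means clusters.

    The cluster with the largest mean centroid distance to all others seeds
    the OOD set; the cluster farthest from it seeds the ID set; remaining
    clusters join the ID set nearest-first until the ID share reaches
    1 − ood_fraction, and the rest go to OOD.
    """
    if cfg.n_clusters < 3:
        raise ValueError("max-dissimilarity needs at least 3 clusters")
    labels, centroids = _kmeans_clusters(records, cfg, seed)
    ids = np.array(_ids(records))
    k = centroids.shape[0]
    D = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    if np.allclose(D, 0.0):
        warnings.warn("all cluster centroids identical; degenerate split")
    mean_dist = D.sum(axis=1) / (k - 1)
    ood_seed_cluster = int(np.argmax(mean_dist))
    ood_clusters = {ood_seed_cluster}
    first_id = int(np.argmax(D[ood_seed_cluster]))
    id_clusters = {first_id}
    remaining = set(range(k)) - ood_clusters - id_clusters
    sizes = np.bincount(labels, minlength=k)
    id_size_target = (1.0 - cfg.ood_fraction) * len(records)
    while remaining and sizes[list(id_clusters)].sum() < id_size_target:
        nxt = min(remaining, key=lambda c: (min(D[c, j] for j in id_clusters), c))
        id_clusters.add(nxt)
        remaining.remove(nxt)
    ood_clusters |= remaining
    ood_ids = set(ids[np.isin(labels, list(ood_clusters))].tolist())
    return _assignment(
        records,
        ood_ids,
        "maxdissim",
        seed,
        {"ood_fraction": cfg.ood_fraction, "n_clusters": cfg.n_clusters},
    )


def split_umap(
    records: Sequence[MoleculeRecord], cfg: SplitterConfig, seed: int
) -> SplitAssignment:
    """UMAP embedding of fingerprints + agglomerative (Ward) clustering;
    clusters farthest from the global embedding centroid go to OOD first
    (the distribution-shift-maximizing rule)."""
    if len(records) < 50:
        raise ValueError("umap split needs at least 50 records")
    import umap  # deferred: slow import

    fps = ecfp_matrix(list(records), radius=cfg.radius, n_bits=cfg.n_bits)
    try:
        emb = umap.UMAP(
            n_components=2,
            n_neighbors=cfg.umap_n_neighbors,
            min_dist=cfg.umap_min_dist,
            metric="jaccard",
            random_state=seed,
        ).fit_transform(fps.astype(bool))
    except Exception as exc:
        raise RuntimeError(f"UMAP embedding failed (seed={seed}): {exc}") from exc
    emb = np.asarray(emb)
    labels = AgglomerativeClustering(
        n_clusters=cfg.n_clusters, linkage="ward"
    ).fit_predict(emb)
    global_centroid = emb.mean(axis=0)
    cluster_ids = np.unique(labels)
    centroid_dist = {
        c: float(np.linalg.norm(emb[labels == c].mean(axis=0) - global_centroid))
        for c in cluster_ids
    }
    order = sorted(cluster_ids, key=lambda c: (-centroid_dist[c], c))
    ids = np.array(_ids(records))
    groups = [ids[labels == c].tolist() for c in order]
    target = _ood_target(len(records), cfg.ood_fraction)
    ood_ids = _groups_to_ood(groups, target, len(records))
    return _assignment(
        records,
        ood_ids,
        "umap",
        seed,
        {"ood_fraction": cfg.ood_fraction, "n_clusters": cfg.n_clusters},
    )


# ---------------------------------------------------------------------------
# similarity-graph ILP splitters


def _pairwise_similarity(
    records: Sequence[MoleculeRecord], cfg: SplitterConfig
) -> np.ndarray:
    if len(records) > cfg.max_pairwise_n:
        raise ValueError(
            f"pairwise-similarity splitters cap at N={cfg.max_pairwise_n} "
            f"(got {len(records)}); O(N^2) memory"
        )
    fps = ecfp_matrix(list(records), radius=cfg.radius, n_bits=cfg.n_bits_ilp)
    return tanimoto_matrix(fps, fps)


def butina_clusters(S: np.ndarray, threshold: float) -> list[list[int]]:
    """Sphere-exclusion (Butina) clustering on a similarity matrix.

    Centroids are picked by descending neighbor count at ``similarity >
    threshold``; each centroid claims its unassigned neighbors.
    """
    n = S.shape[0]
    nbrs = [set(np.nonzero(S[i] > threshold)[0].tolist()) - {i} for i in range(n)]
    unassigned = set(range(n))
    clusters: list[list[int]] = []
    while unassigned:
        c = max(unassigned, key=lambda i: (len(nbrs[i] & unassigned), -i))
        members = (nbrs[c] & unassigned) | {c}
        clusters.append(sorted(members))
        unassigned -= members
    return clusters


def solve_disconnect(
    edges: list[tuple[int, int]],
    weights: np.ndarray,
    ood_fraction: float,
    size_tolerance: float,
    relax_step: float = 0.05,
    mip_rel_gap: float = 0.0,
    time_limit: float = 120.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimum-removal disconnection integer program (Lo-Hi core).

    Each unit (molecule or coarsened cluster, with ``weights`` counting
    molecules) is assigned to ID, OOD, or removed. No edge may join an ID
    unit to an OOD unit; the OOD weight must land within
    ``ood_fraction*(1 ± size_tolerance)`` of the surviving total; the removed
    weight is minimized. The tolerance is relaxed by ``relax_step`` until the
    program is feasible.

    Returns (ood mask, removed mask, tolerance used).
    """
    k = len(weights)
    w = np.asarray(weights, dtype=float)
    W = w.sum()
    f = ood_fraction
    tol = size_tolerance
    while True:
        lo_share, hi_share = f * (1 - tol), min(f * (1 + tol), 1.0)
        n_e = len(edges)
        A = sp.lil_matrix((2 * n_e + k + 2, 2 * k))
        lo: list[float] = []
        hi: list[float] = []
        for e, (u, v) in enumerate(edges):
            # o_u <= o_v + r_u + r_v  and symmetrically
            A[2 * e, u], A[2 * e, v] = 1, -1
            A[2 * e, k + u], A[2 * e, k + v] = -1, -1
            A[2 * e + 1, v], A[2 * e + 1, u] = 1, -1
            A[2 * e + 1, k + u], A[2 * e + 1, k + v] = -1, -1
            lo += [-np.inf, -np.inf]
            hi += [0.0, 0.0]
        for i in range(k):  # o_i + r_i <= 1
            A[2 * n_e + i, i] = 1
            A[2 * n_e + i, k + i] = 1
            lo.append(-np.inf)
            hi.append(1.0)
        # sum(w o) >= lo_share * (W - sum(w r))  and mirrored upper bound
        A[2 * n_e + k, :k] = w
        A[2 * n_e + k, k:] = lo_share * w
        lo.append(lo_share * W)
        hi.append(np.inf)
        A[2 * n_e + k + 1, :k] = w
        A[2 * n_e + k + 1, k:] = hi_share * w
        lo.append(-np.inf)
        hi.append(hi_share * W)
        cost = np.concatenate([np.zeros(k), w])
        res = milp(
            cost,
            constraints=LinearConstraint(sp.csr_matrix(A), lo, hi),
            integrality=np.ones(2 * k),
            bounds=Bounds(0, 1),
            options={"mip_rel_gap": mip_rel_gap, "time_limit": time_limit},
        )
        if res.status == 1 and res.x is not None:
            warnings.warn("disconnection ILP hit its time limit; using incumbent")
        if res.x is not None and res.status in (0, 1):
            x = np.round(res.x).astype(int)
            ood = (x[:k] == 1) & (x[k:] == 0)
            removed = x[k:] == 1
            return ood, removed, tol
        if lo_share <= 0.0 and hi_share >= 1.0:
            raise RuntimeError("disconnection ILP infeasible at any tolerance")
        tol += relax_step


def _greedy_disconnect(
    edges: list[tuple[int, int]],
    weights: np.ndarray,
    ood_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Documented greedy fallback when no ILP solver is available: fill the
    OOD set with whole connected components (smallest first); if the target
    cannot be reached, grow a BFS region inside the largest component and
    remove its boundary."""
    k = len(weights)
    w = np.asarray(weights, dtype=float)
    adj: dict[int, set[int]] = {i: set() for i in range(k)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    if edges:
        eu = np.array([u for u, _ in edges])
        ev = np.array([v for _, v in edges])
        graph = sp.csr_matrix(
            (np.ones(len(edges)), (eu, ev)), shape=(k, k)
        )
    else:
        graph = sp.csr_matrix((k, k))
    n_comp, comp = sp.csgraph.connected_components(graph, directed=False)
    target = ood_fraction * w.sum()
    comp_order = sorted(range(n_comp), key=lambda c: w[comp == c].sum())
    ood = np.zeros(k, dtype=bool)
    removed = np.zeros(k, dtype=bool)
    acc = 0.0
    for c in comp_order[:-1]:  # keep the largest component for ID
        if acc >= target:
            break
        mask = comp == c
        ood |= mask
        acc += w[mask].sum()
    if acc < target:
        giant = comp_order[-1]
        nodes = [int(i) for i in np.nonzero(comp == giant)[0]]
        frontier = [nodes[0]]
        seen = {nodes[0]}
        region: list[int] = []
        while frontier and acc < target:
            node = frontier.pop(0)
            region.append(node)
            acc += w[node]
            for nb in sorted(adj[node]):
                if nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        region_set = set(region)
        ood[list(region_set)] = True
        boundary = {
            nb for node in region_set for nb in adj[node] if nb not in region_set
        }
        removed[list(boundary)] = True
        ood[list(boundary)] = False
    return ood, removed


def split_lohi(
    records: Sequence[MoleculeRecord],
    cfg: SplitterConfig,
    use_ilp: bool = True,
) -> SplitAssignment:
    """Lo-Hi ("Hi") split: remove a minimum molecule set so that no OOD
    molecule has fingerprint Tanimoto similarity above the threshold to any
    ID molecule.

    Builds the similarity graph at ``cfg.similarity_threshold``, optionally
    coarsens it with Butina clustering (above ``cfg.butina_above``
    molecules), and solves the minimum-removal disconnection integer
    program. Deterministic.
    """
    S = _pairwise_similarity(records, cfg)
    n = len(records)
    ids = np.array(_ids(records))
    thr = cfg.similarity_threshold
    if n > cfg.butina_above:
        clusters = butina_clusters(S, thr)
    else:
        clusters = [[i] for i in range(n)]
    k = len(clusters)
    unit_of = np.zeros(n, dtype=int)
    for ci, members in enumerate(clusters):
        unit_of[members] = ci
    weights = np.array([len(c) for c in clusters], dtype=float)
    adj = S > thr
    np.fill_diagonal(adj, False)
    ii, jj = np.nonzero(np.triu(adj, 1))
    edge_set = {
        (min(a, b), max(a, b))
        for a, b in zip(unit_of[ii], unit_of[jj])
        if a != b
    }
    edges = sorted((int(u), int(v)) for u, v in edge_set)
    if use_ilp:
        ood_mask, removed_mask, tol = solve_disconnect(
            edges, weights, cfg.ood_fraction, cfg.ilp_size_tolerance,
            cfg.ilp_relax_step,
        )
    else:
        warnings.warn("solving Lo-Hi with the greedy edge-cut heuristic")
        ood_mask, removed_mask = _greedy_disconnect(
            edges, weights, cfg.ood_fraction
        )
        tol = float("nan")
    ood_ids = set(ids[ood_mask[unit_of]].tolist())
    removed_ids = set(ids[removed_mask[unit_of]].tolist())
    return _assignment(
        records,
        ood_ids,
        "lohi",
        None,
        {
            "ood_fraction": cfg.ood_fraction,
            "similarity_threshold": thr,
            "size_tolerance_used": tol,
            "coarsened": k < n,
        },
        removed=removed_ids,
    )


def solve_min_intersplit_similarity(
    cluster_sim: np.ndarray,
    weights: np.ndarray,
    ood_fraction: float,
    size_tolerance: float,
    relax_step: float = 0.05,
    mip_rel_gap: float = 0.15,
    time_limit: float = 60.0,
) -> tuple[np.ndarray, float, float]:
    """Assign whole clusters to {ID, OOD} minimizing the total similarity
    between clusters landing on opposite sides (DataSAIL-style S1 cold
    split), subject to the OOD weight landing within
    ``ood_fraction*(1 ± size_tolerance)`` of the total.

    Returns (ood mask over clusters, objective value, tolerance used).
    """
    k = len(weights)
    w = np.asarray(weights, dtype=float)
    W = w.sum()
    pairs = [
        (i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if cluster_sim[i, j] > 0
    ]
    f = ood_fraction
    tol = size_tolerance
    while True:
        lo_share, hi_share = f * (1 - tol), min(f * (1 + tol), 1.0)
        n_p = len(pairs)
        # variables: y_0..y_{k-1} (OOD indicators), z per pair (cut indicator)
        A = sp.lil_matrix((2 * n_p + 1, k + n_p))
        lo: list[float] = []
        hi: list[float] = []
        for p, (i, j) in enumerate(pairs):
            A[2 * p, i], A[2 * p, j], A[2 * p, k + p] = 1, -1, -1
            A[2 * p + 1, j], A[2 * p + 1, i], A[2 * p + 1, k + p] = 1, -1, -1
            lo += [-np.inf, -np.inf]
            hi += [0.0, 0.0]
        A[2 * n_p, :k] = w
        lo.append(lo_share * W)
        hi.append(hi_share * W)
        cost = np.concatenate(
            [np.zeros(k), np.array([cluster_sim[i, j] for i, j in pairs])]
        )
        integrality = np.concatenate([np.ones(k), np.zeros(n_p)])
        res = milp(
            cost,
            constraints=LinearConstraint(sp.csr_matrix(A), lo, hi),
            integrality=integrality,
            bounds=Bounds(0, 1),
            options={"mip_rel_gap": mip_rel_gap, "time_limit": time_limit},
        )
        if res.status == 1 and res.x is not None:
            warnings.warn("cold-split ILP hit its time limit; using incumbent")
        if res.x is not None and res.status in (0, 1):
            y = np.round(res.x[:k]).astype(bool)
            return y, float(res.fun), tol
        if lo_share <= 0.0 and hi_share >= 1.0:
            raise RuntimeError("cold-split ILP infeasible at any tolerance")
        tol += relax_step


def split_datasail_s1(
    records: Sequence[MoleculeRecord], cfg: SplitterConfig, seed: int
) -> SplitAssignment:
    """Similarity-based one-dimensional cold split: precluster molecules
    (spectral clustering on the Tanimoto similarity matrix), then assign
    whole clusters to ID/OOD by an integer program minimizing total
    inter-split similarity under the OOD size constraint."""
    S = _pairwise_similarity(records, cfg)
    n = len(records)
    ids = np.array(_ids(records))
    n_clust = min(cfg.n_preclusters, n)
    if n_clust < n:
        labels = SpectralClustering(
            n_clusters=n_clust,
            affinity="precomputed",
            random_state=seed,
            assign_labels="kmeans",
        ).fit_predict(S)
    else:
        labels = np.arange(n)
    k = labels.max() + 1
    member = np.zeros((k, n))
    member[labels, np.arange(n)] = 1.0
    cluster_sim = member @ S @ member.T
    np.fill_diagonal(cluster_sim, 0.0)
    weights = member.sum(axis=1)
    # small instances solve exactly; larger ones accept a relative MIP gap
    # (the balanced min-cut relaxation is weak and proof of optimality is
    # the expensive part, not solution quality)
    gap = 0.0 if k <= 15 else 0.15
    ood_mask, objective, tol = solve_min_intersplit_similarity(
        cluster_sim, weights, cfg.ood_fraction, cfg.ilp_size_tolerance,
        cfg.ilp_relax_step, mip_rel_gap=gap,
    )
    ood_ids = set(ids[ood_mask[labels]].tolist())
    return _assignment(
        records,
        ood_ids,
        "datasail-s1",
        seed,
        {
            "ood_fraction": cfg.ood_fraction,
            "n_preclusters": int(k),
            "objective": objective,
            "size_tolerance_used": tol,
        },
    )


# ---------------------------------------------------------------------------
# registry

SPLITTERS: dict[str, Callable[..., SplitAssignment]] = {
    "random": split_random,
    "scaffold": lambda records, cfg, seed: split_scaffold(records, cfg, seed),
    "scaffold-generic": lambda records, cfg, seed: split_scaffold(
        records, cfg, seed, generic=True
    ),
    "molweight": lambda records, cfg, seed=None: split_property(
        records, cfg, "mol_weight"
    ),
    "molweight-reverse": lambda records, cfg, seed=None: split_property(
        records, cfg, "mol_weight_reverse"
    ),
    "logp": lambda records, cfg, seed=None: split_property(records, cfg, "clogp"),
    "kmeans": split_kmeans,
    "maxdissim": split_max_dissimilarity,
    "umap": split_umap,
    "lohi": lambda records, cfg, seed=None: split_lohi(records, cfg),
    "datasail-s1": split_datasail_s1,
}

#: Splitters whose output does not depend on the seed.
DETERMINISTIC_SPLITTERS = frozenset(
    {"molweight", "molweight-reverse", "logp", "lohi"}
)


def get_splitter(name: str) -> Callable[..., SplitAssignment]:
    try:
        return SPLITTERS[name]
    except KeyError:
        raise ValueError(
            f"unknown splitter {name!r}; choose from {sorted(SPLITTERS)}"
        ) from None
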