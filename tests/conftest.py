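"""Shared fixtures: synthetic libraries, splits, and the brute-force
Tree Mover Distance oracle used to validate the dynamic-programming
implementation."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pytest

import splitshift as ss


@pytest.fixture(scope="session")
def lib400():
    """Small synthetic library for module-level tests."""
    return ss.generate_library(ss.LibraryConfig(n_molecules=400, seed=7))


@pytest.fixture(scope="session")
def lib400_frame():
    return ss.generate_library_frame(ss.LibraryConfig(n_molecules=400, seed=7))


@pytest.fixture(scope="session")
def lib2000():
    """Benchmark-scale synthetic library (chemotype-clustered, 45% active)."""
    return ss.generate_library(ss.LibraryConfig(n_molecules=2000, seed=1))


@pytest.fixture(scope="session")
def benchmark_splits(lib2000):
    """Every splitter run on the benchmark library over five seeds.

    Deterministic splitters are computed once and reused across seeds (their
    output cannot depend on the seed; determinism itself is asserted in the
    splitter tests).
    """
    cfg = ss.SplitterConfig()
    seeds = [101, 102, 103, 104, 105]
    out: dict[tuple[str, int], ss.SplitAssignment] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, fn in ss.SPLITTERS.items():
            if name in ss.DETERMINISTIC_SPLITTERS:
                split = fn(lib2000, cfg, seeds[0])
                for seed in seeds:
                    out[(name, seed)] = split
            else:
                for seed in seeds:
                    out[(name, seed)] = fn(lib2000, cfg, seed)
    return out


# ---------------------------------------------------------------------------
# brute-force TMD oracle (exhaustive assignment at every level)


def _build_tree(g, v, depth, parent_edge_feat=None):
    feat = g.node_features[v]
    if parent_edge_feat is not None:
        feat = np.concatenate([feat, parent_edge_feat])
    children = []
    if depth > 1:
        for e, (i, j) in enumerate(g.edge_list):
            for p, u in ((int(i), int(j)), (int(j), int(i))):
                if p == v:
                    ef = (
                        g.edge_features[e]
                        if g.edge_features is not None
                        else None
                    )
                    children.append(_build_tree(g, u, depth - 1, ef))
    return (feat, children)


def _tree_norm(tree, w):
    feat, children = tree
    return float(np.abs(feat).sum()) + (
        w * sum(_tree_norm(c, w) for c in children) if children else 0.0
    )


def _tree_dist(t1, t2, w):
    f1, c1 = t1
    f2, c2 = t2
    d = float(np.abs(f1 - f2).sum())
    if not c1 and not c2:
        return d
    m = max(len(c1), len(c2))
    cc1 = list(c1) + [None] * (m - len(c1))
    cc2 = list(c2) + [None] * (m - len(c2))

    def pair_cost(a, b):
        if a is None and b is None:
            return 0.0
        if a is None:
            return _tree_norm(b, w)
        if b is None:
            return _tree_norm(a, w)
        return _tree_dist(a, b, w)

    best = min(
        sum(pair_cost(cc1[i], cc2[perm[i]]) for i in range(m))
        for perm in itertools.permutations(range(m))
    )
    return d + w * best


def brute_force_tmd(g1, g2, depth=3, weight=1.0):
    """Exhaustive-permutation Tree Mover Distance for tiny graphs."""
    trees1 = [_build_tree(g1, v, depth) for v in range(g1.n_nodes)]
    trees2 = [_build_tree(g2, v, depth) for v in range(g2.n_nodes)]
    m = max(len(trees1), len(trees2))
    t1 = trees1 + [None] * (m - len(trees1))
    t2 = trees2 + [None] * (m - len(trees2))

    def pair_cost(a, b):
        if a is None and b is None:
            return 0.0
        if a is None:
            return _tree_norm(b, weight)
        if b is None:
            return _tree_norm(a, weight)
        return _tree_dist(a, b, weight)

    return min(
        sum(pair_cost(t1[i], t2[perm[i]]) for i in range(m))
        for perm in itertools.permutations(range(m))
    )


@pytest.fixture(scope="session")
def tmd_oracle():
    return brute_force_tmd
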