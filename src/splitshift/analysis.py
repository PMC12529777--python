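"""Cross-splitter synthesis: hardness rankings, rank correlations between
model-agnostic and model-dependent orderings, and the linear relationship
between ID and OOD performance.

The central question served here: when does in-distribution performance
predict out-of-distribution performance ("accuracy on the line")? Per-split
Pearson r and R² over (ID, OOD) metric pairs answer it; comparing rankings
of splitter hardness across bases (median Tanimoto k-NN distance, median
TMD, median ROC-AUC gap) shows how interchangeable the hardness proxies are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "HardnessRanking",
    "CorrelationReport",
    "rank_splitters",
    "rank_correlation",
    "id_ood_relation",
    "grouped_id_ood_relation",
]


@dataclass(frozen=True)
class HardnessRanking:
    """Splitters ordered from hardest to easiest under one basis."""

    order: tuple[str, ...]
    basis: str
    scores: dict
    has_ties: bool = False


@dataclass(frozen=True)
class CorrelationReport:
    """Linear-relationship statistics between ID and OOD performance."""

    pearson_r: float
    r_squared: float
    spearman_rho: float
    kendall_tau: float
    slope: float
    intercept: float
    n: int
    group: str | None = None
    undefined: bool = False


def rank_splitters(
    scores: Mapping[str, float], basis: str = "median_tanimoto"
) -> HardnessRanking:
    """Order splitters by descending hardness score; ties break
    alphabetically and are flagged."""
    if not scores:
        raise ValueError("empty score map")
    order = tuple(sorted(scores, key=lambda name: (-scores[name], name)))
    values = list(scores.values())
    has_ties = len(set(values)) < len(values)
    return HardnessRanking(
        order=order, basis=basis, scores=dict(scores), has_ties=has_ties
    )


def rank_correlation(
    r1: HardnessRanking, r2: HardnessRanking
) -> tuple[float, float]:
    """(Spearman rho, Kendall tau-b) between two hardness rankings over the
    same splitter set. Ranks come from each ranking's scores, so tied scores
    receive tied ranks."""
    if set(r1.order) != set(r2.order):
        raise ValueError("rankings cover different splitter sets")
    names = sorted(r1.order)
    x = [r1.scores[n] for n in names]
    y = [r2.scores[n] for n in names]
    rho = float(stats.spearmanr(x, y).statistic)
    tau = float(stats.kendalltau(x, y).statistic)  # tau-b: tie-corrected
    return rho, tau


def id_ood_relation(
    points: Sequence[tuple[float, float]], group: str | None = None
) -> CorrelationReport:
    """Pearson r, R², rank correlations, and the least-squares line for
    (ID, OOD) performance pairs.

    Zero variance on either axis makes the correlation undefined; the
    report is then flagged rather than carrying a number.
    """
    pts = np.asarray([(x, y) for x, y in points], dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return CorrelationReport(
            pearson_r=float("nan"),
            r_squared=float("nan"),
            spearman_rho=float("nan"),
            kendall_tau=float("nan"),
            slope=float("nan"),
            intercept=float("nan"),
            n=len(x),
            group=group,
            undefined=True,
        )
    fit = stats.linregress(x, y)
    rho = float(stats.spearmanr(x, y).statistic)
    tau = float(stats.kendalltau(x, y).statistic)
    return CorrelationReport(
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        spearman_rho=rho,
        kendall_tau=tau,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(x),
        group=group,
    )


def grouped_id_ood_relation(
    points: Sequence[tuple[float, float, str]],
) -> dict[str, "CorrelationReport | None"]:
    """Per-group ID-vs-OOD reports from (id_metric, ood_metric, group)
    triples. Groups with fewer than 3 points are flagged with None rather
    than silently dropped."""
    by_group: dict[str, list[tuple[float, float]]] = {}
    for x, y, g in points:
        by_group.setdefault(g, []).append((x, y))
    out: dict[str, CorrelationReport | None] = {}
    for g, pts in sorted(by_group.items()):
        out[g] = id_ood_relation(pts, group=g) if len(pts) >= 3 else None
    return out
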