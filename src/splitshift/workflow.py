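"""Label-shift-controlled split generation and ID-pool subdivision.

OOD splits should shift the input distribution P(X) while leaving the label
marginal P(Y) approximately unchanged; otherwise performance drops conflate
covariate shift with class-prior shift. For stochastic splitters this module
generates candidate splits under successive seeds and keeps only those whose
ID/OOD active-fraction difference falls below a threshold, relaxing the
threshold stepwise when too few candidates qualify. Deterministic splitters
produce a single split whose label shift is accepted as-is.

The accepted ID pool is then subdivided 72/8/20 into train / ID-validation /
ID-test by stratified random splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chem import MoleculeRecord
from .splitters import (
    DETERMINISTIC_SPLITTERS,
    SplitAssignment,
    SplitterConfig,
    get_splitter,
)

__all__ = [
    "LabelShiftPolicy",
    "DatasetSplit",
    "active_fraction",
    "label_shift",
    "generate_label_controlled_splits",
    "subdivide_id",
    "make_dataset_splits",
]


@dataclass
class LabelShiftPolicy:
    """Candidate-filtering schedule for the label-shift control loop.

    Fractions are absolute differences in active fraction (0.01 = one
    percentage point).
    """

    max_candidates: int = 100
    target_splits: int = 10
    initial_threshold: float = 0.01
    relax_step: float = 0.01
    max_threshold: float = 0.10

    def __post_init__(self) -> None:
        for name in ("initial_threshold", "relax_step", "max_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.max_candidates < self.target_splits:
            raise ValueError("max_candidates must be >= target_splits")


@dataclass(frozen=True)
class DatasetSplit:
    """A full experimental split: train / ID-val / ID-test / OOD-test."""

    train: frozenset[str]
    id_val: frozenset[str]
    id_test: frozenset[str]
    ood_test: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [self.train, self.id_val, self.id_test, self.ood_test]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("DatasetSplit subsets must be pairwise disjoint")


def active_fraction(records: Sequence[MoleculeRecord], ids: frozenset[str]) -> float:
    labels = [r.label for r in records if r.id in ids]
    if not labels:
        raise ValueError("empty id set")
    return float(np.mean(labels))


def label_shift(records: Sequence[MoleculeRecord], split: SplitAssignment) -> float:
    """|active%(ID pool) − active%(OOD test)| as a fraction in [0, 1]."""
    return abs(
        active_fraction(records, split.id_pool)
        - active_fraction(records, split.ood_test)
    )


def generate_label_controlled_splits(
    records: Sequence[MoleculeRecord],
    splitter: "str | Callable[..., SplitAssignment]",
    policy: LabelShiftPolicy | None = None,
    base_seed: int = 0,
    cfg: SplitterConfig | None = None,
) -> list[SplitAssignment]:
    """Generate up to ``policy.target_splits`` splits with bounded label shift.

    Candidates are produced with seeds ``base_seed .. base_seed +
    max_candidates − 1`` (in order, for auditability) and accepted while
    their label shift stays below the current threshold. If the target count
    is not reached, the threshold is relaxed by ``relax_step`` and the same
    candidates are re-filtered, up to ``max_threshold`` (then whatever was
    accepted is returned with a warning). Accepted splits carry the
    qualifying threshold in ``params['label_shift_threshold']``.

    A deterministic splitter yields exactly one split regardless of its
    label shift (controlling the label distribution is not possible there).
    """
    policy = policy or LabelShiftPolicy()
    cfg = cfg or SplitterConfig()
    name = splitter if isinstance(splitter, str) else getattr(
        splitter, "__name__", "custom"
    )
    fn = get_splitter(splitter) if isinstance(splitter, str) else splitter

    if isinstance(splitter, str) and splitter in DETERMINISTIC_SPLITTERS:
        split = fn(records, cfg, base_seed)
        shift = label_shift(records, split)
        split.params["label_shift"] = shift
        split.params["label_shift_threshold"] = None  # accepted as-is
        return [split]

    candidates: list[SplitAssignment] = []
    shifts: list[float] = []
    accepted_idx: list[int] = []
    threshold = policy.initial_threshold
    next_seed = base_seed
    while len(accepted_idx) < policy.target_splits:
        if next_seed < base_seed + policy.max_candidates:
            split = fn(records, cfg, next_seed)
            next_seed += 1
            candidates.append(split)
            shifts.append(label_shift(records, split))
            if shifts[-1] < threshold:
                accepted_idx.append(len(candidates) - 1)
            continue
        # candidate budget exhausted: relax and re-filter in candidate order
        new_threshold = threshold + policy.relax_step
        if new_threshold > policy.max_threshold + 1e-12:
            warnings.warn(
                f"only {len(accepted_idx)} of {policy.target_splits} splits "
                f"qualify at max threshold {policy.max_threshold:.3f}"
            )
            break
        threshold = new_threshold
        accepted_idx = [
            i for i, s in enumerate(shifts) if s < threshold
        ][: policy.target_splits]
    if not candidates:
        raise RuntimeError("no candidate splits could be generated")
    out = []
    for i in accepted_idx[: policy.target_splits]:
        split = candidates[i]
        split.params["label_shift"] = shifts[i]
        split.params["label_shift_threshold"] = threshold
        out.append(split)
    return out


def _stratified_three_way(
    ids_by_class: dict[int, list[str]],
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[set[str], set[str], set[str]]:
    """Per-class largest-remainder allocation into three subsets."""
    outs: tuple[set[str], set[str], set[str]] = (set(), set(), set())
    for _, members in sorted(ids_by_class.items()):
        members = sorted(members)
        rng.shuffle(members)
        n = len(members)
        exact = [f * n for f in fractions]
        counts = [int(np.floor(e)) for e in exact]
        short = n - sum(counts)
        remainders = sorted(
            range(3), key=lambda i: (exact[i] - counts[i], -i), reverse=True
        )
        for i in remainders[:short]:
            counts[i] += 1
        pos = 0
        for subset, c in zip(outs, counts):
            subset.update(members[pos : pos + c])
            pos += c
    return outs


def subdivide_id(
    id_pool_records: Sequence[MoleculeRecord], seed: int
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Stratified 72/8/20 subdivision of the ID pool into
    (train, id_val, id_test)."""
    by_class: dict[int, list[str]] = {}
    for r in id_pool_records:
        by_class.setdefault(r.label, []).append(r.id)
    if len(by_class) < 2:
        raise ValueError("both classes must be present in the ID pool")
    for cls, members in by_class.items():
        if len(members) < 3:
            raise ValueError(
                f"class {cls} has {len(members)} members; cannot stratify "
                "into three subsets"
            )
    rng = np.random.default_rng(seed)
    train, id_val, id_test = _stratified_three_way(
        by_class, (0.72, 0.08, 0.20), rng
    )
    return frozenset(train), frozenset(id_val), frozenset(id_test)


def make_dataset_splits(
    records: Sequence[MoleculeRecord],
    splitter: str,
    policy: LabelShiftPolicy | None = None,
    base_seed: int = 0,
    cfg: SplitterConfig | None = None,
) -> list[DatasetSplit]:
    """End-to-end split workflow: label-controlled ID/OOD partitions, each
    subdivided 72/8/20 into train / ID-val / ID-test."""
    assignments = generate_label_controlled_splits(
        records, splitter, policy, base_seed, cfg
    )
    by_id = {r.id: r for r in records}
    out: list[DatasetSplit] = []
    for assignment in assignments:
        pool_records = [by_id[i] for i in sorted(assignment.id_pool)]
        sub_seed = (assignment.seed if assignment.seed is not None else base_seed)
        train, id_val, id_test = subdivide_id(pool_records, sub_seed)
        out.append(
            DatasetSplit(
                train=train,
                id_val=id_val,
                id_test=id_test,
                ood_test=assignment.ood_test,
                provenance={
                    "splitter": assignment.splitter_name,
                    "seed": assignment.seed,
                    **assignment.params,
                },
            )
        )
    return out
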