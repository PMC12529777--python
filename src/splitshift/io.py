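"""Reading and writing the package's text artifacts.

Data sets are CSV with columns ``id, smiles, label``; splits, shift
profiles, evaluation results, and reports are JSON. All text is UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .chem import MoleculeRecord, Rejection
from .distances import ShiftProfile
from .splitters import SplitAssignment
from .workflow import DatasetSplit

__all__ = [
    "read_dataset_csv",
    "read_smiles_file",
    "write_dataset_csv",
    "write_rejections",
    "split_to_dict",
    "split_from_dict",
    "dataset_split_to_dict",
    "dataset_split_from_dict",
    "profile_to_dict",
    "write_json",
    "read_json",
]


def read_dataset_csv(path: "str | Path") -> list[MoleculeRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    missing = {"id", "smiles", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ValueError("dataset ids are not unique")
    return [
        MoleculeRecord(id=r.id, smiles=r.smiles, label=int(r.label))
        for r in df.itertuples()
    ]


def read_smiles_file(path: "str | Path") -> list[str]:
    """Raw SMILES, one per line; blank lines ignored. Feed the result to
    :func:`splitshift.standardize_records` together with ids and labels."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_dataset_csv(records: Sequence[MoleculeRecord], path: "str | Path") -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "label": [r.label for r in records],
        }
    ).to_csv(path, index=False)


def write_rejections(rejections: Sequence[Rejection], path: "str | Path") -> None:
    """Sidecar log of molecules rejected during standardization."""
    with open(path, "w", encoding="utf-8") as fh:
        for rej in rejections:
            fh.write(f"{rej.raw_smiles}\t{rej.reason}\n")


def split_to_dict(split: SplitAssignment) -> dict:
    return {
        "splitter": split.splitter_name,
        "seed": split.seed,
        "params": split.params,
        "id_pool": sorted(split.id_pool),
        "ood_test": sorted(split.ood_test),
        "removed": sorted(split.removed),
    }


def split_from_dict(d: dict) -> SplitAssignment:
    return SplitAssignment(
        id_pool=frozenset(d["id_pool"]),
        ood_test=frozenset(d["ood_test"]),
        splitter_name=d["splitter"],
        seed=d.get("seed"),
        params=d.get("params", {}),
        removed=frozenset(d.get("removed", [])),
    )


def dataset_split_to_dict(split: DatasetSplit) -> dict:
    return {
        "train": sorted(split.train),
        "id_val": sorted(split.id_val),
        "id_test": sorted(split.id_test),
        "ood_test": sorted(split.ood_test),
        "provenance": split.provenance,
    }


def dataset_split_from_dict(d: dict) -> DatasetSplit:
    return DatasetSplit(
        train=frozenset(d["train"]),
        id_val=frozenset(d["id_val"]),
        id_test=frozenset(d["id_test"]),
        ood_test=frozenset(d["ood_test"]),
        provenance=d.get("provenance", {}),
    )


def profile_to_dict(profile: ShiftProfile) -> dict:
    return {
        "metric": profile.metric_name,
        "k": profile.k,
        "summary": profile.summary,
        "per_molecule": [[i, v] for i, v in profile.per_molecule],
    }


def write_json(obj, path: "str | Path") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: "str | Path"):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
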