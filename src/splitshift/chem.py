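"""Molecule ingestion, standardization, and canonical representations.

Everything downstream (splitters, distances, model evaluation) consumes the
objects produced here: standardized :class:`MoleculeRecord` lists, hashed
circular fingerprints (ECFP4), Bemis-Murcko scaffolds, simple physico-chemical
descriptors, and attributed molecular graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "StandardizationConfig",
    "Rejection",
    "Fingerprint",
    "MolecularGraph",
    "standardize",
    "standardize_records",
    "deduplicate",
    "downsample_majority",
    "ecfp",
    "ecfp_matrix",
    "tanimoto",
    "tanimoto_matrix",
    "murcko_scaffold",
    "generic_scaffold",
    "mol_weight",
    "clogp",
    "to_graph",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """One standardized molecule with a binary activity label (1 = active)."""

    id: str
    smiles: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class StandardizationConfig:
    """Switches for the standardization pipeline.

    The pipeline keeps the largest organic fragment (salt stripping),
    neutralizes charges (a pH-independent stand-in for protonation-state
    correction at the configured pH), and canonicalizes tautomers, in that
    order.
    """

    strip_salts: bool = True
    protonate_ph: float = 7.4
    canonical_tautomer: bool = True
    drop_invalid: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.protonate_ph <= 14.0:
            raise ValueError("protonate_ph must lie in [0, 14]")


@dataclass(frozen=True)
class Rejection:
    """Marker for an input SMILES that could not be standardized."""

    raw_smiles: str
    reason: str


@dataclass(frozen=True)
class Fingerprint:
    """Hashed circular (Morgan/ECFP) fingerprint as a dense 0/1 vector."""

    bits: np.ndarray
    n_bits: int
    radius: int

    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph with per-atom (and optionally per-bond) features.

    ``edge_list`` stores each undirected bond once as an (i, j) pair with
    i < j; ``edge_features`` is aligned with it when present.
    """

    node_features: np.ndarray
    edge_list: np.ndarray
    edge_features: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.node_features.shape[0]
        if self.edge_list.size and (
            self.edge_list.min() < 0 or self.edge_list.max() >= n
        ):
            raise ValueError("edge indices out of range")

    @property
    def n_nodes(self) -> int:
        return int(self.node_features.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.edge_list.shape[0])


# ---------------------------------------------------------------------------
# standardization


def _mol_from_smiles(smiles: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smiles)


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER_ENUM: rdMolStandardize.TautomerEnumerator | None = None


def _tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    global _TAUTOMER_ENUM
    if _TAUTOMER_ENUM is None:
        _TAUTOMER_ENUM = rdMolStandardize.TautomerEnumerator()
    return _TAUTOMER_ENUM


def standardize(
    raw_smiles: str, cfg: StandardizationConfig | None = None
) -> str | Rejection:
    """Standardize one SMILES string to its canonical form.

    Steps, in order and each gated by ``cfg``: keep the largest organic
    fragment, neutralize formal charges, canonicalize the tautomer. Returns
    the canonical SMILES, or a :class:`Rejection` for unparseable input
    (never a silent drop).

    Raises
    ------
    ValueError
        If ``raw_smiles`` is empty.
    """
    if cfg is None:
        cfg = StandardizationConfig()
    if not raw_smiles or not raw_smiles.strip():
        raise ValueError("empty SMILES string")
    mol = _mol_from_smiles(raw_smiles)
    if mol is None:
        return Rejection(raw_smiles, "unparseable SMILES")
    try:
        if cfg.strip_salts:
            mol = _FRAGMENT_CHOOSER.choose(mol)
        mol = _UNCHARGER.uncharge(mol)
        if cfg.canonical_tautomer:
            mol = _tautomer_enumerator().Canonicalize(mol)
    except Exception as exc:  # rdkit raises a zoo of exception types
        return Rejection(raw_smiles, f"standardization failed: {exc}")
    if mol is None or mol.GetNumAtoms() == 0:
        return Rejection(raw_smiles, "no atoms after standardization")
    return Chem.MolToSmiles(mol)


def standardize_records(
    rows: list[tuple[str, str, int]],
    cfg: StandardizationConfig | None = None,
) -> tuple[list[MoleculeRecord], list[Rejection]]:
    """Standardize (id, smiles, label) rows; collect rejections separately."""
    records: list[MoleculeRecord] = []
    rejections: list[Rejection] = []
    for rid, smi, label in rows:
        out = standardize(smi, cfg)
        if isinstance(out, Rejection):
            rejections.append(out)
        else:
            records.append(MoleculeRecord(id=str(rid), smiles=out, label=int(label)))
    return records, rejections


def deduplicate(records: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """Collapse records sharing a canonical SMILES to one record each.

    Records whose duplicates carry *conflicting* labels are removed entirely:
    a binary task cannot keep contradictory labels, so neither copy survives.
    Input order of the survivors is preserved.
    """
    labels_by_smiles: dict[str, set[int]] = {}
    for rec in records:
        labels_by_smiles.setdefault(rec.smiles, set()).add(rec.label)
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        if len(labels_by_smiles[rec.smiles]) > 1:
            continue  # conflicting labels: drop all copies
        if rec.smiles in seen:
            continue
        seen.add(rec.smiles)
        out.append(rec)
    return out


def downsample_majority(
    records: list[MoleculeRecord],
    target_active_fraction: float,
    seed: int,
) -> list[MoleculeRecord]:
    """Randomly remove majority-class records until the active fraction
    reaches ``target_active_fraction`` (within ±0.005).

    If the minority class already sits above the target the input is
    returned unchanged with a warning. Reproducible under ``seed``.
    """
    if not 0.0 < target_active_fraction < 1.0:
        raise ValueError("target_active_fraction must lie in (0, 1)")
    actives = [r for r in records if r.label == 1]
    inactives = [r for r in records if r.label == 0]
    n_act, n_inact = len(actives), len(inactives)
    frac = n_act / max(n_act + n_inact, 1)
    t = target_active_fraction
    rng = np.random.default_rng(seed)
    if abs(frac - t) <= 0.005:
        return list(records)
    if frac < t:
        # raising the active fraction means shrinking the inactives; only
        # legitimate when they are the majority class
        if n_inact < n_act:
            warnings.warn(
                "target unreachable by majority downsampling (minority class "
                "already above target); returning input"
            )
            return list(records)
        keep_inact = int(round(n_act * (1 - t) / t))
        kept = set(rng.choice(n_inact, size=keep_inact, replace=False).tolist())
        surviving = {id(r) for i, r in enumerate(inactives) if i in kept}
        return [r for r in records if r.label == 1 or id(r) in surviving]
    if n_act < n_inact:
        warnings.warn(
            "target unreachable by majority downsampling (minority class "
            "already above target); returning input"
        )
        return list(records)
    keep_act = int(round(n_inact * t / (1 - t)))
    kept = set(rng.choice(n_act, size=keep_act, replace=False).tolist())
    surviving = {id(r) for i, r in enumerate(actives) if i in kept}
    return [r for r in records if r.label == 0 or id(r) in surviving]


# ---------------------------------------------------------------------------
# fingerprints


def _as_mol(record: "MoleculeRecord | str | Chem.Mol") -> Chem.Mol:
    if isinstance(record, Chem.Mol):
        return record
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles!r}")
    return mol


def ecfp(
    record: "MoleculeRecord | str", radius: int = 2, n_bits: int = 2048
) -> Fingerprint:
    """ECFP-style hashed circular fingerprint (Morgan, radius 2 == ECFP4)."""
    mol = _as_mol(record)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = gen.GetFingerprintAsNumPy(mol).astype(np.uint8)
    return Fingerprint(bits=bits, n_bits=n_bits, radius=radius)


def ecfp_matrix(
    records: list[MoleculeRecord], radius: int = 2, n_bits: int = 2048
) -> np.ndarray:
    """Stack fingerprints of ``records`` into an (N, n_bits) uint8 matrix."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(records), n_bits), dtype=np.uint8)
    for i, rec in enumerate(records):
        out[i] = gen.GetFingerprintAsNumPy(_as_mol(rec))
    return out


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a∩b| / |a∪b| of two equal-length fingerprints.

    Two all-zero fingerprints are defined to have similarity 1.0 (identical
    objects).
    """
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    inter = int(np.logical_and(a.bits, b.bits).sum())
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 1.0
    return inter / union


def tanimoto_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between the rows of two 0/1 matrices.

    Vectorized via the bit-count identity |a∪b| = |a| + |b| − |a∩b|.
    All-zero pairs get similarity 1.0 (same convention as :func:`tanimoto`).
    """
    if a.shape[1] != b.shape[1]:
        raise ValueError("fingerprint lengths differ")
    af = a.astype(np.float32)
    bf = b.astype(np.float32)
    # popcounts and intersections are small integers, exact in float32;
    # divide in float64 so ratios like 10/25 come out exactly 0.4
    inter = (af @ bf.T).astype(np.float64)
    pa = af.sum(axis=1, dtype=np.float64)[:, None]
    pb = bf.sum(axis=1, dtype=np.float64)[None, :]
    union = pa + pb - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


# ---------------------------------------------------------------------------
# scaffolds & descriptors


def murcko_scaffold(record: "MoleculeRecord | str") -> str:
    """Bemis-Murcko scaffold SMILES: ring systems plus linkers, side chains
    removed. Acyclic molecules yield the empty string."""
    mol = _as_mol(record)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def generic_scaffold(record: "MoleculeRecord | str") -> str:
    """Generic Bemis-Murcko scaffold: every atom mapped to carbon, every
    bond to single order. Empty string for acyclic molecules."""
    mol = _as_mol(record)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    generic = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    return Chem.MolToSmiles(generic)


def mol_weight(record: "MoleculeRecord | str") -> float:
    """Exact (monoisotopic) molecular weight in Da."""
    return float(rdMolDescriptors.CalcExactMolWt(_as_mol(record)))


def clogp(record: "MoleculeRecord | str") -> float:
    """Crippen atomic-contribution calculated logP."""
    return float(Descriptors.MolLogP(_as_mol(record)))


# ---------------------------------------------------------------------------
# attributed graphs

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
_BOND_ORDERS = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

FEATURE_SCHEMES = ("default",)


def _atom_features(atom: Chem.Atom) -> list[float]:
    onehot = [1.0 if atom.GetSymbol() == el else 0.0 for el in _ELEMENTS]
    onehot.append(1.0 if atom.GetSymbol() not in _ELEMENTS else 0.0)  # "other"
    return onehot + [
        float(atom.GetDegree()),
        float(atom.GetFormalCharge()),
        1.0 if atom.GetIsAromatic() else 0.0,
    ]


def _bond_features(bond: Chem.Bond) -> list[float]:
    onehot = [1.0 if bond.GetBondType() == bt else 0.0 for bt in _BOND_ORDERS]
    return onehot + [1.0 if bond.GetIsConjugated() else 0.0]


def to_graph(
    record: "MoleculeRecord | str",
    feature_scheme: str = "default",
    with_bond_features: bool = True,
) -> MolecularGraph:
    """Convert a molecule to a heavy-atom attributed graph.

    The ``default`` scheme encodes atoms as one-hot element
    (C,N,O,S,F,Cl,Br,I,P,other) + degree + formal charge + aromaticity
    (13 dims), and bonds as one-hot order (single/double/triple/aromatic)
    + conjugation flag (5 dims).
    """
    if feature_scheme not in FEATURE_SCHEMES:
        raise ValueError(f"unknown feature scheme {feature_scheme!r}")
    mol = _as_mol(record)
    nodes = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=np.float64)
    edges: list[tuple[int, int]] = []
    efeat: list[list[float]] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
        efeat.append(_bond_features(bond))
    edge_list = (
        np.array(edges, dtype=np.int64)
        if edges
        else np.zeros((0, 2), dtype=np.int64)
    )
    edge_features = (
        np.array(efeat, dtype=np.float64)
        if (efeat and with_bond_features)
        else None
    )
    return MolecularGraph(
        node_features=nodes, edge_list=edge_list, edge_features=edge_features
    )
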