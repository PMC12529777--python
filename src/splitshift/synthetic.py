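"""Synthetic molecule libraries with planted chemotype structure.

The generator decorates a fixed set of ring-system templates (chemotypes)
with substituent chains and emits valid, unique, canonical SMILES. Activity
is a deterministic function of structure: each template is paired with one
pharmacophore group, and a molecule is active exactly when its ring system
carries that group (optionally XOR-ed with Bernoulli label noise). Because
activity depends on the template x group *interaction* — every group also
appears as an inactive decoy on other templates — holding out whole
chemotypes creates genuine covariate shift in label-relevant features while
leaving the label marginal nearly unchanged.

Ring-bearing substituents (phenyl, cyclopropyl, cyclopentyl) deliberately
fragment Bemis-Murcko scaffolds within a chemotype, so scaffold-based
splits separate less chemical space than fingerprint-cluster splits do —
mirroring the low molecules-per-scaffold ratio of real screening sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import MolecularGraph, MoleculeRecord

__all__ = [
    "LibraryConfig",
    "SCAFFOLD_TEMPLATES",
    "PHARMACOPHORE_GROUPS",
    "generate_library",
    "generate_library_frame",
    "structural_label",
    "pharmacophore_patterns",
    "generate_toy_graphs",
]

#: Ring-system templates spanning a molecular-weight and logP range.
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "C1CCCCC1",            # cyclohexane
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc2ncccc2c1",      # quinoline
    "C1CCNCC1",            # piperidine
    "c1ccsc1",             # thiophene
    "c1ccoc1",             # furan
    "c1ccc(-c2ccccc2)cc1", # biphenyl
)

#: Pharmacophore groups; template t is paired with group t mod 4.
PHARMACOPHORE_GROUPS: tuple[str, ...] = (
    "S(=O)(=O)N",  # sulfonamide
    "C(=O)O",      # carboxylic acid
    "C(F)(F)F",    # trifluoromethyl
    "C#N",         # nitrile
)

#: Ordinary substituents (first atom is the attachment point). None of these
#: contains a pharmacophore group.
SUBSTITUENT_ALPHABET: tuple[str, ...] = (
    "C", "O", "F", "CC", "OC", "N", "c1ccccc1", "C1CC1",
    "Cl", "N(C)C", "CCC", "C1CCCC1", "Br", "C(C)C", "OCC",
)


@dataclass
class LibraryConfig:
    """Generator settings.

    ``active_fraction`` must lie in [0.30, 0.70], the class-balance envelope
    that realistic binary bioactivity benchmarks are screened for; the
    library size defaults emulate a down-scaled screening set.
    """

    n_molecules: int = 2000
    n_scaffold_templates: int = 10
    n_substituents: int = 12
    active_fraction: float = 0.45
    label_noise: float = 0.1
    seed: int = 0
    max_extra_substituents: int = 3
    decoy_rate: float = 0.35

    def __post_init__(self) -> None:
        if self.n_molecules < 50:
            raise ValueError("n_molecules must be >= 50")
        if not 0.30 <= self.active_fraction <= 0.70:
            raise ValueError("active_fraction must lie in [0.30, 0.70]")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 2 <= self.n_scaffold_templates <= len(SCAFFOLD_TEMPLATES):
            raise ValueError(
                f"n_scaffold_templates must lie in [2, {len(SCAFFOLD_TEMPLATES)}]"
            )
        if not 1 <= self.n_substituents <= len(SUBSTITUENT_ALPHABET):
            raise ValueError(
                f"n_substituents must lie in [1, {len(SUBSTITUENT_ALPHABET)}]"
            )


def _group_for_template(t: int) -> str:
    return PHARMACOPHORE_GROUPS[t % len(PHARMACOPHORE_GROUPS)]


def _attach(mol: Chem.Mol, core_atom: int, frag_smiles: str) -> Chem.Mol | None:
    """Attach a fragment (atom 0 = attachment point) to ``core_atom`` by a
    single bond; returns None if the result does not sanitize."""
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        return None
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(core_atom, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _open_core_positions(mol: Chem.Mol, n_core: int) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIdx() < n_core and a.GetTotalNumHs() >= 1
    ]


def pharmacophore_patterns(n_templates: int = 10) -> list[Chem.Mol]:
    """Substructure queries defining activity: each template core decorated
    with its paired pharmacophore group at every attachable ring position."""
    patterns: list[Chem.Mol] = []
    seen: set[str] = set()
    for t in range(n_templates):
        core = Chem.MolFromSmiles(SCAFFOLD_TEMPLATES[t])
        group = _group_for_template(t)
        for pos in _open_core_positions(core, core.GetNumAtoms()):
            pat = _attach(core, pos, group)
            if pat is None:
                continue
            smi = Chem.MolToSmiles(pat)
            if smi not in seen:
                seen.add(smi)
                patterns.append(pat)
    return patterns


def structural_label(
    mol: "Chem.Mol | str", patterns: list[Chem.Mol] | None = None
) -> int:
    """Noise-free activity oracle: 1 iff the molecule matches any
    template-plus-matching-pharmacophore pattern."""
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise ValueError("invalid molecule")
    if patterns is None:
        patterns = pharmacophore_patterns()
    return int(any(mol.HasSubstructMatch(p) for p in patterns))


def _sample_molecule(
    rng: np.random.Generator,
    template_idx: int,
    want_pharma: bool,
    cfg: LibraryConfig,
) -> str | None:
    """Build one decorated molecule; returns canonical SMILES or None."""
    mol = Chem.MolFromSmiles(SCAFFOLD_TEMPLATES[template_idx])
    n_core = mol.GetNumAtoms()
    attachments: list[str] = []
    if want_pharma:
        attachments.append(_group_for_template(template_idx))
    elif rng.random() < cfg.decoy_rate:
        # decoy: some *other* template's pharmacophore group
        own = _group_for_template(template_idx)
        others = [g for g in PHARMACOPHORE_GROUPS if g != own]
        attachments.append(others[rng.integers(len(others))])
    alphabet = SUBSTITUENT_ALPHABET[: cfg.n_substituents]
    n_extra = int(rng.integers(1, cfg.max_extra_substituents + 1))
    attachments.extend(alphabet[i] for i in rng.integers(len(alphabet), size=n_extra))
    for frag in attachments:
        open_pos = _open_core_positions(mol, n_core)
        if not open_pos:
            return None
        for _ in range(4):  # a few tries: some positions fail sanitization
            pos = int(open_pos[rng.integers(len(open_pos))])
            new = _attach(mol, pos, frag)
            if new is not None:
                mol = new
                break
        else:
            return None
    return Chem.MolToSmiles(mol)


def generate_library_frame(cfg: LibraryConfig) -> pd.DataFrame:
    """Generate the library with per-molecule metadata.

    Columns: id, smiles, label, template (index of the chemotype template),
    structural_label (the noise-free activity), flipped (noise flag).
    Quota sampling fixes the pre-noise active count exactly, then label
    noise is applied; the realized active fraction must land within 2
    percentage points of the target or generation fails.
    """
    rng = np.random.default_rng(cfg.seed)
    patterns = pharmacophore_patterns(cfg.n_scaffold_templates)
    eps = cfg.label_noise
    # choose the pre-noise fraction so that the expected post-noise
    # fraction equals the target: f_noisy = f(1-2e) + e
    struct_target = (cfg.active_fraction - eps) / (1.0 - 2.0 * eps)
    struct_target = min(max(struct_target, 0.0), 1.0)
    n_active = int(round(cfg.n_molecules * struct_target))
    n_inactive = cfg.n_molecules - n_active

    seen: set[str] = set()
    rows: list[tuple[str, int, int]] = []  # smiles, template, structural label
    got_active = got_inactive = 0
    attempts = 0
    max_attempts = 80 * cfg.n_molecules
    while len(rows) < cfg.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not reach the target active fraction: "
                f"{got_active} actives / {got_inactive} inactives after "
                f"{attempts} attempts (target {n_active}/{n_inactive})"
            )
        t = int(rng.integers(cfg.n_scaffold_templates))
        want = bool(rng.random() < struct_target)
        smi = _sample_molecule(rng, t, want, cfg)
        if smi is None or smi in seen:
            continue
        y = structural_label(Chem.MolFromSmiles(smi), patterns)
        if y == 1 and got_active < n_active:
            got_active += 1
        elif y == 0 and got_inactive < n_inactive:
            got_inactive += 1
        else:
            continue
        seen.add(smi)
        rows.append((smi, t, y))

    # fixed-count noise: flip exactly eps of each class so the realized
    # active fraction stays on target instead of drifting binomially
    struct = np.array([r[2] for r in rows])
    flips = np.zeros(cfg.n_molecules, dtype=bool)
    for cls in (0, 1):
        members = np.nonzero(struct == cls)[0]
        n_flip = int(round(eps * len(members)))
        if n_flip:
            flips[rng.choice(members, size=n_flip, replace=False)] = True
    df = pd.DataFrame(
        {
            "id": [f"M{i:05d}" for i in range(cfg.n_molecules)],
            "smiles": [r[0] for r in rows],
            "template": [r[1] for r in rows],
            "structural_label": [r[2] for r in rows],
            "flipped": flips,
        }
    )
    df["label"] = (df["structural_label"] ^ flips).astype(int)
    realized = df["label"].mean()
    if abs(realized - cfg.active_fraction) > 0.02:
        raise RuntimeError(
            f"realized active fraction {realized:.3f} misses target "
            f"{cfg.active_fraction:.3f} by more than 0.02"
        )
    return df[["id", "smiles", "label", "template", "structural_label", "flipped"]]


def generate_library(cfg: LibraryConfig) -> list[MoleculeRecord]:
    """Generate a seed-reproducible library of unique, valid molecules."""
    df = generate_library_frame(cfg)
    return [
        MoleculeRecord(id=r.id, smiles=r.smiles, label=int(r.label))
        for r in df.itertuples()
    ]


def generate_toy_graphs(
    n: int, max_nodes: int, feature_dim: int, seed: int
) -> list[MolecularGraph]:
    """Random connected attributed graphs for brute-force distance checks."""
    if max_nodes > 6:
        raise ValueError("max_nodes must be <= 6 (brute-force fixture regime)")
    rng = np.random.default_rng(seed)
    graphs: list[MolecularGraph] = []
    for _ in range(n):
        m = int(rng.integers(1, max_nodes + 1))
        edges: set[tuple[int, int]] = set()
        for i in range(1, m):  # random spanning tree keeps it connected
            j = int(rng.integers(i))
            edges.add((j, i))
        for i in range(m):
            for j in range(i + 1, m):
                if (i, j) not in edges and rng.random() < 0.3:
                    edges.add((i, j))
        feats = rng.uniform(0.0, 1.0, size=(m, feature_dim))
        edge_list = (
            np.array(sorted(edges), dtype=np.int64)
            if edges
            else np.zeros((0, 2), dtype=np.int64)
        )
        graphs.append(MolecularGraph(node_features=feats, edge_list=edge_list))
    return graphs
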