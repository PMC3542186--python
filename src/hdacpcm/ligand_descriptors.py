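"""Ligand descriptor blocks: general descriptors (GD) and drug-like index (DLI).

GD is a 32-dimensional physical-property block: van der Waals surface area
partitioned by per-atom Wildman-Crippen logP contribution (10 bins), by
per-atom molar-refractivity contribution (8 bins) and by Gasteiger partial
charge (10 bins), plus whole-molecule logP, molar refractivity, total surface
area and formal-charge sum.

DLI is a 28-dimensional topological block counting rings, links and molecular
frameworks (Murcko-style scaffolds) together with simple graph indices of the
heavy-atom molecular graph.

Both providers operate on the largest covalent fragment of the input SMILES
(salts and mixture components are stripped) and are invariant to the SMILES
writing of a molecule. When the original descriptor values of a study are
available as a table, :func:`load_descriptor_table` ingests them instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .config import (
    DLI_FEATURE_NAMES,
    GD_FEATURE_NAMES,
    PEOE_VSA_BINS,
    SLOGP_VSA_BINS,
    SMR_VSA_BINS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LigandDescriptorBlock",
    "BLOCK_DIMS",
    "compute_gd",
    "compute_dli",
    "compute_block",
    "load_descriptor_table",
]

BLOCK_DIMS = {"GD": 32, "DLI": 28}


@dataclass
class LigandDescriptorBlock:
    """Descriptor matrix for a set of compounds (rows) of one kind."""

    compound_ids: list[str]
    kind: str  # "GD" or "DLI"
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = BLOCK_DIMS[self.kind]
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"{self.kind} block must have {expected} columns, got shape {self.values.shape}"
            )
        if np.isnan(self.values).any():
            raise ValueError(f"{self.kind} block contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids,
                            columns=list(self.feature_names))

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "compound_id"
        df.to_csv(path)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    # keep the largest covalent fragment (salt/mixture stripping)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return mol


def compute_gd(smiles: str) -> np.ndarray:
    """32 general descriptors for one molecule."""
    mol = _mol_from_smiles(smiles)
    slogp = rdMolDescriptors.SlogP_VSA_(mol, bins=list(SLOGP_VSA_BINS))
    smr = rdMolDescriptors.SMR_VSA_(mol, bins=list(SMR_VSA_BINS))
    peoe = rdMolDescriptors.PEOE_VSA_(mol, bins=list(PEOE_VSA_BINS))
    whole = [
        Crippen.MolLogP(mol),
        Crippen.MolMR(mol),
        rdMolDescriptors.CalcLabuteASA(mol),
        float(sum(a.GetFormalCharge() for a in mol.GetAtoms())),
    ]
    vec = np.array([*slogp, *smr, *peoe, *whole], dtype=float)
    if vec.shape != (32,) or not np.isfinite(vec).all():
        raise ValueError(f"GD computation failed for {smiles!r}")
    return vec


def _ring_system_count(mol: Chem.Mol) -> int:
    """Number of fused ring systems (rings sharing an atom are one system)."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    systems: list[set[int]] = []
    for ring in rings:
        merged = ring
        rest = []
        for sys_ in systems:
            if sys_ & merged:
                merged = merged | sys_
            else:
                rest.append(sys_)
        systems = rest + [merged]
    return len(systems)


def compute_dli(smiles: str) -> np.ndarray:
    """28 drug-like index descriptors for one molecule."""
    mol = _mol_from_smiles(smiles)
    n_atoms = mol.GetNumHeavyAtoms()
    n_bonds = mol.GetNumBonds()

    ring_info = mol.GetRingInfo()
    atom_rings = ring_info.AtomRings()
    n_rings = len(atom_rings)
    n_aromatic = rdMolDescriptors.CalcNumAromaticRings(mol)
    largest_ring = max((len(r) for r in atom_rings), default=0)
    ring_atoms = len({a for ring in atom_rings for a in ring})

    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    scaf_atoms = scaffold.GetNumHeavyAtoms()
    scaf_bonds = scaffold.GetNumBonds()
    # linkers are the acyclic part of the framework
    linker_bonds = sum(1 for b in scaffold.GetBonds() if not b.IsInRing())
    side_chain_atoms = n_atoms - scaf_atoms

    rotatable = rdMolDescriptors.CalcNumRotatableBonds(mol)
    rigid = n_bonds - rotatable
    hbd = rdMolDescriptors.CalcNumHBD(mol)
    hba = rdMolDescriptors.CalcNumHBA(mol)
    halogens = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (9, 17, 35, 53))
    hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    sp3_pct = 100.0 * rdMolDescriptors.CalcFractionCSP3(mol)
    chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False))

    if n_atoms > 1:
        dmat = Chem.GetDistanceMatrix(mol)
        ecc = dmat.max(axis=1)
        diameter = float(ecc.max())
        radius = float(ecc.min())
    else:
        diameter = radius = 0.0

    degrees = [a.GetDegree() for a in mol.GetAtoms()]
    deg_counts = [sum(1 for d in degrees if d == k) for k in (1, 2, 3, 4)]
    max_degree = max(degrees, default=0)
    terminal = deg_counts[0]
    branch_points = sum(1 for d in degrees if d >= 3)

    vec = np.array(
        [
            n_atoms, n_bonds, n_rings, n_aromatic, _ring_system_count(mol),
            largest_ring, ring_atoms, scaf_atoms, scaf_bonds, linker_bonds,
            side_chain_atoms, rotatable, rigid, hbd, hba, halogens, hetero,
            sp3_pct, chiral, diameter, radius, terminal, branch_points,
            *deg_counts, max_degree,
        ],
        dtype=float,
    )
    if vec.shape != (28,) or not np.isfinite(vec).all():
        raise ValueError(f"DLI computation failed for {smiles!r}")
    return vec


_COMPUTERS = {"GD": compute_gd, "DLI": compute_dli}
_FEATURE_NAMES = {"GD": GD_FEATURE_NAMES, "DLI": DLI_FEATURE_NAMES}


def compute_block(
    compounds: dict[str, str],
    kind: str = "GD",
) -> LigandDescriptorBlock:
    """Compute a descriptor block for compound_id -> SMILES.

    Molecules whose descriptors cannot be computed are dropped with a logged
    reason; the returned block has no missing values.
    """
    if kind not in _COMPUTERS:
        raise ValueError(f"kind must be one of {sorted(_COMPUTERS)}, got {kind!r}")
    fn = _COMPUTERS[kind]
    ids, rows = [], []
    for cid, smiles in compounds.items():
        try:
            rows.append(fn(smiles))
            ids.append(cid)
        except ValueError as exc:
            logger.warning("dropping compound %s: %s", cid, exc)
    if not rows:
        raise ValueError("no computable molecules in input")
    return LigandDescriptorBlock(ids, kind, np.vstack(rows), _FEATURE_NAMES[kind])


def load_descriptor_table(
    path: str | Path,
    kind: str,
    expected_dim: int | None = None,
) -> LigandDescriptorBlock:
    """Ingest a precomputed ligand descriptor table.

    CSV with a ``compound_id`` column plus exactly ``expected_dim`` numeric
    columns (defaults to the dimensionality of ``kind``). Supports using the
    original descriptor values of a study in place of the built-in providers.
    """
    expected = expected_dim if expected_dim is not None else BLOCK_DIMS[kind]
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise ValueError(f"{path}: missing compound_id column")
    ids = df["compound_id"].astype(str).tolist()
    data = df.drop(columns=["compound_id"])
    if data.shape[1] != expected:
        raise ValueError(
            f"{path}: expected {expected} descriptor columns for {kind}, found {data.shape[1]}"
        )
    try:
        values = data.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric descriptor cell: {exc}") from exc
    if np.isnan(values).any():
        rows, cols = np.where(np.isnan(values))
        raise ValueError(
            f"{path}: missing value at row {ids[rows[0]]!r}, column {data.columns[cols[0]]!r}"
        )
    return LigandDescriptorBlock(ids, kind, values, tuple(data.columns))
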