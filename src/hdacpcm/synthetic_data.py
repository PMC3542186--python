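"""Synthetic proteochemometric datasets with known ground truth.

The generator emulates the statistical structure of a compound-target
activity panel: ``T`` targets and ``L`` compounds described by Gaussian
descriptor blocks, with per-pair pIC50

    pIC50 = intercept + beta_p . p + beta_l . l + p^T W l + eps,

i.e. additive protein and ligand main effects, an optional bilinear
protein x ligand interaction ``W`` and Gaussian noise. Pair coverage is
unbalanced across targets (each target measures a without-replacement sample
of the compounds), mirroring public activity panels where one well-assayed
isoform dominates.

Class-selective compounds can be *planted*: the first protein descriptor is a
class indicator (+1 for class I targets, -1 for class II) and the first
ligand descriptor a selectivity axis; their product enters the response with
weight ``selectivity_gain``. A planted compound gets an extreme coordinate on
the axis (+/- ``planted_marker``), giving it a multi-log-unit potency
separation between the two classes, the signature of a genuinely
class-selective chemotype. The main-effect coefficients of the two marker
dimensions are zero, so planting shifts between-class contrast only.

A second generator emits ideal poly-alanine helix coordinates in PDB format,
the fixture for the geometry descriptor block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    ALPHA_HELIX_OMEGA,
    ALPHA_HELIX_PHI,
    ALPHA_HELIX_PSI,
    IDEAL_BACKBONE,
)
from .dataset_io import InteractionRecord, from_pic50

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_helix_structure",
    "STUB_SMILES",
]

#: Small library of valid structures cycled onto synthetic compounds so the
#: emitted tables remain consumable by SMILES-based tooling.
STUB_SMILES: tuple[str, ...] = (
    "C", "CC", "CCO", "c1ccccc1", "CC(=O)O", "CCN", "c1ccncc1", "C1CCCCC1",
    "CC(C)O", "CCOCC", "CC(=O)NC", "c1ccc2ccccc2c1", "CCS", "C=CC=C",
    "OCC(O)CO", "CC#N", "ClCCCl", "FC(F)F", "c1ccsc1", "CNC",
)


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of a synthetic activity panel.

    Defaults give five targets (two class I, three class II), 200 compounds
    and per-target pair counts proportional to a real unbalanced HDAC panel
    scaled to ~250 pairs. Main effects each contribute unit response
    variance; the background interaction ``w_scale=0.5`` contributes ~0.25
    and the class-selectivity axis ``selectivity_gain=1.0`` a further ~1.
    """

    n_targets: int = 5
    n_compounds: int = 200
    d_protein: int = 5
    d_ligand: int = 32
    pairs_per_target: tuple[int, ...] = (43, 39, 106, 9, 57)
    noise_sd: float = 0.1
    seed: int = 0
    intercept: float = 6.5
    beta_protein: np.ndarray | None = None
    beta_ligand: np.ndarray | None = None
    W: np.ndarray | None = None
    w_scale: float = 0.5
    w_density: float = 0.1
    selectivity_gain: float = 1.0
    planted_marker: float = 4.0
    planted_selectives: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.pairs_per_target) != self.n_targets:
            raise ValueError("pairs_per_target length must equal n_targets")
        if any(k > self.n_compounds for k in self.pairs_per_target):
            raise ValueError("pairs_per_target cannot exceed n_compounds")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for idx, cls in self.planted_selectives:
            if not 0 <= idx < self.n_compounds:
                raise ValueError(f"planted compound index {idx} out of range")
            if cls not in ("I", "II"):
                raise ValueError(f"planted class must be 'I' or 'II', got {cls!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load a configuration from a JSON or YAML mapping."""
        import json

        import yaml

        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        for key in ("pairs_per_target", "planted_selectives"):
            if key in data:
                data[key] = tuple(tuple(v) if isinstance(v, list) else v for v in data[key])
        for key in ("beta_protein", "beta_ligand", "W"):
            if data.get(key) is not None:
                data[key] = np.asarray(data[key], dtype=float)
        return cls(**data)


@dataclass
class SyntheticDataset:
    """Generated panel: descriptor blocks, records and the generating truth."""

    protein_block: pd.DataFrame
    ligand_block: pd.DataFrame
    records: list[InteractionRecord]
    target_classes: dict[str, str]
    config: SyntheticConfig
    beta_protein: np.ndarray = field(repr=False, default=None)
    beta_ligand: np.ndarray = field(repr=False, default=None)
    W: np.ndarray = field(repr=False, default=None)


def _target_classes(n_targets: int) -> list[str]:
    n_class1 = max(1, round(0.4 * n_targets))
    return ["I"] * n_class1 + ["II"] * (n_targets - n_class1)


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Draw a synthetic panel from the configured generating model.

    The same seed always yields bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    T, L = config.n_targets, config.n_compounds
    d_p, d_l = config.d_protein, config.d_ligand

    target_ids = [f"T{i + 1}" for i in range(T)]
    compound_ids = [f"C{i + 1:04d}" for i in range(L)]
    classes = _target_classes(T)

    P = rng.standard_normal((T, d_p))
    Lmat = rng.standard_normal((L, d_l))
    # marker dimensions: protein col 0 = class indicator, ligand col 0 = axis
    P[:, 0] = [1.0 if c == "I" else -1.0 for c in classes]
    for idx, cls in config.planted_selectives:
        Lmat[idx, 0] = config.planted_marker if cls == "I" else -config.planted_marker

    if config.beta_protein is not None:
        beta_p = np.asarray(config.beta_protein, dtype=float)
    else:
        beta_p = rng.standard_normal(d_p) / math.sqrt(max(d_p - 1, 1))
        beta_p[0] = 0.0
    if config.beta_ligand is not None:
        beta_l = np.asarray(config.beta_ligand, dtype=float)
    else:
        beta_l = rng.standard_normal(d_l) / math.sqrt(max(d_l - 1, 1))
        beta_l[0] = 0.0

    if config.W is not None:
        W = np.asarray(config.W, dtype=float)
        if W.shape != (d_p, d_l):
            raise ValueError(f"W must have shape ({d_p}, {d_l})")
    else:
        W = np.zeros((d_p, d_l))
        if config.w_scale > 0:
            mask = rng.random((d_p, d_l)) < config.w_density
            mask[0, 0] = False  # keep the selectivity axis separate
            n_nz = int(mask.sum())
            if n_nz:
                W[mask] = rng.standard_normal(n_nz) * config.w_scale / math.sqrt(n_nz)
        W[0, 0] = config.selectivity_gain

    # Planted (reference) selective compounds are panel-profiled: like known
    # selective inhibitors in the literature, they are assayed against every
    # target. Their pairs count toward the per-target totals.
    planted_idx = [idx for idx, _ in config.planted_selectives]
    records: list[InteractionRecord] = []
    for t_idx, tid in enumerate(target_ids):
        n_pairs = config.pairs_per_target[t_idx]
        if n_pairs < len(planted_idx):
            raise ValueError(
                f"pairs_per_target[{t_idx}]={n_pairs} cannot hold {len(planted_idx)} planted compounds"
            )
        others = np.setdiff1d(np.arange(L), planted_idx)
        sampled = rng.choice(others, size=n_pairs - len(planted_idx), replace=False)
        chosen = np.concatenate([np.array(planted_idx, dtype=int), sampled])
        for c_idx in np.sort(chosen):
            p, l = P[t_idx], Lmat[c_idx]
            eps = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
            pic50 = (
                config.intercept
                + float(beta_p @ p)
                + float(beta_l @ l)
                + float(p @ W @ l)
                + eps
            )
            records.append(
                InteractionRecord(
                    compound_id=compound_ids[c_idx],
                    smiles=STUB_SMILES[c_idx % len(STUB_SMILES)],
                    target_id=tid,
                    ic50=from_pic50(pic50),
                )
            )

    return SyntheticDataset(
        protein_block=pd.DataFrame(P, index=target_ids,
                                   columns=[f"pd{i + 1}" for i in range(d_p)]),
        ligand_block=pd.DataFrame(Lmat, index=compound_ids,
                                  columns=[f"ld{i + 1}" for i in range(d_l)]),
        records=records,
        target_classes=dict(zip(target_ids, classes)),
        config=config,
        beta_protein=beta_p,
        beta_ligand=beta_l,
        W=W,
    )


# ---------------------------------------------------------------------------
# Synthetic helix structures (geometry-descriptor fixture)
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given three predecessors by internal coordinates
    (natural extension reference frame)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * math.cos(angle),
            length * math.sin(angle) * math.cos(dihedral),
            length * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def generate_helix_structure(
    n_residues: int,
    noise_A: float = 0.0,
    seed: int = 0,
    phi: float = ALPHA_HELIX_PHI,
    psi: float = ALPHA_HELIX_PSI,
    omega: float = ALPHA_HELIX_OMEGA,
    path: str | Path | None = None,
) -> str:
    """Build a poly-alanine helix from ideal backbone internal coordinates.

    Returns the structure as PDB-format text (and writes it to ``path`` when
    given). ``noise_A`` adds isotropic Gaussian jitter per coordinate, seeded.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    ib = IDEAL_BACKBONE

    # seed atoms of residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([ib["len_N_CA"], 0.0, 0.0])
    ang = math.radians(ib["ang_N_CA_C"])
    c0 = ca0 + ib["len_CA_C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])

    backbone = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_residues):
        prev = backbone[-1]
        n = _nerf(prev["N"], prev["CA"], prev["C"], ib["len_C_N"], ib["ang_CA_C_N"], psi)
        ca = _nerf(prev["CA"], prev["C"], n, ib["len_N_CA"], ib["ang_C_N_CA"], omega)
        c = _nerf(prev["C"], n, ca, ib["len_CA_C"], ib["ang_N_CA_C"], phi)
        backbone.append({"N": n, "CA": ca, "C": c})

    for i, res in enumerate(backbone):
        # carbonyl O anti to the next amide N about the CA-C bond
        res["O"] = _nerf(res["N"], res["CA"], res["C"],
                         ib["len_C_O"], ib["ang_CA_C_O"], psi - 180.0)
        res["CB"] = _nerf(res["N"], res["C"], res["CA"],
                          ib["len_CA_CB"], ib["ang_C_CA_CB"], ib["dih_CB_improper"])

    rng = np.random.default_rng(seed)
    lines = []
    serial = 1
    for i, res in enumerate(backbone):
        for atom in ("N", "CA", "C", "O", "CB"):
            x, y, z = res[atom] + (rng.normal(0.0, noise_A, 3) if noise_A > 0 else 0.0)
            element = atom[0]
            lines.append(
                f"ATOM  {serial:5d}  {atom:<3s} ALA A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
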