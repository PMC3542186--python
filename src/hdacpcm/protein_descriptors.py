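"""Protein descriptor blocks for proteochemometric models.

Three blocks describe each target of the panel:

* **P0 — sequence similarity**: percent identity of a global (Needleman-
  Wunsch) alignment against a set of reference sequences, BLOSUM62 with
  affine gaps (open 10, extend 0.5, end gaps free — the EMBOSS ``needle``
  defaults). Identity is counted over the full alignment length including
  gap columns. For the HDAC panel the references are the 11 classical
  isoforms, giving an 11-dimensional block.
* **P1 — structure similarity**: pairwise structure-alignment scores are
  *ingested*, not computed; any matrix passing validation (unit
  self-similarity) is accepted. The canonical 5x5 HDAC matrix ships as a
  fixture.
* **P2 — geometry**: mean and sample sd of 15 backbone/side-chain internal
  coordinate classes measured over all residues of a structure, 30 features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.vectors import calc_angle, calc_dihedral

from .config import (
    CHI1_GAMMA_ATOM,
    GEOMETRY_CLASSES,
    GEOMETRY_FEATURE_NAMES,
    PEPTIDE_BOND_MAX_A,
)

__all__ = [
    "SimilarityMatrix",
    "GeometryDescriptorVector",
    "AlignmentStats",
    "global_identity",
    "global_alignment_stats",
    "build_p0",
    "load_similarity_matrix",
    "bundled_p0_matrix",
    "bundled_p1_matrix",
    "compute_geometry_descriptors",
    "build_p2",
]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_STANDARD_RESNAMES = set(CHI1_GAMMA_ATOM) | {"ALA", "GLY"}
_BACKBONE = ("N", "CA", "C", "O")


# ---------------------------------------------------------------------------
# P0: global sequence identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentStats:
    """Summary of one global pairwise alignment."""

    score: float
    identical: int
    alignment_length: int

    @property
    def identity_percent(self) -> float:
        return 100.0 * self.identical / self.alignment_length


def _validate_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - _STANDARD_AA - {"X"}
    if bad:
        raise ValueError(f"{label}: non-amino-acid characters {sorted(bad)}")
    return seq


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # EMBOSS convention: a gap of length L costs gap_open + gap_extend * L,
    # and terminal gaps are free.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.end_gap_score = 0.0
    return aligner


def global_alignment_stats(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentStats:
    """Globally align two protein sequences and report score and identity."""
    seq_a = _validate_sequence(seq_a, "seq_a")
    seq_b = _validate_sequence(seq_b, "seq_b")
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return AlignmentStats(
        score=float(alignment.score),
        identical=int(counts.identities),
        alignment_length=int(alignment.length),
    )


def global_identity(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent identity of the global alignment of two protein sequences.

    Identity = 100 x (identical aligned positions) / (alignment length
    including gap columns).
    """
    return global_alignment_stats(seq_a, seq_b, gap_open, gap_extend).identity_percent


# ---------------------------------------------------------------------------
# Similarity matrices (P0 built or loaded, P1 ingested)
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """A named row x reference matrix of similarity values."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    kind: str = "similarity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match id lists")
        if (self.values < 0).any():
            raise ValueError("similarity values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def row(self, target_id: str) -> np.ndarray:
        try:
            i = self.row_ids.index(target_id)
        except ValueError as exc:
            raise KeyError(f"no similarity row for target {target_id!r}") from exc
        return self.values[i]


def build_p0(
    panel_seqs: dict[str, str],
    reference_seqs: dict[str, str],
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> SimilarityMatrix:
    """Compute the P0 block: percent identity of each panel sequence against
    each reference sequence (5x11 for the HDAC panel vs the 11 classical
    isoforms)."""
    import warnings

    col_ids = list(reference_seqs)
    if len(set(col_ids)) < len(col_ids):  # pragma: no cover - dict keys unique
        warnings.warn("duplicate reference ids; keeping all columns")
    seen_seqs: dict[str, str] = {}
    for rid, seq in reference_seqs.items():
        if seq in seen_seqs:
            warnings.warn(
                f"reference {rid!r} duplicates sequence of {seen_seqs[seq]!r}; both kept"
            )
        else:
            seen_seqs[seq] = rid
    missing = [t for t in panel_seqs if panel_seqs[t] is None]
    if missing:
        raise KeyError(f"missing sequences for panel targets {missing}")
    values = np.array(
        [
            [global_identity(panel_seqs[t], reference_seqs[r], gap_open, gap_extend)
             for r in col_ids]
            for t in panel_seqs
        ]
    )
    return SimilarityMatrix(list(panel_seqs), col_ids, values, kind="P0")


def load_similarity_matrix(
    path: str | Path,
    self_value: float | None = None,
    kind: str = "similarity",
) -> SimilarityMatrix:
    """Load a similarity matrix CSV (header row/column of target ids).

    Where a row id also appears as a column id the entry must equal
    ``self_value`` (1.0 for structure-similarity P1 matrices, 100.0 for
    percent-identity P0 matrices; auto-detected when None) within 1e-9.
    """
    df = pd.read_csv(path, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in similarity matrix {path}: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError(f"missing value in similarity matrix {path}")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    shared = [(i, col_ids.index(r)) for i, r in enumerate(row_ids) if r in col_ids]
    if shared:
        diag = np.array([values[i, j] for i, j in shared])
        if self_value is None:
            for candidate in (1.0, 100.0):
                if np.allclose(diag, candidate, atol=1e-9):
                    self_value = candidate
                    break
        if self_value is None or not np.allclose(diag, self_value, atol=1e-9):
            raise ValueError(
                f"self-similarity violation in {path}: diagonal {diag.tolist()} "
                f"does not match expected self value {self_value}"
            )
    return SimilarityMatrix(row_ids, col_ids, values, kind=kind)


def _bundled(name: str) -> Path:
    return Path(str(resources.files("hdacpcm").joinpath("data", name)))


def bundled_p0_matrix() -> SimilarityMatrix:
    """The canonical HDAC panel P0 block: percent identity of the five
    crystal-structure isoforms against the 11 classical HDACs."""
    return load_similarity_matrix(_bundled("hdac_p0_sequence_identity.csv"),
                                  self_value=100.0, kind="P0")


def bundled_p1_matrix() -> SimilarityMatrix:
    """The canonical HDAC panel P1 block: pairwise structure-alignment
    similarity of the five crystal structures."""
    return load_similarity_matrix(_bundled("hdac_p1_structure_similarity.csv"),
                                  self_value=1.0, kind="P1")


# ---------------------------------------------------------------------------
# P2: geometry descriptors
# ---------------------------------------------------------------------------

@dataclass
class GeometryDescriptorVector:
    """30 geometry features (mean, sample sd of 15 internal-coordinate
    classes) for one structure."""

    target_id: str
    features: np.ndarray
    feature_names: tuple[str, ...] = GEOMETRY_FEATURE_NAMES
    missing_classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (30,):
            raise ValueError(f"geometry vector must have 30 features, got {self.features.shape}")


def _coord(residue, name: str) -> np.ndarray | None:
    if residue is None or name not in residue:
        return None
    return residue[name].get_coord()


def _vec(residue, name: str):
    if residue is None or name not in residue:
        return None
    return residue[name].get_vector()


def _chain_residues(structure, chain_id: str | None):
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ValueError(f"chain {chain_id!r} not found")
    residues = []
    for chain in chains[:1] if chain_id is None else chains:
        for res in chain.get_residues():
            # standard amino acids only; HETATM records carry a non-blank hetflag
            if res.id[0] != " " or res.get_resname() not in _STANDARD_RESNAMES:
                continue
            residues.append(res)
    return residues


def _consecutive(prev, curr) -> bool:
    c = _coord(prev, "C")
    n = _coord(curr, "N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c - n)) <= PEPTIDE_BOND_MAX_A


def compute_geometry_descriptors(
    structure,
    chain: str | None = None,
    target_id: str = "",
) -> GeometryDescriptorVector:
    """Measure the P2 geometry block from a protein structure.

    ``structure`` is a PDB file path or a parsed ``Bio.PDB`` structure. The
    first model is used; by default the first chain. Internal coordinates are
    collected over all residues where the required atoms exist (first/last
    residues lacking phi/psi are simply not instances of those classes), and
    each of the 15 classes is summarised by mean and sample sd. A class with
    no instances yields NaN features and is listed in ``missing_classes``.
    """
    if isinstance(structure, (str, Path)):
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure(target_id or Path(structure).stem, str(structure))

    residues = _chain_residues(structure, chain)

    # longest run of consecutively bonded residues must reach 3
    run = best = 1 if residues else 0
    for i in range(1, len(residues)):
        run = run + 1 if _consecutive(residues[i - 1], residues[i]) else 1
        best = max(best, run)
    if best < 3:
        raise ValueError("insufficient structure: need >= 3 consecutive standard residues")

    samples: dict[str, list[float]] = {cls: [] for cls in GEOMETRY_CLASSES}

    def add_length(cls: str, a, b) -> None:
        if a is not None and b is not None:
            samples[cls].append(float(np.linalg.norm(a - b)))

    def add_angle(cls: str, a, b, c) -> None:
        if a is not None and b is not None and c is not None:
            samples[cls].append(math.degrees(calc_angle(a, b, c)))

    def add_dihedral(cls: str, a, b, c, d) -> None:
        if a is not None and b is not None and c is not None and d is not None:
            samples[cls].append(math.degrees(calc_dihedral(a, b, c, d)))

    for i, res in enumerate(residues):
        prev = residues[i - 1] if i > 0 and _consecutive(residues[i - 1], res) else None
        nxt = residues[i + 1] if i + 1 < len(residues) and _consecutive(res, residues[i + 1]) else None

        n, ca, c, o = (_coord(res, a) for a in _BACKBONE)
        cb = _coord(res, "CB")
        add_length("len_N_CA", n, ca)
        add_length("len_CA_C", ca, c)
        add_length("len_C_O", c, o)
        add_length("len_CA_CB", ca, cb)
        if nxt is not None:
            add_length("len_C_Nnext", c, _coord(nxt, "N"))

        nv, cav, cv = _vec(res, "N"), _vec(res, "CA"), _vec(res, "C")
        ov, cbv = _vec(res, "O"), _vec(res, "CB")
        add_angle("ang_N_CA_C", nv, cav, cv)
        add_angle("ang_CA_C_O", cav, cv, ov)
        add_angle("ang_N_CA_CB", nv, cav, cbv)
        add_angle("ang_C_CA_CB", cv, cav, cbv)
        if nxt is not None:
            add_angle("ang_CA_C_Nnext", cav, cv, _vec(nxt, "N"))
            add_dihedral("dih_psi", nv, cav, cv, _vec(nxt, "N"))
            add_dihedral("dih_omega", cav, cv, _vec(nxt, "N"), _vec(nxt, "CA"))
        if prev is not None:
            add_angle("ang_C_N_CA", _vec(prev, "C"), nv, cav)
            add_dihedral("dih_phi", _vec(prev, "C"), nv, cav, cv)
        gamma = CHI1_GAMMA_ATOM.get(res.get_resname())
        if gamma:
            add_dihedral("dih_chi1", nv, cav, cbv, _vec(res, gamma))

    features = np.empty(30)
    missing: list[str] = []
    for k, cls in enumerate(GEOMETRY_CLASSES):
        vals = np.array(samples[cls], dtype=float)
        if vals.size == 0:
            features[2 * k] = features[2 * k + 1] = np.nan
            missing.append(cls)
        else:
            features[2 * k] = vals.mean()
            features[2 * k + 1] = vals.std(ddof=1) if vals.size > 1 else 0.0
    return GeometryDescriptorVector(target_id=target_id, features=features,
                                    missing_classes=missing)


def build_p2(
    structures: dict[str, str | Path],
    chains: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Geometry block for a panel: one 30-feature row per target."""
    rows = {}
    for tid, path in structures.items():
        chain = (chains or {}).get(tid)
        rows[tid] = compute_geometry_descriptors(path, chain=chain, target_id=tid).features
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(GEOMETRY_FEATURE_NAMES))
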