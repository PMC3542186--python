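"""Design-matrix assembly for proteochemometric models.

A model specification combines one protein block (P0/P1/P2) with one ligand
block (GD/DLI) in one of three modes: the two blocks side by side, the blocks
plus their multiplicative cross-terms, or the cross-terms alone. Enumerating
3 protein blocks x 2 ligand blocks x 3 modes gives the 18 model grid.

Cross-terms are the flattened outer product of the *centered and scaled*
protein and ligand descriptor vectors of a pair (protein-major order); they
model interface complementarity that neither block captures additively.
Scaling statistics are sample-sd based and fit on training pairs only by
default (``fit_rows``), so the test set never leaks into preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import InteractionRecord, Split

__all__ = [
    "ModelSpec",
    "FeatureMatrix",
    "ColumnScaling",
    "center_scale",
    "apply_scaling",
    "make_crossterms",
    "assemble_features",
    "enumerate_model_specs",
]

PROTEIN_BLOCKS = ("P0", "P1", "P2")
LIGAND_BLOCKS = ("GD", "DLI")
MODES = ("blocks_only", "blocks_plus_cross", "cross_only")


@dataclass(frozen=True)
class ModelSpec:
    """One of the 18 descriptor-combination specifications."""

    protein_block: str
    ligand_block: str
    mode: str

    def __post_init__(self) -> None:
        if self.protein_block not in PROTEIN_BLOCKS:
            raise ValueError(f"unknown protein block {self.protein_block!r}")
        if self.ligand_block not in LIGAND_BLOCKS:
            raise ValueError(f"unknown ligand block {self.ligand_block!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def name(self) -> str:
        p, l = self.protein_block, self.ligand_block
        if self.mode == "blocks_only":
            return f"{p}-{l}"
        if self.mode == "blocks_plus_cross":
            return f"{p}-{l}-C"
        return f"C({p},{l})"

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        name = name.strip()
        if name.startswith("C(") and name.endswith(")"):
            p, l = name[2:-1].split(",")
            return cls(p.strip(), l.strip(), "cross_only")
        parts = name.split("-")
        if len(parts) == 3 and parts[2] == "C":
            return cls(parts[0], parts[1], "blocks_plus_cross")
        if len(parts) == 2:
            return cls(parts[0], parts[1], "blocks_only")
        raise ValueError(f"unrecognized model spec name {name!r}")

    def n_features(self, d_protein: int, d_ligand: int) -> int:
        if self.mode == "blocks_only":
            return d_protein + d_ligand
        if self.mode == "blocks_plus_cross":
            return d_protein + d_ligand + d_protein * d_ligand
        return d_protein * d_ligand


def enumerate_model_specs() -> list[ModelSpec]:
    """The full deterministic grid of 18 model specifications."""
    return [
        ModelSpec(p, l, mode)
        for mode in MODES
        for p in PROTEIN_BLOCKS
        for l in LIGAND_BLOCKS
    ]


@dataclass
class ColumnScaling:
    """Per-column mean/sd fitted on a row subset; constant columns are
    centered only and flagged."""

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean mask of columns with sd < 1e-12


def center_scale(
    block: np.ndarray,
    fit_rows: np.ndarray | list[int] | None = None,
) -> tuple[np.ndarray, ColumnScaling]:
    """Center and unit-variance scale columns using fit-row statistics.

    Columns with sd < 1e-12 on the fit rows are centered but not divided,
    keeping the column (and the dimension bookkeeping) intact.
    """
    block = np.asarray(block, dtype=float)
    if fit_rows is None:
        fit = block
    else:
        fit_rows = np.asarray(fit_rows)
        fit = block[fit_rows.astype(int)] if fit_rows.size else block[:0]
    if fit.shape[0] == 0:
        raise ValueError("empty fit set")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=1) if fit.shape[0] > 1 else np.zeros(block.shape[1])
    constant = sd < 1e-12
    scaling = ColumnScaling(mean=mean, sd=np.where(constant, 1.0, sd), constant=constant)
    return apply_scaling(block, scaling), scaling


def apply_scaling(block: np.ndarray, scaling: ColumnScaling) -> np.ndarray:
    """Apply stored column statistics to (possibly new) rows."""
    return (np.asarray(block, dtype=float) - scaling.mean) / scaling.sd


def make_crossterms(protein_vec: np.ndarray, ligand_vec: np.ndarray) -> np.ndarray:
    """Flattened outer product, protein-major: element i*d_l + j = p_i * l_j.

    Inputs are expected to be already centered/scaled.
    """
    p = np.asarray(protein_vec, dtype=float).ravel()
    l = np.asarray(ligand_vec, dtype=float).ravel()
    return np.outer(p, l).ravel()


@dataclass
class FeatureMatrix:
    """Pair-level design matrix with named block slices and the scaling
    needed to featurize new pairs."""

    pair_index: list[tuple[str, str]]  # (compound_id, target_id)
    values: np.ndarray
    block_slices: dict[str, slice]
    feature_names: list[str]
    spec: ModelSpec
    protein_scaling: ColumnScaling | None = None
    ligand_scaling: ColumnScaling | None = None
    train_mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.pair_index, names=["compound_id", "target_id"])
        return pd.DataFrame(self.values, index=idx, columns=self.feature_names)


def _row_for(frame: pd.DataFrame, key: str, what: str, pair: tuple[str, str]) -> np.ndarray:
    try:
        return frame.loc[key].to_numpy(dtype=float)
    except KeyError as exc:
        raise KeyError(f"missing {what} descriptor row for pair {pair}") from exc


def assemble_features(
    spec: ModelSpec,
    protein_block: pd.DataFrame,
    ligand_block: pd.DataFrame,
    pairs: list[InteractionRecord],
    fit_on: str = "train",
) -> FeatureMatrix:
    """Build the pair-level design matrix for a model specification.

    ``protein_block`` is indexed by target_id, ``ligand_block`` by
    compound_id; the target's descriptor row is repeated across its pairs.
    Both blocks are centered/scaled with statistics fit on the training pairs
    (``fit_on="train"``; ``"all"`` reproduces preprocessing fitted on every
    pair), cross-terms are formed from the scaled blocks and are not re-scaled.
    """
    if fit_on not in ("train", "all"):
        raise ValueError(f"fit_on must be 'train' or 'all', got {fit_on!r}")

    pair_index = [(r.compound_id, r.target_id) for r in pairs]
    p_raw = np.vstack([_row_for(protein_block, t, "protein", (c, t)) for c, t in pair_index])
    l_raw = np.vstack([_row_for(ligand_block, c, "ligand", (c, t)) for c, t in pair_index])
    if np.isnan(p_raw).any() or np.isnan(l_raw).any():
        raise ValueError("descriptor blocks contain missing values")

    train_mask = np.array([r.split is Split.train for r in pairs])
    if fit_on == "all" or not train_mask.any():
        fit_rows = np.arange(len(pairs))
    else:
        fit_rows = np.flatnonzero(train_mask)

    p_scaled, p_scaling = center_scale(p_raw, fit_rows)
    l_scaled, l_scaling = center_scale(l_raw, fit_rows)

    d_p, d_l = p_scaled.shape[1], l_scaled.shape[1]
    p_names = [f"p:{c}" for c in protein_block.columns]
    l_names = [f"l:{c}" for c in ligand_block.columns]
    cross_names = [f"x:{pc}*{lc}" for pc in protein_block.columns for lc in ligand_block.columns]

    sections: list[np.ndarray] = []
    names: list[str] = []
    block_slices: dict[str, slice] = {}
    offset = 0

    def add(name: str, mat: np.ndarray, cols: list[str]) -> None:
        nonlocal offset
        sections.append(mat)
        names.extend(cols)
        block_slices[name] = slice(offset, offset + mat.shape[1])
        offset += mat.shape[1]

    if spec.mode in ("blocks_only", "blocks_plus_cross"):
        add("protein", p_scaled, p_names)
        add("ligand", l_scaled, l_names)
    if spec.mode in ("blocks_plus_cross", "cross_only"):
        cross = np.einsum("ni,nj->nij", p_scaled, l_scaled).reshape(len(pairs), d_p * d_l)
        add("cross", cross, cross_names)

    values = np.hstack(sections)
    assert values.shape[1] == spec.n_features(d_p, d_l)
    return FeatureMatrix(
        pair_index=pair_index,
        values=values,
        block_slices=block_slices,
        feature_names=names,
        spec=spec,
        protein_scaling=p_scaling,
        ligand_scaling=l_scaling,
        train_mask=train_mask,
    )
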