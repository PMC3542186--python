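"""End-to-end conveniences: fit one model on a dataset, or rerun the full
18-model descriptor-combination grid.

The kernel width defaults to the median pairwise training distance (the
standard heuristic for distance kernels) unless explicit Puk parameters are
given, so the same workflow is usable across design matrices whose
dimensionality ranges from tens to hundreds of columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import InteractionRecord, reset_split, scale_response, stratified_split
from .feature_assembly import FeatureMatrix, ModelSpec, assemble_features, enumerate_model_specs
from .pcm_model import (
    ModelMetrics,
    PukParams,
    SVRParams,
    TrainedPCMModel,
    evaluate_model,
    median_heuristic_sigma,
)
from .synthetic_data import SyntheticDataset

__all__ = [
    "fit_pcm",
    "run_model_grid",
    "fit_synthetic",
    "fit_final",
    "DEFAULT_SVR",
    "KERNEL_WIDTH_MULTIPLIER",
]

#: Workflow-level SVR defaults. PCM responses are dominated by smooth
#: low-order structure (additive block effects plus bilinear cross-terms), so
#: the workflows run the Puk kernel in a wide, near-linear regime: the width
#: is a large multiple of the median pairwise training distance, and a large
#: cost keeps the epsilon-insensitive fit tight on standardized responses.
DEFAULT_SVR = SVRParams(cost=1000.0, epsilon_tube=0.001)
KERNEL_WIDTH_MULTIPLIER = 16.0


@dataclass
class PCMFit:
    """A trained model bundled with its feature matrix and metrics."""

    model: TrainedPCMModel
    features: FeatureMatrix
    metrics: ModelMetrics
    response_scaling: object


def fit_pcm(
    spec: ModelSpec | str,
    protein_block: pd.DataFrame,
    ligand_block: pd.DataFrame,
    records: list[InteractionRecord],
    puk: PukParams | None = None,
    svr: SVRParams = DEFAULT_SVR,
    omega: float = 1.0,
    cv_folds: int = 10,
    seed: int = 0,
    fit_on: str = "train",
) -> PCMFit:
    """Assemble features for one model spec, train and validate.

    Records must already carry train/test split labels and scaled responses
    (``stratified_split`` + ``scale_response``). When ``puk`` is None the
    kernel width is the median pairwise distance of the training rows.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    features = assemble_features(spec, protein_block, ligand_block, records, fit_on=fit_on)
    y = np.array([r.y_scaled for r in records])
    if np.isnan(y).any():
        raise ValueError("records lack scaled responses; call scale_response first")
    if puk is None:
        fit_rows = features.values[features.train_mask] if features.train_mask.any() else features.values
        sigma = KERNEL_WIDTH_MULTIPLIER * median_heuristic_sigma(fit_rows, seed=seed)
        puk = PukParams(omega=omega, sigma=sigma)
    model, metrics = evaluate_model(features, y, puk, svr, cv_folds=cv_folds, seed=seed)
    return PCMFit(model=model, features=features, metrics=metrics, response_scaling=None)


def run_model_grid(
    protein_blocks: dict[str, pd.DataFrame],
    ligand_blocks: dict[str, pd.DataFrame],
    records: list[InteractionRecord],
    puk: PukParams | None = None,
    svr: SVRParams = DEFAULT_SVR,
    cv_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Train and validate every descriptor combination of the 18-model grid.

    ``protein_blocks`` maps block names ("P0"/"P1"/"P2") to raw descriptor
    frames indexed by target id, ``ligand_blocks`` likewise for "GD"/"DLI".
    Returns one row per model (index = model name) with columns
    ``R2, Q2_cv, Q2_test, n_features``, mirroring a published model-grid
    layout.
    """
    rows = {}
    for spec in enumerate_model_specs():
        if spec.protein_block not in protein_blocks or spec.ligand_block not in ligand_blocks:
            continue
        fit = fit_pcm(
            spec,
            protein_blocks[spec.protein_block],
            ligand_blocks[spec.ligand_block],
            records,
            puk=puk,
            svr=svr,
            cv_folds=cv_folds,
            seed=seed,
        )
        rows[spec.name] = {
            "R2": fit.metrics.r2_train,
            "Q2_cv": fit.metrics.q2_cv,
            "Q2_test": fit.metrics.q2_test,
            "n_features": fit.features.values.shape[1],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def fit_synthetic(
    dataset: SyntheticDataset,
    mode: str = "blocks_plus_cross",
    fraction_train: float = 0.65,
    svr: SVRParams = DEFAULT_SVR,
    puk: PukParams | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> PCMFit:
    """Split, scale and fit one model on a synthetic dataset.

    Synthetic panels carry a single protein and a single ligand block, so the
    model spec reduces to the combination mode; the protein block is treated
    as "P1" and the ligand block as "GD" for naming purposes.
    """
    records = dataset.records
    reset_split(records)
    stratified_split(records, fraction_train=fraction_train, seed=seed)
    scaling = scale_response(records, fit_on="train")
    fit = fit_pcm(
        ModelSpec("P1", "GD", mode),
        dataset.protein_block,
        dataset.ligand_block,
        records,
        puk=puk,
        svr=svr,
        cv_folds=cv_folds,
        seed=seed,
    )
    fit.model.response_scaling = scaling
    fit.response_scaling = scaling
    return fit


def fit_final(
    dataset: SyntheticDataset,
    mode: str = "blocks_plus_cross",
    svr: SVRParams = DEFAULT_SVR,
    puk: PukParams | None = None,
    seed: int = 0,
) -> TrainedPCMModel:
    """Fit the deployment model on *all* pairs of a synthetic dataset.

    After a model family is validated on held-out data, the model actually
    used for screening is refit on the full dataset; this returns that model
    (with response scaling attached), ready for :func:`~hdacpcm.predict_profile`.
    """
    from .pcm_model import train_svr

    records = dataset.records
    reset_split(records)
    scaling = scale_response(records, fit_on="all")
    features = assemble_features(
        ModelSpec("P1", "GD", mode),
        dataset.protein_block,
        dataset.ligand_block,
        records,
        fit_on="all",
    )
    y = np.array([r.y_scaled for r in records])
    if puk is None:
        sigma = KERNEL_WIDTH_MULTIPLIER * median_heuristic_sigma(features.values, seed=seed)
        puk = PukParams(omega=1.0, sigma=sigma)
    model = train_svr(features, y, puk, svr, response_scaling=scaling, seed=seed)
    return model
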