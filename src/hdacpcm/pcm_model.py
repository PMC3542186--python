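"""Pearson-VII-kernel support vector regression and its validation metrics.

The kernel is the Pearson VII universal function ("Puk"),

    K(x, y) = 1 / [ 1 + ( 2 * ||x - y|| * sqrt(2^(1/omega) - 1) / sigma )^2 ]^omega,

a positive-definite distance kernel whose tailing factor ``omega``
interpolates between Lorentzian (omega = 1) and Gaussian (omega -> inf)
shapes, with width ``sigma``. The epsilon-insensitive SVR dual problem is
solved by libsvm (via scikit-learn) on a precomputed Gram matrix, which keeps
training deterministic for fixed inputs and parameters.

Predictive ability is summarised by PRESS-based Q² statistics:

    Q² = 1 - sum (y_obs - y_pred)² / sum (y_obs - y_ref_mean)²,

where the reference mean is the training mean (Q²_test, R²_train) or the
per-fold training mean pooled across folds (Q²_cv).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .feature_assembly import ColumnScaling, FeatureMatrix, ModelSpec

__all__ = [
    "PukParams",
    "SVRParams",
    "TrainedPCMModel",
    "ModelMetrics",
    "puk_kernel",
    "gram_matrix",
    "cross_gram",
    "median_heuristic_sigma",
    "train_svr",
    "predict",
    "q_squared",
    "cross_validate",
    "evaluate_model",
]


@dataclass(frozen=True)
class PukParams:
    """Pearson VII kernel parameters: tailing factor omega, width sigma."""

    omega: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.sigma <= 0:
            raise ValueError("omega and sigma must be positive")

    @property
    def _scale(self) -> float:
        # 2 * sqrt(2^(1/omega) - 1) / sigma, precombined distance multiplier
        return 2.0 * np.sqrt(2.0 ** (1.0 / self.omega) - 1.0) / self.sigma


@dataclass(frozen=True)
class SVRParams:
    """Epsilon-insensitive SVR parameters."""

    cost: float = 1.0
    epsilon_tube: float = 0.001
    tolerance: float = 1e-4
    max_iter: int = 2_000_000

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.epsilon_tube < 0:
            raise ValueError("epsilon_tube must be non-negative")


def puk_kernel(x: np.ndarray, y: np.ndarray, params: PukParams = PukParams()) -> float:
    """Pearson VII kernel between two feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    dist = float(np.linalg.norm(x - y))
    return float((1.0 + (dist * params._scale) ** 2) ** (-params.omega))


def cross_gram(
    X: np.ndarray, Y: np.ndarray, params: PukParams = PukParams()
) -> np.ndarray:
    """Kernel matrix between the rows of two feature matrices."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    d = euclidean_distances(X, Y)
    return (1.0 + (d * params._scale) ** 2) ** (-params.omega)


def gram_matrix(X: np.ndarray, params: PukParams = PukParams()) -> np.ndarray:
    """Symmetric unit-diagonal kernel matrix of a feature matrix."""
    K = cross_gram(X, X, params)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def median_heuristic_sigma(X: np.ndarray, max_rows: int = 500, seed: int = 0) -> float:
    """Median pairwise Euclidean distance, the standard width heuristic for
    distance kernels. Rows are subsampled beyond ``max_rows``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], max_rows, replace=False)]
    d = euclidean_distances(X, X)
    vals = d[np.triu_indices_from(d, k=1)]
    med = float(np.median(vals)) if vals.size else 1.0
    return med if med > 0 else 1.0


@dataclass
class TrainedPCMModel:
    """A fitted Puk-kernel SVR together with everything needed to featurize
    and predict new compound-target pairs."""

    puk: PukParams
    svr: SVRParams
    support_vectors: np.ndarray
    dual_coefficients: np.ndarray
    bias: float
    spec: ModelSpec | None = None
    protein_scaling: ColumnScaling | None = None
    ligand_scaling: ColumnScaling | None = None
    response_scaling: "ResponseScaling | None" = None  # noqa: F821 - dataset_io type
    n_train: int = 0
    data_hash: str = ""
    seed: int | None = None

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz archive (JSON metadata + arrays)."""
        meta = {
            "puk": {"omega": self.puk.omega, "sigma": self.puk.sigma},
            "svr": {"cost": self.svr.cost, "epsilon_tube": self.svr.epsilon_tube,
                    "tolerance": self.svr.tolerance},
            "bias": self.bias,
            "spec": self.spec.name if self.spec else None,
            "n_train": self.n_train,
            "data_hash": self.data_hash,
            "seed": self.seed,
            "response_scaling": (
                {"mean": self.response_scaling.mean, "sd": self.response_scaling.sd}
                if self.response_scaling else None
            ),
        }
        arrays = {
            "support_vectors": self.support_vectors,
            "dual_coefficients": self.dual_coefficients,
            "meta": np.array(json.dumps(meta)),
        }
        for label, scaling in (("protein", self.protein_scaling),
                               ("ligand", self.ligand_scaling)):
            if scaling is not None:
                arrays[f"{label}_mean"] = scaling.mean
                arrays[f"{label}_sd"] = scaling.sd
                arrays[f"{label}_constant"] = scaling.constant
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPCMModel":
        from .dataset_io import ResponseScaling

        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            scalings = {}
            for label in ("protein", "ligand"):
                if f"{label}_mean" in archive:
                    scalings[label] = ColumnScaling(
                        mean=archive[f"{label}_mean"],
                        sd=archive[f"{label}_sd"],
                        constant=archive[f"{label}_constant"],
                    )
            return cls(
                puk=PukParams(**meta["puk"]),
                svr=SVRParams(**meta["svr"]),
                support_vectors=archive["support_vectors"],
                dual_coefficients=archive["dual_coefficients"],
                bias=float(meta["bias"]),
                spec=ModelSpec.from_name(meta["spec"]) if meta["spec"] else None,
                protein_scaling=scalings.get("protein"),
                ligand_scaling=scalings.get("ligand"),
                response_scaling=(
                    ResponseScaling(**meta["response_scaling"])
                    if meta["response_scaling"] else None
                ),
                n_train=int(meta["n_train"]),
                data_hash=str(meta["data_hash"]),
                seed=meta["seed"],
            )


@dataclass
class ModelMetrics:
    """Goodness-of-fit and predictive-ability summary of one model."""

    r2_train: float
    q2_cv: float
    q2_test: float
    n_train: int
    n_test: int
    fold_assignment_seed: int = 0
    spec_name: str = ""


def _as_xy(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    return features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)


def train_svr(
    features: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    puk: PukParams = PukParams(),
    svr: SVRParams = SVRParams(),
    response_scaling=None,
    seed: int | None = None,
) -> TrainedPCMModel:
    """Fit epsilon-insensitive SVR in the Puk-kernel feature space.

    When ``features`` is a :class:`FeatureMatrix` with training pairs marked,
    only those rows are used (and the block scalings travel with the model);
    a bare array uses every row. Training is deterministic for fixed inputs.
    """
    y = np.asarray(y, dtype=float).ravel()
    if isinstance(features, FeatureMatrix) and features.train_mask.any():
        X = features.values[features.train_mask]
        y = y[features.train_mask] if y.shape[0] == features.n_pairs else y
    else:
        X = _as_xy(features)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"feature/response length mismatch: {X.shape[0]} vs {y.shape[0]}")
    if X.shape[0] < 2:
        raise ValueError("need at least two training pairs")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in features or responses")

    K = gram_matrix(X, puk)
    est = SVR(kernel="precomputed", C=svr.cost, epsilon=svr.epsilon_tube,
              tol=svr.tolerance, max_iter=svr.max_iter)
    est.fit(K, y)
    if est.fit_status_ != 0:
        raise RuntimeError(
            f"SVR solver did not converge within {svr.max_iter} iterations "
            f"(n={X.shape[0]}, C={svr.cost}, sigma={puk.sigma})"
        )
    support = est.support_
    model = TrainedPCMModel(
        puk=puk,
        svr=svr,
        support_vectors=X[support],
        dual_coefficients=est.dual_coef_.ravel().copy(),
        bias=float(est.intercept_[0]),
        spec=features.spec if isinstance(features, FeatureMatrix) else None,
        protein_scaling=getattr(features, "protein_scaling", None),
        ligand_scaling=getattr(features, "ligand_scaling", None),
        response_scaling=response_scaling,
        n_train=X.shape[0],
        data_hash=hashlib.sha256(np.ascontiguousarray(X).tobytes() + y.tobytes()).hexdigest()[:16],
        seed=seed,
    )
    return model


def predict(
    model: TrainedPCMModel,
    features: FeatureMatrix | np.ndarray,
    return_pic50: bool = False,
) -> np.ndarray:
    """Predict scaled responses (or pIC50 with ``return_pic50``) for rows of
    an assembled feature matrix."""
    X = _as_xy(features)
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_features:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs model {model.n_features}")
    if model.dual_coefficients.size == 0:
        yhat = np.full(X.shape[0], model.bias)
    else:
        K = cross_gram(X, model.support_vectors, model.puk)
        yhat = K @ model.dual_coefficients + model.bias
    if return_pic50:
        if model.response_scaling is None:
            raise ValueError("model has no response scaling; cannot return pIC50")
        yhat = np.asarray(model.response_scaling.inverse(yhat))
    return yhat


def q_squared(y_obs: np.ndarray, y_pred: np.ndarray, y_ref_mean: float) -> float:
    """PRESS-based predictive ability: 1 - RSS / TSS about a reference mean.

    The reference mean must come from the data the model was trained on (the
    training set for Q²_test, the fold-training set for Q²_cv), never from the
    evaluated responses themselves.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape or y_obs.size < 2:
        raise ValueError("y_obs and y_pred must have equal length >= 2")
    tss = float(np.sum((y_obs - y_ref_mean) ** 2))
    if tss <= 0:
        raise ValueError("degenerate Q²: zero total sum of squares about the reference mean")
    rss = float(np.sum((y_obs - y_pred) ** 2))
    return 1.0 - rss / tss


def cross_validate(
    features: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    puk: PukParams = PukParams(),
    svr: SVRParams = SVRParams(),
    k: int = 10,
    seed: int = 0,
) -> float:
    """k-fold cross-validated Q².

    Pairs are assigned to folds at random (pair level) by ``seed``; each fold
    is predicted by a model trained on the remaining folds, and Q²_cv pools
    all out-of-fold residuals, each referenced to its fold-training mean.
    """
    X = _as_xy(features)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rss = 0.0
    tss = 0.0
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        fold_model = train_svr(X[train_idx], y[train_idx], puk, svr)
        yhat = predict(fold_model, X[test_idx])
        fold_mean = float(y[train_idx].mean())
        rss += float(np.sum((y[test_idx] - yhat) ** 2))
        tss += float(np.sum((y[test_idx] - fold_mean) ** 2))
    if tss <= 0:
        raise ValueError("degenerate Q²_cv: zero total sum of squares")
    return 1.0 - rss / tss


def evaluate_model(
    features: FeatureMatrix,
    y: np.ndarray,
    puk: PukParams = PukParams(),
    svr: SVRParams = SVRParams(),
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[TrainedPCMModel, ModelMetrics]:
    """Train on the training pairs and report R²_train, Q²_cv and Q²_test."""
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != features.n_pairs:
        raise ValueError("y must align with the feature matrix pairs")
    train = features.train_mask
    if not train.any():
        raise ValueError("feature matrix has no training pairs marked")
    test = ~train
    X_train, y_train = features.values[train], y[train]
    X_test, y_test = features.values[test], y[test]

    model = train_svr(features, y, puk, svr, seed=seed)
    train_mean = float(y_train.mean())
    r2_train = q_squared(y_train, predict(model, X_train), train_mean)
    folds = min(cv_folds, X_train.shape[0])
    q2_cv = cross_validate(X_train, y_train, puk, svr, k=folds, seed=seed)
    q2_test = (
        q_squared(y_test, predict(model, X_test), train_mean)
        if y_test.size >= 2 else float("nan")
    )
    metrics = ModelMetrics(
        r2_train=r2_train,
        q2_cv=q2_cv,
        q2_test=q2_test,
        n_train=int(train.sum()),
        n_test=int(test.sum()),
        fold_assignment_seed=seed,
        spec_name=features.spec.name if features.spec else "",
    )
    return model, metrics
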