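"""Panel-wide affinity profiling and selectivity calling.

A trained PCM model predicts one scaled affinity per panel target for a
compound; the profile is then classified by a threshold rule into pan,
class-I-selective, class-II-selective, isoform-selective, inactive or mixed.
Predictions are on the centered/scaled pIC50 scale, so the default activity
threshold is 0 (above-average predicted affinity counts as active).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_assembly import apply_scaling, make_crossterms
from .pcm_model import TrainedPCMModel, predict

__all__ = [
    "SelectivityProfile",
    "predict_profile",
    "call_selectivity",
    "screen_compounds",
    "external_validation_report",
    "report_from_predictions",
    "bundled_ten_inhibitor_table",
    "HDAC_CLASS_MAP",
]

#: Major-class membership of the five-isoform HDAC panel.
HDAC_CLASS_MAP: dict[str, str] = {
    "HDAC2": "I",
    "HDAC8": "I",
    "HDAC4": "II",
    "HDAC7": "II",
    "HDAC6": "II",
}


@dataclass
class SelectivityProfile:
    """Per-target predicted scaled affinities and the resulting call."""

    compound_id: str
    per_target_pred: dict[str, float]
    call: str
    activity_threshold: float = 0.0
    margin: float = 0.1
    label: str | None = None
    agree: bool | None = None


def predict_profile(
    model: TrainedPCMModel,
    ligand_vector: np.ndarray,
    panel_block: pd.DataFrame,
) -> dict[str, float]:
    """Predict the scaled affinity of one compound against every panel target.

    ``ligand_vector`` is the compound's raw (unscaled) ligand descriptor
    vector; ``panel_block`` holds the raw protein descriptor rows indexed by
    target id. Rows are featurized with the scalings stored in the model and
    combined per the model's specification mode.
    """
    if model.spec is None or model.protein_scaling is None or model.ligand_scaling is None:
        raise ValueError("model lacks the spec/scaling information needed for profiling")
    l_raw = np.asarray(ligand_vector, dtype=float).ravel()
    if np.isnan(l_raw).any() or panel_block.isna().any().any():
        raise ValueError("missing descriptor values for profile prediction")
    l_scaled = apply_scaling(l_raw[None, :], model.ligand_scaling)[0]
    rows = []
    targets = list(panel_block.index)
    for tid in targets:
        p_scaled = apply_scaling(
            panel_block.loc[tid].to_numpy(dtype=float)[None, :], model.protein_scaling
        )[0]
        parts = []
        if model.spec.mode in ("blocks_only", "blocks_plus_cross"):
            parts.extend([p_scaled, l_scaled])
        if model.spec.mode in ("blocks_plus_cross", "cross_only"):
            parts.append(make_crossterms(p_scaled, l_scaled))
        rows.append(np.concatenate(parts))
    preds = predict(model, np.vstack(rows))
    return {tid: float(v) for tid, v in zip(targets, preds)}


def call_selectivity(
    profile: dict[str, float],
    class_map: dict[str, str],
    threshold: float = 0.0,
    margin: float = 0.1,
    strict: bool = False,
) -> str:
    """Classify a per-target prediction profile.

    A target is active when its prediction exceeds ``threshold``. The rule:
    no target active -> ``inactive``; all active -> ``pan``; exactly one
    active -> ``isoform_selective(<target>)``; the active set equal to one
    full major class -> ``class_I_selective``/``class_II_selective``;
    anything else -> ``mixed``. With ``strict=True`` a selective or pan call
    additionally requires min(active) - max(inactive) > ``margin`` (pan is
    exempt, having no inactive targets).
    """
    if not profile:
        raise ValueError("empty prediction profile")
    missing = set(profile) - set(class_map)
    if missing:
        raise ValueError(f"targets without class assignment: {sorted(missing)}")
    targets = sorted(profile)
    active = {t for t in targets if profile[t] > threshold}
    inactive = set(targets) - active

    if strict and active and inactive:
        separation = min(profile[t] for t in active) - max(profile[t] for t in inactive)
        if separation <= margin:
            return "mixed"

    if not active:
        return "inactive"
    if not inactive:
        return "pan"
    if len(active) == 1:
        return f"isoform_selective({next(iter(active))})"
    for cls in ("I", "II"):
        members = {t for t in targets if class_map[t] == cls}
        if members and active == members:
            return f"class_{cls}_selective"
    return "mixed"


def _consistent(call: str, label: str, class_map: dict[str, str]) -> bool:
    """A call is label-consistent if it matches the label's class directly or
    names a single isoform belonging to the labeled class."""
    if label == "pan":
        return call == "pan"
    cls = label.removeprefix("class_")
    if call == f"class_{cls}_selective":
        return True
    if call.startswith("isoform_selective("):
        target = call[len("isoform_selective("):-1]
        return class_map.get(target) == cls
    return False


def screen_compounds(
    model: TrainedPCMModel,
    ligand_block: pd.DataFrame,
    panel_block: pd.DataFrame,
    class_map: dict[str, str],
    labels: dict[str, str] | None = None,
    threshold: float = 0.0,
    margin: float = 0.1,
    strict: bool = False,
) -> list[SelectivityProfile]:
    """Profile every compound of a raw ligand descriptor block and call its
    selectivity; attach label agreement when known labels are supplied."""
    profiles = []
    for cid in ligand_block.index:
        preds = predict_profile(model, ligand_block.loc[cid].to_numpy(dtype=float), panel_block)
        call = call_selectivity(preds, class_map, threshold, margin, strict)
        label = (labels or {}).get(str(cid))
        profiles.append(
            SelectivityProfile(
                compound_id=str(cid),
                per_target_pred=preds,
                call=call,
                activity_threshold=threshold,
                margin=margin,
                label=label,
                agree=_consistent(call, label, class_map) if label else None,
            )
        )
    return profiles


def report_from_predictions(
    predictions: pd.DataFrame,
    class_map: dict[str, str],
    labels: dict[str, str] | None = None,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Build a selectivity report from an already-predicted profile table
    (rows = compounds, columns = targets)."""
    rows = []
    for cid in predictions.index:
        profile = {t: float(predictions.loc[cid, t]) for t in predictions.columns}
        call = call_selectivity(profile, class_map, threshold)
        label = (labels or {}).get(str(cid))
        rows.append(
            {
                "compound_id": str(cid),
                **{f"pred_{t}": profile[t] for t in predictions.columns},
                "call": call,
                "label": label,
                "agree": _consistent(call, label, class_map) if label else None,
            }
        )
    return pd.DataFrame(rows).set_index("compound_id")


def external_validation_report(
    model: TrainedPCMModel,
    ligand_block: pd.DataFrame,
    labels: dict[str, str],
    panel_block: pd.DataFrame,
    class_map: dict[str, str],
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Predict profiles for externally labeled compounds and summarise
    agreement; the ``agreement`` fraction is stored in ``df.attrs``."""
    profiles = screen_compounds(model, ligand_block, panel_block, class_map,
                                labels=labels, threshold=threshold)
    targets = list(panel_block.index)
    df = pd.DataFrame(
        [
            {
                "compound_id": p.compound_id,
                **{f"pred_{t}": p.per_target_pred[t] for t in targets},
                "call": p.call,
                "label": p.label,
                "agree": p.agree,
            }
            for p in profiles
        ]
    ).set_index("compound_id")
    labeled = df[df["label"].notna()]
    df.attrs["agreement"] = float(labeled["agree"].mean()) if len(labeled) else float("nan")
    return df


def bundled_ten_inhibitor_table() -> tuple[pd.DataFrame, dict[str, str]]:
    """The published external-validation fixture: predicted scaled affinities
    of ten known HDAC inhibitors across the five-isoform panel, with their
    reported pan/class-I/class-II labels."""
    path = Path(str(resources.files("hdacpcm").joinpath("data", "ten_inhibitor_predictions.csv")))
    df = pd.read_csv(path, index_col="compound_id")
    labels = df["label"].to_dict()
    return df.drop(columns=["label"]), labels
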