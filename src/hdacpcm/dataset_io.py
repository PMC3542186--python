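"""Activity-data handling for proteochemometric modeling.

Loads compound-target IC50 tables, converts potencies to pIC50, performs the
per-target stratified train/test split and centers/scales the response.

Conventions
-----------
* pIC50 is the negative base-10 logarithm of the molar IC50; with IC50 given
  in nM this is ``9 - log10(ic50_nm)`` (1 uM -> 6.0, 1 nM -> 9.0).
* All standard deviations are sample (n-1) standard deviations.
* The stratified split assigns ``floor(fraction_train * n)`` pairs of each
  target stratum to the training set.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

__all__ = [
    "HdacClass",
    "TargetInfo",
    "InteractionRecord",
    "SplitSummary",
    "RejectionTally",
    "ResponseScaling",
    "HDAC_PANEL",
    "load_panel",
    "load_activities",
    "to_pic50",
    "from_pic50",
    "stratified_split",
    "scale_response",
    "write_activities",
]


class HdacClass(str, enum.Enum):
    """Zinc-dependent ("classical") HDAC class."""

    I = "I"
    IIa = "IIa"
    IIb = "IIb"
    IV = "IV"

    @property
    def major(self) -> str:
        """Collapse IIa/IIb into the major class label used for selectivity."""
        return "II" if self in (HdacClass.IIa, HdacClass.IIb) else self.value


@dataclass(frozen=True)
class TargetInfo:
    """One protein target of the modeled panel."""

    target_id: str
    hdac_class: HdacClass
    pdb_id: str | None = None
    sequence: str | None = None


#: The five crystal-structure HDAC isoforms modeled throughout the package.
HDAC_PANEL: tuple[TargetInfo, ...] = (
    TargetInfo("HDAC2", HdacClass.I, "3MAX"),
    TargetInfo("HDAC4", HdacClass.IIa, "2VQJ"),
    TargetInfo("HDAC6", HdacClass.IIb, "3C5K"),
    TargetInfo("HDAC7", HdacClass.IIa, "3C0Z"),
    TargetInfo("HDAC8", HdacClass.I, "1T69"),
)


class Split(str, enum.Enum):
    train = "train"
    test = "test"
    unassigned = "unassigned"


@dataclass
class InteractionRecord:
    """One compound-target activity measurement."""

    compound_id: str
    smiles: str
    target_id: str
    ic50: float  # nM
    pic50: float = field(default=math.nan)
    y_scaled: float = field(default=math.nan)
    split: Split = Split.unassigned

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError(f"ic50 must be positive, got {self.ic50}")
        if math.isnan(self.pic50):
            self.pic50 = to_pic50(self.ic50)


@dataclass
class RejectionTally:
    """Counts of rows dropped while loading an activity table."""

    nonpositive_ic50: int = 0
    missing_ic50: int = 0
    bad_smiles: int = 0
    unknown_target: int = 0

    @property
    def total(self) -> int:
        return (
            self.nonpositive_ic50
            + self.missing_ic50
            + self.bad_smiles
            + self.unknown_target
        )


@dataclass
class SplitSummary:
    """Per-target train/test counts produced by :func:`stratified_split`."""

    per_target_counts: dict[str, tuple[int, int, int]]  # (total, n_train, n_test)
    fraction_train: float


@dataclass(frozen=True)
class ResponseScaling:
    """Mean/sd used to standardize pIC50; supports the inverse transform."""

    mean: float
    sd: float

    def transform(self, pic50: float | np.ndarray) -> float | np.ndarray:
        return (pic50 - self.mean) / self.sd

    def inverse(self, y_scaled: float | np.ndarray) -> float | np.ndarray:
        return y_scaled * self.sd + self.mean


def to_pic50(ic50_nm: float) -> float:
    """Convert an IC50 in nM to pIC50 (= -log10 of the molar IC50)."""
    if ic50_nm <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nm}")
    return 9.0 - math.log10(ic50_nm)


def from_pic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`: pIC50 back to IC50 in nM."""
    return 10.0 ** (9.0 - pic50)


def load_panel(path: str | Path) -> list[TargetInfo]:
    """Read a panel definition CSV (``target_id,hdac_class,pdb_id,fasta_path``).

    ``pdb_id`` and ``fasta_path`` may be empty; when ``fasta_path`` is given the
    first sequence of that FASTA file is attached to the target.
    """
    from Bio import SeqIO

    df = pd.read_csv(path, dtype=str).fillna("")
    panel = []
    for row in df.itertuples(index=False):
        seq = None
        fasta = getattr(row, "fasta_path", "")
        if fasta:
            fasta_file = Path(path).parent / fasta if not Path(fasta).is_absolute() else Path(fasta)
            seq = str(next(SeqIO.parse(str(fasta_file), "fasta")).seq)
        panel.append(
            TargetInfo(
                target_id=row.target_id,
                hdac_class=HdacClass(row.hdac_class),
                pdb_id=row.pdb_id or None,
                sequence=seq,
            )
        )
    return panel


def _smiles_ok(smiles: str) -> bool:
    RDLogger.DisableLog("rdApp.error")
    try:
        return Chem.MolFromSmiles(smiles) is not None
    finally:
        RDLogger.EnableLog("rdApp.error")


def load_activities(
    path: str | Path,
    panel: list[TargetInfo] | tuple[TargetInfo, ...] = HDAC_PANEL,
    smiles_file: str | Path | None = None,
) -> tuple[list[InteractionRecord], RejectionTally]:
    """Load an activity table into interaction records.

    The table is a CSV with columns ``compound_id, smiles, target_id, ic50_nm``.
    If ``smiles_file`` (``.smi``, lines of ``SMILES<whitespace>id``) is given,
    its structures override/fill the ``smiles`` column, joined on compound id.

    Rows with missing or non-positive IC50, unparsable SMILES or a target not
    in ``panel`` are dropped and counted in the returned tally. Duplicate
    (compound, target) rows raise ``ValueError``: each pair must be measured
    once.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"compound_id", "target_id", "ic50_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    if "smiles" not in df.columns:
        df["smiles"] = ""

    if smiles_file is not None:
        mapping = read_smiles_file(smiles_file)
        df["smiles"] = df["compound_id"].map(mapping).fillna(df["smiles"])

    known = {t.target_id for t in panel}
    tally = RejectionTally()
    records: list[InteractionRecord] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        cid, tid = str(row.compound_id), str(row.target_id)
        if pd.isna(row.ic50_nm):
            tally.missing_ic50 += 1
            continue
        ic50 = float(row.ic50_nm)
        if ic50 <= 0:
            tally.nonpositive_ic50 += 1
            continue
        if tid not in known:
            tally.unknown_target += 1
            continue
        smiles = "" if pd.isna(row.smiles) else str(row.smiles)
        if smiles and not _smiles_ok(smiles):
            tally.bad_smiles += 1
            continue
        key = (cid, tid)
        if key in seen:
            raise ValueError(f"duplicate (compound, target) pair: {key}")
        seen.add(key)
        records.append(InteractionRecord(cid, smiles, tid, ic50))

    if not records:
        raise ValueError(f"no valid activity rows in {path}")
    if tally.total:
        logger.info("load_activities: dropped %d rows (%s)", tally.total, tally)
    return records, tally


def read_smiles_file(path: str | Path) -> dict[str, str]:
    """Read a ``.smi`` file (``SMILES<whitespace>id`` per line) into id->SMILES."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"malformed SMILES line: {line!r}")
        smiles, cid = parts
        mapping[cid.strip()] = smiles
    return mapping


def reset_split(records: list[InteractionRecord]) -> None:
    """Clear split labels so records can be re-split."""
    for r in records:
        r.split = Split.unassigned


def stratified_split(
    records: list[InteractionRecord],
    fraction_train: float = 0.65,
    seed: int = 0,
) -> SplitSummary:
    """Randomly split pairs into train/test within each target stratum.

    Exactly ``floor(fraction_train * n)`` pairs per stratum are labeled train;
    membership is randomized by ``seed``. Labels are written back onto the
    records in place.
    """
    if not 0 < fraction_train < 1:
        raise ValueError(f"fraction_train must be in (0, 1), got {fraction_train}")
    if any(r.split is not Split.unassigned for r in records):
        raise ValueError("records must all be unassigned before splitting")

    rng = np.random.default_rng(seed)
    by_target: dict[str, list[InteractionRecord]] = {}
    for r in records:
        by_target.setdefault(r.target_id, []).append(r)

    counts: dict[str, tuple[int, int, int]] = {}
    for tid in sorted(by_target):
        stratum = by_target[tid]
        n = len(stratum)
        if n == 0:  # pragma: no cover - defensive; dict never holds empty lists
            logger.warning("empty stratum for target %s skipped", tid)
            continue
        n_train = math.floor(fraction_train * n)
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            stratum[idx].split = Split.train if pos < n_train else Split.test
        counts[tid] = (n, n_train, n - n_train)
    return SplitSummary(per_target_counts=counts, fraction_train=fraction_train)


def scale_response(
    records: list[InteractionRecord],
    fit_on: str = "train",
) -> ResponseScaling:
    """Center and unit-variance scale pIC50 into ``y_scaled``.

    The mean and sample sd are estimated on the training subset by default
    (``fit_on="train"``) so that test responses never influence the scaling;
    ``fit_on="all"`` uses every record. The fitted parameters are returned for
    the inverse transform.
    """
    if fit_on not in ("train", "all"):
        raise ValueError(f"fit_on must be 'train' or 'all', got {fit_on!r}")
    subset = records if fit_on == "all" else [r for r in records if r.split is Split.train]
    if len(subset) < 2:
        raise ValueError("need at least two records in the fitting subset")
    values = np.array([r.pic50 for r in subset], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd < 1e-12:
        raise ValueError("degenerate scaling: pIC50 has zero variance in the fitting subset")
    scaling = ResponseScaling(mean=mean, sd=sd)
    for r in records:
        r.y_scaled = float(scaling.transform(r.pic50))
    return scaling


def write_activities(records: list[InteractionRecord], path: str | Path) -> None:
    """Write records back to CSV, including the split label."""
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "target_id": [r.target_id for r in records],
            "ic50_nm": [r.ic50 for r in records],
            "pic50": [r.pic50 for r in records],
            "split": [r.split.value for r in records],
        }
    ).to_csv(path, index=False)
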