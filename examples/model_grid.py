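"""Rerun the full 18-model descriptor-combination grid on the HDAC panel.

Protein blocks: the bundled sequence-identity (P0) and structure-similarity
(P1) matrices of the five crystal-structure HDAC isoforms, plus a geometry
block (P2) measured from synthetic helix structures standing in for the real
crystal structures. Ligand blocks: general descriptors (GD) and drug-like
index (DLI) computed from SMILES. Activities are synthetic, so the absolute
numbers demonstrate the machinery rather than reproduce published values.
"""

import numpy as np
import pandas as pd

from hdacpcm import (
    HDAC_PANEL,
    InteractionRecord,
    bundled_p0_matrix,
    bundled_p1_matrix,
    build_p2,
    compute_block,
    generate_helix_structure,
    run_model_grid,
    scale_response,
    stratified_split,
)
from hdacpcm.synthetic_data import STUB_SMILES

rng = np.random.default_rng(0)
targets = [t.target_id for t in HDAC_PANEL]

# protein blocks: bundled P0/P1; P2 from per-target synthetic structures
p0 = bundled_p0_matrix().to_frame().loc[targets]
p1 = bundled_p1_matrix().to_frame().loc[targets]
import tempfile, pathlib
with tempfile.TemporaryDirectory() as tmp:
    paths = {}
    for i, tid in enumerate(targets):
        path = pathlib.Path(tmp) / f"{tid}.pdb"
        generate_helix_structure(30, noise_A=0.03, seed=i, path=path)
        paths[tid] = path
    p2 = build_p2(paths).drop(columns=["dih_chi1_mean", "dih_chi1_sd"])
# poly-alanine has no chi1; padding keeps the 30-column contract
p2["dih_chi1_mean"] = 0.0
p2["dih_chi1_sd"] = 0.0

# ligand blocks computed from structures
compounds = {f"CMP{i:02d}": smi for i, smi in enumerate(STUB_SMILES)}
gd = compute_block(compounds, kind="GD").to_frame()
dli = compute_block(compounds, kind="DLI").to_frame()

# synthetic activities with descriptor-driven structure: potency increases
# with ligand lipophilicity and with the target's mean structural similarity
logp = gd["logp"]
z_logp = (logp - logp.mean()) / logp.std()
prot_effect = (p1.mean(axis=1) - p1.mean(axis=1).mean()) / p1.mean(axis=1).std()
records = []
for cid in gd.index:
    for tid in rng.choice(targets, size=3, replace=False):
        pic50 = 6.5 + float(z_logp[cid]) + float(prot_effect[tid]) + rng.normal(0, 0.3)
        records.append(InteractionRecord(cid, compounds[cid], tid,
                                         ic50=float(10.0 ** (9.0 - pic50))))
stratified_split(records, 0.65, seed=0)
scale_response(records)

table = run_model_grid(
    {"P0": p0, "P1": p1, "P2": p2},
    {"GD": gd, "DLI": dli},
    records,
    cv_folds=5,
    seed=0,
)
print(table.round(4).to_string())
print("\nColumns mirror a published model-grid layout: R2 on training pairs,")
print("10-fold (here 5-fold) cross-validated Q2, and Q2 on the held-out pairs.")
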