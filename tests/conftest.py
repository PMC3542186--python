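import pandas as pd
import pytest
from hypothesis import settings

from hdacpcm import SyntheticConfig, generate_dataset, generate_helix_structure

settings.register_profile("repeatable", derandomize=True, max_examples=50)
settings.load_profile("repeatable")

#: Per-target pair totals of the canonical HDAC activity panel.
PANEL_COUNTS = {"HDAC2": 215, "HDAC4": 197, "HDAC6": 531, "HDAC7": 46, "HDAC8": 286}


@pytest.fixture(scope="session")
def helix_pdb(tmp_path_factory):
    """Ideal (noise-free) 20-residue poly-alanine helix, written as PDB."""
    path = tmp_path_factory.mktemp("structures") / "helix20.pdb"
    generate_helix_structure(20, noise_A=0.0, seed=1, path=path)
    return path


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture()
def panel_activity_csv(tmp_path):
    """Activity table whose per-target pair counts match the canonical HDAC
    panel distribution (1275 pairs total), with valid structures."""
    rows = []
    k = 0
    for tid, n in PANEL_COUNTS.items():
        for i in range(n):
            rows.append(
                {
                    "compound_id": f"CMP{k:05d}",
                    "smiles": "CCO",
                    "target_id": tid,
                    "ic50_nm": 10.0 + i,
                }
            )
            k += 1
    path = tmp_path / "panel_activity.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
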