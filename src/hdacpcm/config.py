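"""Frozen constants shared across the package.

Feature orders, bin edges and internal-coordinate definitions are fixed here
so that descriptor vectors and assembled design matrices are reproducible:
a model trained with one release predicts correctly from descriptors computed
with the same constants.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Ligand general descriptors (GD): binned atomic-contribution VSA descriptors
# plus four whole-molecule properties, 32 features total.
#
# Bin edges follow widely used VSA conventions (subsets of the Wildman-Crippen
# logP/MR and Gasteiger partial-charge binnings), reduced to 10/8/10 bins.
# ---------------------------------------------------------------------------

SLOGP_VSA_BINS: tuple[float, ...] = (-0.4, -0.2, 0.0, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4)
SMR_VSA_BINS: tuple[float, ...] = (1.29, 1.82, 2.24, 2.45, 2.75, 3.05, 3.63)
PEOE_VSA_BINS: tuple[float, ...] = (-0.25, -0.2, -0.1, -0.05, 0.0, 0.05, 0.1, 0.2, 0.25)

GD_FEATURE_NAMES: tuple[str, ...] = (
    *[f"slogp_vsa_{i + 1}" for i in range(len(SLOGP_VSA_BINS) + 1)],
    *[f"smr_vsa_{i + 1}" for i in range(len(SMR_VSA_BINS) + 1)],
    *[f"peoe_vsa_{i + 1}" for i in range(len(PEOE_VSA_BINS) + 1)],
    "logp",
    "molar_refractivity",
    "total_vsa",
    "formal_charge_sum",
)
assert len(GD_FEATURE_NAMES) == 32

# ---------------------------------------------------------------------------
# Ligand drug-like index (DLI): 28 graph-topological counts and indices on the
# heavy-atom molecular graph (explicit hydrogens are not graph nodes).
# ---------------------------------------------------------------------------

DLI_FEATURE_NAMES: tuple[str, ...] = (
    "atom_count",
    "bond_count",
    "ring_count",
    "aromatic_ring_count",
    "ring_system_count",
    "largest_ring_size",
    "ring_atom_count",
    "framework_atom_count",
    "framework_bond_count",
    "linker_bond_count",
    "side_chain_atom_count",
    "rotatable_bond_count",
    "rigid_bond_count",
    "hbd_count",
    "hba_count",
    "halogen_count",
    "heteroatom_count",
    "sp3_carbon_percent",
    "chiral_center_count",
    "graph_diameter",
    "graph_radius",
    "terminal_atom_count",
    "branch_point_count",
    "degree1_count",
    "degree2_count",
    "degree3_count",
    "degree4_count",
    "max_degree",
)
assert len(DLI_FEATURE_NAMES) == 28

# ---------------------------------------------------------------------------
# Protein geometry descriptors: 15 internal-coordinate classes, summarised by
# mean and sample standard deviation -> 30 features. Order is frozen; each
# class contributes the pair (<name>_mean, <name>_sd).
#
# Bond lengths in Angstrom; bond angles and dihedrals in degrees, dihedrals on
# (-180, 180] with the IUPAC sign convention. omega is CA-C-N(+1)-CA(+1);
# chi1 is N-CA-CB-XG where XG is the first gamma heavy atom.
# ---------------------------------------------------------------------------

GEOMETRY_CLASSES: tuple[str, ...] = (
    # bond lengths
    "len_N_CA",
    "len_CA_C",
    "len_C_O",
    "len_C_Nnext",
    "len_CA_CB",
    # bond angles
    "ang_N_CA_C",
    "ang_CA_C_Nnext",
    "ang_CA_C_O",
    "ang_C_N_CA",
    "ang_N_CA_CB",
    "ang_C_CA_CB",
    # dihedrals
    "dih_phi",
    "dih_psi",
    "dih_omega",
    "dih_chi1",
)
assert len(GEOMETRY_CLASSES) == 15

GEOMETRY_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{cls}_{stat}" for cls in GEOMETRY_CLASSES for stat in ("mean", "sd")
)
assert len(GEOMETRY_FEATURE_NAMES) == 30

# Atom names of the first side-chain gamma heavy atom per residue, for chi1.
CHI1_GAMMA_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

# ---------------------------------------------------------------------------
# Ideal backbone internal coordinates used by the synthetic helix generator
# (standard Engh-Huber-style values; lengths in Angstrom, angles in degrees).
# ---------------------------------------------------------------------------

IDEAL_BACKBONE: dict[str, float] = {
    "len_N_CA": 1.458,
    "len_CA_C": 1.525,
    "len_C_N": 1.329,
    "len_C_O": 1.231,
    "len_CA_CB": 1.521,
    "ang_N_CA_C": 111.2,
    "ang_CA_C_N": 116.2,
    "ang_C_N_CA": 121.7,
    "ang_CA_C_O": 120.8,
    "ang_C_CA_CB": 110.1,
    "dih_CB_improper": -122.6,  # dihedral N-C-CA-CB placing CB off the backbone plane
}

ALPHA_HELIX_PHI = -57.0
ALPHA_HELIX_PSI = -47.0
ALPHA_HELIX_OMEGA = 180.0

# Maximum peptide-bond C(i)-N(i+1) distance treated as a covalent connection
# when scanning a chain for consecutive residues.
PEPTIDE_BOND_MAX_A = 2.5
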