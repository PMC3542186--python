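# Methods

## Scope and data model

The package models inhibitor potency across a panel of protein targets as a
single regression over compound–target pairs. A pair carries an IC50 in nM,
transformed to pIC50 = 9 − log₁₀(IC50 nM), i.e. −log₁₀ of the molar IC50 (the
unit convention of the field; 1 µM → 6, 1 nM → 9). Responses are mean-centered
and scaled to unit variance; all standard deviations in the package — for
responses, descriptor columns and geometry features — are sample (n−1) sds.
Scaling statistics are fit on the training pairs only by default, so held-out
pairs never leak into preprocessing; `fit_on="all"` reproduces pipelines that
standardize before splitting.

Rows with missing or non-positive IC50, unparsable SMILES or unknown targets
are dropped and tallied, never fatal, so partially curated public exports
remain usable. Duplicate (compound, target) rows are an error: the data model
is one measurement per pair.

### Train/test split

The split is stratified per target: within each target's pairs, exactly
⌊f·n⌋ pairs (f = 0.65 by default) are labeled train, the remainder test,
membership randomized by seed. The floor rule is a deliberate, documented
choice — with unbalanced panels no single rounding rule reproduces every
historically printed split, and floor keeps |n_train − f·n| < 1 in every
stratum.

## Protein descriptors

**P0 — sequence similarity.** Global Needleman–Wunsch alignment under
BLOSUM62 with affine gaps, gap open 10 and extend 0.5, terminal gaps free —
the EMBOSS `needle` defaults. Percent identity uses the full alignment length
including gap columns as denominator (the EMBOSS "Identity" convention;
alternative denominators such as shorter-sequence length inflate identities
between unequal-length sequences and were rejected). The implementation is
Biopython's `PairwiseAligner`; the test suite checks it against an
independent Gotoh dynamic-programming reference on random short sequences.
For the HDAC panel the descriptor is the identity of each modeled isoform
against the 11 classical HDACs (an 11-vector per target); the canonical
matrix ships as a CSV fixture.

**P1 — structure similarity.** Structure-alignment similarity scores are
ingested, not computed: published score definitions of structure-comparison
tools are generally not reproducible from text, so the package validates and
consumes any user matrix (self-similarity 1.0 within 1e−9, non-negative
entries) and ships the canonical 5×5 HDAC matrix as the reference fixture.

**P2 — geometry.** Thirty features: mean and sample sd of 15 internal-
coordinate classes — bond lengths N–CA, CA–C, C–O, C–N(next), CA–CB; bond
angles N–CA–C, CA–C–N(next), CA–C–O, C–N–CA, N–CA–CB, C–CA–CB; dihedrals φ,
ψ, ω (CA–C–N′–CA′) and χ1 — measured over all residues of the first model's
selected chain where the atoms exist. The class list is frozen in
`config.GEOMETRY_CLASSES` so that models remain reproducible. Dihedrals use
the IUPAC sign convention in degrees on (−180, 180]; first/last residues
lacking φ/ψ contribute no instance rather than an imputed one; HETATM and
non-standard residues are excluded; chain breaks are detected by a C–N
distance above 2.5 Å. A class with zero instances (e.g. χ1 in poly-alanine)
yields NaN features and is flagged. Known limitation: ω of trans peptide
bonds sits at the ±180° branch cut, where an arithmetic mean/sd of wrapped
angles is unstable; the feature is still rotation/translation-invariant and
deterministic, but not a meaningful summary there.

## Ligand descriptors

**GD (32).** Per-atom van der Waals surface area binned by Wildman–Crippen
logP contribution (10 bins), by molar-refractivity contribution (8 bins) and
by Gasteiger partial charge (10 bins) — bin edges are frozen constants
mirroring widely used VSA conventions — plus whole-molecule logP, molar
refractivity, total Labute ASA and the formal-charge sum. Gasteiger charges
are the charge model; quantum or forcefield charges would be equally
defensible but are not available from SMILES alone.

**DLI (28).** Topological counts on the heavy-atom graph (explicit hydrogens
are not nodes): atom/bond/ring counts, aromatic rings, fused ring systems,
largest ring, ring atoms, Murcko framework atoms/bonds, linker bonds,
side-chain atoms, rotatable/rigid bonds, H-bond donors/acceptors, halogens,
heteroatoms, sp³-carbon percentage, chiral centers (assigned + unassigned),
graph diameter/radius, terminal atoms, branch points, degree-1..4 counts and
maximum degree.

Both providers strip salts/mixtures to the largest covalent fragment and are
invariant to the SMILES writing of a molecule. Where the original descriptor
values of a study exist as a table, `load_descriptor_table` ingests them
(dimension-checked) in place of the built-in providers; models record which
features they were trained on via their scaling vectors.

## Cross-terms and assembly

Cross-terms are the flattened outer product (protein-major order) of the
*centered and scaled* protein and ligand descriptor vectors of a pair, and
are not re-scaled afterwards — centering before multiplication is what makes
the product an interaction rather than a main-effect proxy, and the product
of standardized columns is already on a comparable scale. Protein rows enter
at pair level by repetition across the target's pairs (standard PCM
practice). Constant columns are centered but not divided, keeping dimension
bookkeeping exact (e.g. 5+32+160 = 197 columns for the P1-GD cross mode).

## Kernel and regression

The Pearson VII universal ("Puk") kernel

K(x,y) = [1 + (2‖x−y‖√(2^(1/ω)−1)/σ)²]^(−ω)

is positive definite, bounded in (0,1], equal to 1 iff x = y, and
interpolates between Lorentzian (ω=1) and Gaussian (ω→∞) shapes. Parameter
defaults on the `PukParams` type are ω=1, σ=1, the reference-implementation
defaults. The ε-insensitive SVR dual is solved by libsvm (scikit-learn) on a
precomputed Gram matrix: deterministic for fixed inputs, box constraints
|α| ≤ C, and non-convergence raises rather than silently returning a bad fit.

**Width heuristic.** Distance kernels at σ=1 become effectively diagonal in
a few hundred standardized dimensions (typical here once cross-terms are
included), which makes any kernel regression collapse to its bias. The
workflow layer therefore sets σ = 16 × the median pairwise training distance
and C = 1000 by default, running the kernel in a wide, near-linear regime.
This is deliberate: PCM signals are dominated by smooth low-order structure —
additive block effects plus bilinear cross-terms — and in the wide-σ limit
Puk-SVR behaves like a heavily over-parameterized linear model with
ε-insensitive loss (the dual equality constraint Σα=0 cancels the quadratic
distance term), which suits that signal class. No per-dataset hyperparameter
search is performed; explicit `PukParams`/`SVRParams` override the heuristic.

**Validation.** All predictive statistics are PRESS-based:
Q² = 1 − Σ(y−ŷ)²/Σ(y−ȳ_ref)² with the reference mean always taken from the
data the model was fit on — the training mean for R²train/Q²test, the
per-fold training mean (pooled residuals) for Q²cv. Cross-validation folds
are random pair-level partitions; grouped (compound- or target-held-out)
evaluation is a caller choice by pre-assigning splits. Q²test > R²train is
possible and not treated as an error.

## Selectivity screen

A trained model predicts one scaled affinity per panel target for a compound
(featurized with the model's stored scalings). The call rule on a profile,
with activity threshold 0 on the scaled response (above-average predicted
affinity): none active → inactive; all active → pan; exactly one active →
isoform-selective(target); the active set equal to one full class →
class-selective; otherwise mixed. Isoform precedence (a single active target
is an isoform call even when it exhausts no class) reflects that an
isoform-selective compound is the stronger claim. A strict variant
additionally requires min(active) − max(inactive) > margin (default 0.1)
before any selective call. The published ten-inhibitor external-validation
profiles ship as a fixture; under the default rule they yield 5/10
label-consistent calls (isoform calls inside the labeled class counted as
consistent) — notably a pan-labeled compound with one inactive isoform
cannot be called pan by any fixed threshold, so agreement is reported, not
asserted.

## Synthetic data generator

The generator emulates the statistical structure of a public activity panel:
T targets (classes I/II assigned 40/60), L compounds, standard-normal
descriptor blocks, and

pIC50 = 6.5 + βₚ·p + βₗ·l + pᵀWl + ε,  ε ~ N(0, noise_sd²).

Defaults: 5 targets, 200 compounds, d_p=5, d_l=32, per-target pair counts
(43, 39, 106, 9, 57) — a real panel's unbalanced shape scaled to ~250 pairs,
exercising the stratified splitter and the data-starved-target regime —
noise sd 0.1, and β coefficients scaled to unit main-effect variance per
block. W combines a sparse background (density 0.1, total variance
`w_scale`² = 0.25 by default) with one structured entry: protein descriptor 1
is the class indicator (±1), ligand descriptor 1 a selectivity axis, and
their product enters with weight `selectivity_gain` (1.0). Setting
`w_scale=0, selectivity_gain=0` turns the interaction off entirely.

Planted class-selective compounds get an extreme coordinate (±4) on the
selectivity axis — a ≥4 log-unit potency separation between classes, the
signature of a genuinely selective chemotype — and are **panel-profiled**:
the generator guarantees them a measured pair with every target (counted
within the per-target totals), as known selective reference inhibitors are
panel-profiled in practice. This matters statistically: with ~9 pairs on the
smallest target, the class contrast of an *unmeasured* compound–target pair
at that target is essentially unidentifiable (verified with an exactly
specified linear oracle), so the screen is evaluated in the setting it is
designed for — profiling compounds whose assay data the deployed model has
seen. Accordingly the deployment model for screening (`fit_final`) is refit
on all pairs after the model family is validated on held-out data, the
standard final-refit practice.

The main-effect coefficients of the two marker dimensions are zero, so
planting changes between-class contrast only. What the generator does *not*
emulate: real descriptor correlation structure (VSA bins are strongly
correlated in real molecules), heavy-tailed activity distributions, assay
noise heterogeneity, and chemically meaningful SMILES (a stub library is
cycled so emitted tables stay parseable). Passing recovery tests therefore
demonstrate the pipeline's statistical machinery, not chemistry-level
accuracy on real data.

A second generator builds poly-alanine helices from ideal backbone internal
coordinates (NeRF chain construction; φ=−57°, ψ=−47°, ω=180° by default)
with optional Gaussian coordinate jitter, written as standard PDB text. PDB
coordinates are quantized to 0.001 Å, so even noise-free structures show
bond-length sds of a few 10⁻⁴ Å after a round trip through the format.

## Numerical and design notes

* Gram matrices are symmetrized and given an exact unit diagonal before the
  solver; PSD is verified in tests to eigenvalue −1e−8.
* Constant descriptor columns: centered, kept, flagged — never dropped.
* Degenerate inputs raise: zero response variance, empty fit sets, Q² with a
  zero reference sum of squares, fewer than 3 consecutive residues.
* Model serialization is a single `.npz` archive (JSON metadata + arrays);
  a loaded model reproduces predictions bit-for-bit.
* Problem sizes in tests and examples (≤ ~260 pairs, ≤ 20 CV seeds) were
  chosen so the full suite runs in well under a minute on one core while
  keeping every statistical check meaningfully powered.
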