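# hdacpcm

Proteochemometric (PCM) modeling and selectivity screening of histone
deacetylase (HDAC) inhibitors.

## The problem

HDACs are zinc-dependent epigenetic drug targets whose eleven "classical"
isoforms fall into classes I, IIa, IIb and IV. Pan-HDAC inhibitors carry
substantial side effects, so drug discovery increasingly asks not "is this
compound active?" but "against *which* isoforms is it active?". Answering
that with one QSAR model per isoform is wasteful and cannot extrapolate to
targets with little data. PCM instead fits a **single** regression over
compound–target *pairs*, described jointly by ligand descriptors, protein
descriptors and (optionally) their cross-terms, so that every assay point for
every isoform informs one model — which can then predict a full
per-isoform affinity profile for any compound and call it pan-,
class-I/II- or isoform-selective.

## The model

For a pair (ligand *l*, protein *p*) with descriptor vectors **x**ₗ, **x**ₚ
(each column mean-centered and scaled to unit variance on training pairs), the
design row is one of

* blocks: [**x**ₚ, **x**ₗ]
* blocks + cross-terms: [**x**ₚ, **x**ₗ, **x**ₚ ⊗ **x**ₗ]
* cross-terms only: [**x**ₚ ⊗ **x**ₗ]

where ⊗ is the flattened outer product modeling interface complementarity.
Protein blocks are P0 (global sequence identities vs the 11 classical HDACs,
Needleman–Wunsch/BLOSUM62 at EMBOSS defaults), P1 (ingested structure-
alignment similarities; the canonical 5×5 HDAC matrix ships with the package)
and P2 (30 geometry features: mean and sd of 15 backbone/side-chain internal-
coordinate classes). Ligand blocks are GD (32 surface-area/logP/molar-
refractivity/partial-charge descriptors) and DLI (28 topological drug-like
indices). Three modes × three protein blocks × two ligand blocks give the
18-model grid.

The regressor is ε-insensitive SVR under the Pearson VII universal kernel

    K(x, y) = 1 / [1 + (2‖x−y‖·√(2^(1/ω)−1)/σ)²]^ω,

and predictive ability is summarised by PRESS-based statistics

    Q² = 1 − Σ(y − ŷ)² / Σ(y − ȳ_train)²

as R²(train), Q²cv (10-fold, fold-training reference means) and Q²test.
Responses are pIC50 = 9 − log₁₀(IC50 in nM), standardized. A profile of
predicted scaled affinities is called **pan** (all targets above threshold),
**class-I/II-selective** (exactly one full class active),
**isoform-selective** (a single target), **inactive** or **mixed**.

## Worked example

```bash
python examples/synthetic_pipeline.py
```

```
pairs: 254 across 5 targets
model: P1-GD-C  (n_train=162, n_test=92)
R2_train = 0.9999   # goodness of fit on training pairs
Q2_cv    = 0.8948   # 10-fold cross-validated predictive ability
Q2_test  = 0.9282   # predictive ability on held-out pairs
```

A 5-target/200-compound synthetic panel (unbalanced pair counts, noise sd
0.1) is split 65/35 per target and fit with blocks + cross-terms; Q²test ≈
0.93 means the model recovers nearly all generating signal. The other
examples rerun the 18-model grid (`examples/model_grid.py`), screen the
bundled ten-inhibitor external-validation profiles and two planted
class-selective compounds (`examples/selectivity_screen.py`), and print the
geometry descriptor block of an ideal helix
(`examples/geometry_descriptors.py`). For the bundled ten-inhibitor table the
threshold rule reproduces the canonical calls — apicidin class-I-selective,
NCT-10a class-II-selective, panobinostat (LBH589) pan.

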