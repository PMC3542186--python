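"""Fit one proteochemometric model end to end on a synthetic activity panel.

Generates a 5-target / 200-compound panel with known additive and bilinear
structure, splits it 65/35 per target, standardizes the pIC50 responses,
trains a Pearson-VII-kernel SVR on protein + ligand descriptors plus their
cross-terms, and prints the validation metrics.
"""

from hdacpcm import SyntheticConfig, fit_synthetic, generate_dataset

dataset = generate_dataset(SyntheticConfig(seed=1))
print(f"pairs: {len(dataset.records)} across {len(dataset.protein_block)} targets")

fit = fit_synthetic(dataset, mode="blocks_plus_cross", seed=1)
m = fit.metrics
print(f"model: {m.spec_name}  (n_train={m.n_train}, n_test={m.n_test})")
print(f"R2_train = {m.r2_train:.4f}   # goodness of fit on training pairs")
print(f"Q2_cv    = {m.q2_cv:.4f}   # 10-fold cross-validated predictive ability")
print(f"Q2_test  = {m.q2_test:.4f}   # predictive ability on held-out pairs")

# R2_train near 1 with Q2 well below it is the expected signature of a
# tight-tube kernel SVR; Q2_test ~0.9 means the model recovers most of the
# generating signal (noise sd 0.1 on a response of unit variance).
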