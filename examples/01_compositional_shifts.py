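"""Detect cell-type abundance shifts across pathology groups.

Simulates a donor cohort in which one neuronal subtype loses relative
abundance as pathology advances (log2FC -1.5 from low to high), fits the
Dirichlet-multinomial compositional model with a spike-and-slab prior on the
disease-group effects, and prints the credible effects.
"""

import numpy as np

import scresilience as sr

lfc = np.zeros(8)
lfc[1] = -1.5  # T1 is depleted at high pathology

cfg = sr.CohortConfig(n_donors_per_group=20, n_celltypes=8,
                      n_cells_per_donor=2000, comp_log2fc=lfc, n_genes=50, seed=0)
counts, donor_meta = sr.simulate_composition(cfg)
ct = sr.CompositionTable(counts, donor_meta)

reference = sr.select_reference(ct)
print(f"automatic reference cell type: {reference}")

post = sr.fit_dirichlet_multinomial(ct, reference=reference, mcmc={"seed": 0})
print(f"sampler diagnostics: {post.diagnostics}")

effects = sr.credible_effects(post, pip_min=0.95, min_abs_log2fc=0.1)
print("\ncredible compositional effects (PIP > 0.95 and |log2FC| > 0.1):")
print(effects.to_string(index=False))
print("\nT1 was planted with a high-vs-low log2FC of -1.5; the posterior mean"
      "\nabove should recover it, and no unplanted type should appear.")

beta = sr.fit_beta_regression(ct, contrast="high")
print("\nbeta-regression check (coefficient = logit-scale high-vs-low shift):")
print(beta[["coef", "p", "fdr"]].round(4).to_string())
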