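# scresilience

Analyses for asking which cortical neuron populations *survive* advancing
neurodegenerative pathology — and what distinguishes them — from staged
single-nucleus RNA-seq cohorts, spatial panel data, and calcium imaging.
The package is aimed at computational biologists working with donor cohorts
stratified into low / intermediate / high pathology groups (e.g. collapsed
Braak stages), who need the full pipeline from raw counts to
"high-confidence" answers: which cell types shift in relative abundance,
which genes change expression at each disease stage, which co-expression
modules organize those changes, where the populations sit in tissue, and
whether candidate genes alter neuronal activity in vitro.

Everything runs end to end on a built-in synthetic cohort generator with
known ground truth, so every claim the pipeline makes can be checked against
planted structure — no external data download is required.

## What it computes

**Compositional shifts** (`composition`).  Donor x cell-type counts are
modeled as `counts_d ~ DirichletMultinomial(n_d, phi * softmax(a + x_d B))`
with an automatically selected reference type (B[:, ref] = 0), adjusting for
sex, APOE, assay and age.  Disease-group effects carry a spike-and-slab
prior; an effect is credible when its posterior inclusion probability (PIP)
exceeds 0.95 and |log2FC| > 0.1.  A loss-only stress variant constrains
every group coefficient to beta <= 0 (HalfNormal magnitude), and a
fixed-effects beta regression with logit link provides a frequentist check.

**Consensus differential expression** (`diffexpr`).  Per cluster and
disease-stage contrast ("early" = intermediate vs low, "late" = high vs
intermediate), three engines run on the same cells: a two-part hurdle model
with a donor random intercept (detection + expression, 2-df LRT, the
published pct > 20% / |logFC| > 0.1 / FDR < 0.05 filters); a 100-iteration
stratified 50% subsampling bootstrap retaining genes called in the same
direction in >= 20 iterations; and donor-level pseudobulk NB Wald tests
(>= 20-nuclei gene filter, median-of-ratios size factors).  A gene is
**high-confidence** iff the mixed model calls it and bootstrap, pseudobulk
(same direction) or co-expression hub membership corroborates it.

**Co-expression modules** (`coexpression`).  k = 25 metacells per group
(>= 50 cells), soft-power |cor|^beta adjacency with a scale-free/connectivity
scan, topological overlap, average-linkage modules with eigengene merging
and kME rescue, per-module top-10 hubs and top-50 kME lists (which feed the
DE consensus), and bootstrap Jaccard stability.

**Spatial ensemble annotation** (`spatial`).  Independent classifiers
(marker heuristic, Leiden communities, kNN label transfer, plus any plugged
external votes) combined by strict plurality; cells are retained only with
consensus confidence > 0.5, and neurons with > 50 transcripts receive
subtypes by kNN transfer in the reference PCA space (15 PCs, k = 20).

**Calcium events** (`calcium`).  dF/F0 against a rolling 10th-percentile
10-second baseline, events as strict upward crossings of 0.2 dF/F0, rates in
events/min averaged at the well level (wells are the biological replicates).

Supporting stages: QC filters (>= 300 genes, <= 5% mitochondrial reads),
median-library log normalization, dispersion-based HVG selection, Wilcoxon
marker ranking with the strict pts / pts_rest / ratio / logFC / padj
filters, cosine cluster matching, and pseudobulk aggregation.

## Worked example

```python
import numpy as np
import scresilience as sr

lfc = np.zeros(8); lfc[1] = -1.5          # T1 depleted at high pathology
cfg = sr.CohortConfig(n_donors_per_group=20, n_celltypes=8,
                      n_cells_per_donor=2000, comp_log2fc=lfc, seed=0)
counts, donors = sr.simulate_composition(cfg)
ct = sr.CompositionTable(counts, donors)
post = sr.fit_dirichlet_multinomial(ct, reference=sr.select_reference(ct),
                                    mcmc={"seed": 0})
print(sr.credible_effects(post))
```

prints (run via `python examples/01_compositional_shifts.py`):

```
celltype     contrast    log2fc  pip
      T1 intermediate -0.839628  1.0
      T1         high -1.408850  1.0
```

T1 was planted with a high-vs-low log2 fold change of -1.5; the posterior
recovers -1.41 at the high stage (and about half that at the intermediate
stage, as the generator places the intermediate group halfway on the log
scale), with PIP 1.0 — and no unplanted type passes the credibility gate.
The `examples/` directory holds one narrative script per capability
(composition, consensus DE, co-expression, spatial annotation, calcium
events, markers/label transfer); each simulates a small input, runs the
method and explains the numbers it prints.

## Documentation

`docs/methods.md` describes the models, priors, numerical choices, the
synthetic generator's assumptions and what passing tests do and do not show
about real data.
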