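# Methods

`scresilience` re-implements, as a tested library, the computational pipeline
used to identify cortical neuron populations whose relative abundance is
preserved across advancing tau-pathology stages: compositional testing of
cell-type proportions, a three-engine consensus for differential expression,
metacell co-expression networks with kME hub ranking, ensemble annotation of
spatial panel data, and calcium-transient quantification.  Everything is
exercised end to end on a synthetic cohort generator with known ground truth;
no external download is required.

## The synthetic cohort generator

The generator produces the data model the downstream analyses assume, layer
by layer:

* **Donors.** Three pathology groups (low / intermediate / high), a
  configurable number of donors per group, with covariates (sex, age, APOE
  genotype, assay platform, RIN) drawn independently of group.  Covariates
  have zero true effect by default, so any sensitivity they cost downstream
  is the price of adjustment, not confounding.
* **Composition.** Per donor, cell-type counts are Dirichlet-multinomial
  around group-shifted baseline proportions.  `comp_log2fc` is the **total
  high-vs-low** log2 shift of a type's relative abundance (groups are scored
  0 / 0.5 / 1), so the intermediate group sits halfway on the log scale.
  The concentration default `dm_concentration = 150` gives donor-level
  proportion CVs around 20% at a 1/8 baseline — typical of cortical subtype
  proportions across individuals.
* **Expression.** Per cell, gene counts are negative binomial (theta =
  `nb_dispersion`, default 2) with mean = gene base mean x marker multiplier
  x donor random effect x condition effect x module latent factor, thinned
  by a per-gene-per-cell logistic detection curve in log mean
  (`dropout_midpoint = -2`, slope 1) — the zero-inflation structure a hurdle
  model assumes.  Base means are log-normal (median 0.3, sigma 1.2).
  `de_log2fc` is the log2 fold change of each **adjacent-stage** contrast
  (early: intermediate vs low; late: high vs intermediate), applied with
  alternating signs to the planted genes.
* **Donor random effect.** A single multiplicative log-normal factor
  (`donor_sd = 0.15`) shared across genes.  Deliberately the simplest
  structure that makes naive per-cell tests anti-conservative; note that
  because it is shared across genes it acts like a library-size shift and is
  largely removed by normalization — residual donor correlation enters
  through the nonlinear detection layer.
* **Planted structure placement.** DE genes, markers and module members are
  floored at moderate base expression (mean >= 1; module members at a common
  mean of 2).  This is intentional: recovery benchmarks should measure the
  testing machinery, not detection limits, and a hub is only a meaningful
  ground truth if its kME margin is resolvable.  Module loadings are hub =
  1.0 and members tapering 0.7 -> 0.45 (all scaled by `module_strength`).
* **RNG.** One top-level seed, hierarchical `SeedSequence` substreams per
  donor: byte-identical regeneration, including of single donors.

Spatial sections place cells uniformly in horizontal type bands with Poisson
panel counts from per-type expected-count profiles plus uniform Poisson
background ("spillover") at `noise_rate`.  Calcium traces are a slowly
varying baseline times (1 + sum of instantaneous-rise exponential-decay
transients) plus Gaussian noise, 100 s at 5 Hz by default.

What the generator does **not** emulate: ambient RNA and droplet artifacts,
doublets, batch structure beyond a categorical assay covariate, spatial
segmentation errors, gene-gene correlation outside the planted modules, and
donor effects that differ between genes.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its assumed data
model, not performance on any real cohort.

## Compositional inference

Donor x cell-type counts are modeled as

    counts_d ~ DirichletMultinomial(n_d, phi * softmax(a + x_d B)),

with one reference type's coefficients fixed at zero.  The explicit
concentration phi (log-normal prior, median 100) separates composition from
donor-level overdispersion and makes the likelihood exactly invariant to
adding a constant to all type logits — the compositional closure property.
The automatic reference is the most dispersion-stable type among those
present in >= 90% of donors (variance of proportion / mean proportion,
lexicographic ties).

Disease-group coefficients carry a spike-and-slab prior (point mass at zero,
Normal(0, 1) slab, prior inclusion probability 0.2); nuisance covariates
(sex, APOE, assay, standardized age) carry plain Normal(0, 1) priors.  The
posterior is sampled by Hamiltonian Monte Carlo (8 leapfrog steps, step size
tuned by dual averaging to 0.8 acceptance during warmup) with the inclusion
indicators Gibbs-updated each sweep and inactive slab values refreshed from
their prior (their exact full conditional).  Defaults: 4 chains, 1000
warmup, 1000 samples, with split R-hat, a crude bulk ESS, acceptance and
divergence counts reported; R-hat > 1.05 on any group coefficient raises a
warning and flags the result.  An effect is credible when its posterior
inclusion probability exceeds 0.95 **and** |posterior-mean log2FC| > 0.1.

The loss-only stress variant reparameterizes each group coefficient as
beta = -|b| with b Gaussian — a HalfNormal magnitude — so every posterior
draw satisfies beta <= 0 exactly while HMC moves on a smooth unconstrained
scale.  There is no spike on the half-line, so credibility is reported from
the 95% credible interval instead of a PIP; with a continuous prior that
interval excludes zero almost surely, which is why the variant is a
direction-of-effect stress test rather than a detection procedure.

The frequentist cross-check is a fixed-effects beta regression of donor
proportions (shrunk away from {0,1} by (y(n-1)+0.5)/n) on the same
covariates with a logit link, one model per type, BH across types; types
observed in fewer than 3 donors are excluded.  A donor random intercept is
unidentifiable here — one observation per donor per type — so it is omitted
by design.  Constant proportions yield a zero coefficient with p = 1 by
convention.

## Consensus differential expression

The contrasts are early (intermediate vs low) and late (high vs
intermediate), per cluster and region.

**Hurdle mixed model.**  Per gene, a detection part (penalized logistic
regression of expressed 0/1) and an expression part (penalized linear model
of log-normalized values among expressing cells) share one design:
intercept, condition, standardized detected-gene count, assay, age, sex,
RIN, total counts, plus a donor random intercept fitted by penalized
quasi-likelihood (ridge on donor indicators, lambda = 1/sigma_u^2
re-estimated over outer iterations).  Donor indicators being one-hot, the
working equations are solved through their p x p Schur complement, keeping
per-gene cost linear in cells.  The gene p-value is chi-square on the summed
penalized likelihood-ratio statistics of the two parts for dropping the
condition column (2 df; 1 df when only one part is estimable).  With <= 4
donors the donor terms are dropped (a pooled fit, recorded per gene) — donor
fixed effects would absorb the between-donor condition contrast entirely.
Logistic separation flags the gene and sets p to NA.  Published filters
gate significance: expression fraction > 20% in at least one condition,
|logFC| > 0.1 (the expression-part condition coefficient, natural log), BH
FDR < 0.05.

**Bootstrap.**  100 iterations; each draws, without replacement, 50% of the
nuclei of each condition (a stratified half-sample, not a classical
bootstrap), reruns the hurdle test with its filters, and tallies directional
significance.  A gene passes with support >= 20/100 in one direction and
zero significant calls in the other — any opposite-direction call
disqualifies.  Sampling is keyed to sorted cell identifiers, so support
counts are bit-reproducible under a fixed seed and invariant to input order.

**Pseudobulk.**  Donor-level summed counts, genes expressed in < 20 nuclei
dropped, DESeq-style median-of-ratios size factors as offsets, per-gene NB
GLM with maximum-likelihood dispersion profiled on a bounded log grid, Wald
test on the condition coefficient, BH.  With <= 4 donors per group,
dispersions are shrunk halfway (log scale) toward an a/mean + b trend before
testing.

**Consensus.**  A gene is high-confidence iff the mixed model calls it
significant AND at least one of {bootstrap support, pseudobulk significance
in the same direction, membership in a module's top-50 kME list}
corroborates it; a corroborating method significant in the opposite
direction excludes the gene and is logged.  The consensus set is therefore
always a subset of the mixed calls.  UpSet-style intersections across
region x contrast conditions are exact set algebra.

A power note: with ~28 donors and five to six randomly drawn donor-level
covariates, a fifth to a quarter of the condition's between-donor variance
is typically all that remains identifiable after adjustment.  Benchmarks
here use 14 donors per group — the scale of the cohort the pipeline is built
for (10–18 donors per pathology group) — where sensitivity for |log2FC| = 1
planted genes is about 0.9; at 8 donors per group the same machinery is
correct but underpowered (verified against pooled statsmodels fits).

## Co-expression networks

Cells are aggregated into metacells within each group (cluster x donor):
each accepted seed cell averages itself and its k-1 = 24 nearest neighbors
in the group's PCA space; candidates overlapping an accepted metacell in
more than 10 cells are rejected, and groups under 50 cells contribute
nothing.  Gene-gene |Pearson correlation| over metacells is raised to a soft
power: the scan reports (power, scale-free R^2, mean connectivity) for
powers 1–20, choosing the smallest power with R^2 >= 0.8 among powers whose
mean connectivity stays >= 0.1; if none qualifies, the smallest power that
brings mean connectivity down to 0.5.  The connectivity-based fallback
replaces an argmax over R^2 because on planted-module data the R^2 curve
plateaus into noise while connectivity is smooth and monotone in the power —
the failure modes of an unstable choice are concrete (low powers merge
unrelated modules under the fixed cut height; high powers empty the network
and leave everything unassigned).

Adjacency becomes a topological overlap matrix (TOM_ij = (sum_u a_iu a_uj +
a_ij) / (min(k_i,k_j) + 1 - a_ij), unit diagonal); modules come from
average-linkage clustering of 1-TOM cut at the constant height 0.99,
filtered to >= 30 genes, merged when eigengene correlation >= 0.75, and
finished with a kME reassignment pass: unassigned genes whose |kME| to some
eigengene reaches 0.5 join that module (the standard membership rescue;
without it the constant-height cut trims weakly loaded members).  Eigengenes
are first principal components of the standardized module genes over
metacells, sign-oriented to correlate positively with their members.  kME is
the Pearson correlation of a gene with a module eigengene; hubs are the
top-10 by kME and the top-50 feed the DE consensus.  Stability resamples
metacells with replacement (default 100 iterations; the full-scale setting
is 5000), re-detects modules at the same power, and reports the mean
best-match Jaccard per reference module.

## Spatial ensemble annotation

Three native classifiers vote per cell: (1) a heuristic that scores each
type by its mean marker-gene count and takes the argmax (ties and zero
signal are "unknown"); (2) Leiden community detection (resolution 1.0,
seeded) on a kNN graph of log-normalized panel profiles, each community
labeled by its best mean marker score; (3) kNN label transfer from a
dissociated reference through the reference-fitted PCA space (15 PCs,
k = 20, majority vote, ties unassigned).  Any additional vote table (e.g. an
external DNN classifier) can be plugged in.  Consensus is strict plurality:
confidence is the agreeing share of cast votes — "unknown" votes stay in
the denominator unless every method abstained — and only cells with
confidence strictly above 0.5 are retained.  Retained neuronal cells with
strictly more than 50 transcripts receive a subtype by the same kNN
transfer restricted to the shared panel.

## Calcium events

dF/F0 uses a rolling 10th-percentile baseline over a 10-second window,
centered with edge truncation (centering minimizes onset bias; the
percentile interpolates linearly between order statistics).  A non-positive
baseline rejects the trace.  Events are strict upward crossings of
dF/F0 = 0.2, debounced at 0.4 s (two samples at 5 Hz); whether the original
quantification counted crossings or supra-threshold peaks is not specified,
and crossing-with-debounce is the documented choice here.  Rates are
events/minute per trace, averaged to well level; condition summaries average
well means, never pooled traces.  The rate-recovery benchmark plants evenly
spaced transients of amplitude 0.5 with noise sd 0.02 — the threshold then
sits many noise standard deviations above the baseline and well below the
peaks, so counting should be exact and any deviation indicates a detector
defect rather than a noise artifact (at noise approaching amplitude/5, the
decaying tail lingers near threshold and occasional double counts are
expected behavior of any crossing detector).

## Problem sizes used by the test suite and acceptance script

Compositional checks run 20 donors/group, 8 types, 2000 cells/donor at the
default 4 x (1000 + 1000) MCMC setting.  Consensus-DE checks use a fully
null 10,000-gene cohort on a ~220-cell cluster plus ten 500-gene planted
replicates on a 616-cell cluster (14 donors/group x 22 cells) with the full
100-iteration bootstrap.  Co-expression recovery uses two planted 50-gene
modules among 400 noise genes over repeated seeds (5 donors x 150 cells).
`scripts/acceptance.py` recomputes the same quantities at reduced replicate
counts, all seeded from `--seed`.

## Known limitations

* PQL is an approximation; its p-values are asymptotic and the donor
  variance estimate is floored, so calibration claims rest on the simulation
  checks, not theory.
* The DM sampler's PIPs inherit the 0.2 prior inclusion probability; with
  very small donor counts the PIP scale (not just the 0.95 gate) should be
  interpreted cautiously.
* The constant-height module cut assumes the soft power lands in its working
  range; the connectivity-guarded scan arranges this, but pathological
  correlation structures could still defeat both.
* Dispersion moderation in the pseudobulk engine is a simple halfway
  log-shrinkage toward a two-parameter trend, adequate at the benchmarked
  scales but cruder than full empirical-Bayes machinery.
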