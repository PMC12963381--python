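"""Three-engine differential expression and the high-confidence consensus.

For one neuronal cluster, region and disease-stage contrast ("early" =
intermediate vs low pathology, "late" = high vs intermediate) three tests
run on the same cells:

* a two-part hurdle model with a donor random intercept (detection +
  expression parts, 2-df combined likelihood-ratio test), the primary engine;
* half-sample bootstrap consensus: 100 stratified 50% subsamples of nuclei,
  keeping genes called significantly in the same direction in >= 20
  iterations (any opposite-direction significant iteration disqualifies);
* donor-level pseudobulk negative-binomial Wald tests on summed counts.

A gene is "high-confidence" when the mixed model calls it significant AND at
least one of {bootstrap, pseudobulk (same direction), co-expression hub
membership} corroborates it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from ._hurdle import hurdle_test_all
from .data import NormalizedMatrix

CONTRAST_GROUPS = {"early": ("low", "intermediate"), "late": ("intermediate", "high")}

DEFAULT_COVARIATES = ("cngeneson", "assay", "age", "sex", "RIN", "total_counts")


@dataclass(frozen=True)
class Contrast:
    """A disease-stage comparison: ``comparison`` vs ``baseline``."""

    name: str
    baseline: str = ""
    comparison: str = ""

    def __post_init__(self) -> None:
        if self.name in CONTRAST_GROUPS:
            base, comp = CONTRAST_GROUPS[self.name]
            if not self.baseline:
                object.__setattr__(self, "baseline", base)
            if not self.comparison:
                object.__setattr__(self, "comparison", comp)
            if (self.baseline, self.comparison) != (base, comp):
                raise ValueError(
                    f"contrast {self.name!r} must compare {comp} vs {base}"
                )
        elif not self.baseline or not self.comparison:
            raise ValueError("custom contrasts need explicit baseline/comparison")


@dataclass
class DEResult:
    """Per-gene statistics of one DE method for one cluster/region/contrast."""

    table: pd.DataFrame
    method: str
    contrast: Contrast
    cluster: str | None = None
    region: str | None = None
    info: dict = field(default_factory=dict)

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"].fillna(False)]


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _build_design(
    cell_meta: pd.DataFrame,
    donor_meta: pd.DataFrame,
    contrast: Contrast,
    covariates: tuple[str, ...],
    expressed_counts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Fixed-effect design (intercept, condition, covariates) + donor index."""
    joined = cell_meta.join(donor_meta, on="donor_id", rsuffix="_donor")
    cond = (joined["pathology_group"] == contrast.comparison).to_numpy(float)
    cols = [np.ones(len(joined)), cond]
    for cov in covariates:
        if cov == "cngeneson":
            cols.append(_standardize(expressed_counts))
        elif cov == "assay":
            d = pd.get_dummies(joined["assay"].astype(str), drop_first=True)
            for c in d.columns:
                col = d[c].to_numpy(float)
                if col.std() > 0:
                    cols.append(_standardize(col))
        elif cov == "sex":
            col = (joined["sex"].astype(str) == "M").to_numpy(float)
            if col.std() > 0:
                cols.append(_standardize(col))
        elif cov in ("age", "RIN"):
            col = joined[cov].to_numpy(float)
            if col.std() > 0:
                cols.append(_standardize(col))
        elif cov == "total_counts":
            col = joined["total_counts"].to_numpy(float)
            if col.std() > 0:
                cols.append(_standardize(col))
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    X = np.column_stack(cols)
    donors, donor_idx = np.unique(joined["donor_id"].to_numpy(), return_inverse=True)
    return X, donor_idx.astype(np.int64), cond, len(donors)


def fit_hurdle_mixed(
    nm: NormalizedMatrix,
    cell_meta: pd.DataFrame,
    donor_meta: pd.DataFrame,
    contrast: Contrast,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    pct_min: float = 0.2,
    logfc_min: float = 0.1,
    fdr_max: float = 0.05,
    cluster: str | None = None,
    region: str | None = None,
) -> DEResult:
    """Hurdle mixed-model DE test for the cells in ``cell_meta``.

    Cells are canonicalized to sorted id order, so results are invariant to
    the order in which cells arrive.  The donor random intercept uses PQL;
    with 4 or fewer donors the donor terms are dropped (pooled fit) and this
    fallback is recorded in ``info['donor_handling']``.  Published filters
    (expression fraction > ``pct_min`` in at least one condition, |logFC| >
    ``logfc_min``, BH FDR < ``fdr_max``) flag significance.
    """
    meta = cell_meta.join(donor_meta, on="donor_id", rsuffix="_donor")
    in_contrast = meta["pathology_group"].isin([contrast.baseline, contrast.comparison])
    meta = meta[in_contrast].sort_index()
    if len(meta) < 20:
        raise ValueError("contrast groups have fewer than 20 cells in total")
    for group in (contrast.baseline, contrast.comparison):
        sub = meta[meta["pathology_group"] == group]
        if sub["donor_id"].nunique() < 2:
            raise ValueError(f"group {group!r} has fewer than 2 donors")

    idx = nm.cell_ids.get_indexer(meta.index)
    if (idx < 0).any():
        raise ValueError("cells missing from the normalized matrix")
    Y = np.ascontiguousarray(nm.values[:, idx])
    E = (Y > 0).astype(np.float64)
    expressed_counts = E.sum(axis=0)

    X, donor_idx, cond, n_donors = _build_design(
        meta, donor_meta, contrast, covariates, expressed_counts
    )
    use_donor = n_donors > 4
    X_red = np.ascontiguousarray(np.delete(X, 1, axis=1))
    X = np.ascontiguousarray(X)

    logfc, lr, dfs, flags = hurdle_test_all(
        Y, E, X, X_red, 1, donor_idx, n_donors, use_donor
    )
    pvals = np.full(len(logfc), np.nan)
    ok = dfs > 0
    pvals[ok] = stats.chi2.sf(lr[ok], dfs[ok])

    base_mask = cond == 0
    pct_base = E[:, base_mask].mean(axis=1)
    pct_comp = E[:, ~base_mask].mean(axis=1)

    padj = np.full(len(pvals), np.nan)
    tested = np.isfinite(pvals)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    with np.errstate(invalid="ignore"):
        significant = (
            tested
            & (padj < fdr_max)
            & ((pct_base > pct_min) | (pct_comp > pct_min))
            & (np.abs(np.nan_to_num(logfc)) > logfc_min)
        )
    direction = np.where(np.nan_to_num(logfc) > 0, "up", "down")
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "p": pvals,
            "padj": padj,
            "pct_base": pct_base,
            "pct_comp": pct_comp,
            "direction": direction,
            "significant": significant,
            "separation": flags % 2 == 1,
        },
        index=nm.gene_ids,
    )
    return DEResult(
        table=table,
        method="mixed",
        contrast=contrast,
        cluster=cluster,
        region=region,
        info={
            "n_cells": int(len(meta)),
            "n_donors": int(n_donors),
            "donor_handling": "random_intercept_pql" if use_donor else "pooled_fixed",
        },
    )


def bootstrap_de(
    nm: NormalizedMatrix,
    cell_meta: pd.DataFrame,
    donor_meta: pd.DataFrame,
    contrast: Contrast,
    n_iter: int = 100,
    frac: float = 0.5,
    min_support: int = 20,
    seed: int = 0,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    cluster: str | None = None,
    region: str | None = None,
) -> DEResult:
    """Half-sample bootstrap consensus over the hurdle test.

    Each iteration draws, without replacement, ``frac`` of the nuclei of each
    condition (stratified) and reruns the hurdle test with its published
    significance filters.  A gene passes with directional support >=
    ``min_support`` and zero significant iterations in the opposite
    direction.  Sampling is keyed to sorted cell ids, so support counts are
    bit-reproducible under a fixed seed and invariant to input cell order.
    """
    meta = cell_meta.join(donor_meta, on="donor_id", rsuffix="_donor")
    meta = meta[
        meta["pathology_group"].isin([contrast.baseline, contrast.comparison])
    ].sort_index()
    if len(meta) < 40:
        raise ValueError("bootstrap needs at least 40 cells in the contrast")

    by_group = {
        g: meta.index[meta["pathology_group"] == g].to_numpy()
        for g in (contrast.baseline, contrast.comparison)
    }
    support_up = pd.Series(0, index=nm.gene_ids, dtype=int)
    support_down = pd.Series(0, index=nm.gene_ids, dtype=int)
    failed = 0
    for it in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(it,)))
        chosen: list[np.ndarray] = []
        for g in (contrast.baseline, contrast.comparison):
            cells = by_group[g]
            take = int(np.floor(frac * len(cells)))
            chosen.append(rng.choice(cells, size=take, replace=False))
        sel = np.sort(np.concatenate(chosen))
        try:
            res = fit_hurdle_mixed(
                nm, cell_meta.loc[sel], donor_meta, contrast,
                covariates=covariates,
            )
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        sig = res.table["significant"].fillna(False)
        up = sig & (res.table["direction"] == "up")
        down = sig & (res.table["direction"] == "down")
        support_up[up.to_numpy()] += 1
        support_down[down.to_numpy()] += 1
    if failed > 0.2 * n_iter:
        warnings.warn(f"{failed}/{n_iter} bootstrap iterations failed", stacklevel=2)
    support, direction, passed = bootstrap_support_decision(
        support_up.to_numpy(), support_down.to_numpy(), min_support
    )
    table = pd.DataFrame(
        {
            "support_up": support_up,
            "support_down": support_down,
            "support": support,
            "direction": direction,
            "significant": passed,
        },
        index=nm.gene_ids,
    )
    return DEResult(
        table=table,
        method="bootstrap",
        contrast=contrast,
        cluster=cluster,
        region=region,
        info={"n_iter": n_iter, "frac": frac, "min_support": min_support,
              "failed_iterations": failed, "flagged": failed > 0.2 * n_iter},
    )


def bootstrap_support_decision(
    support_up: np.ndarray, support_down: np.ndarray, min_support: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The bootstrap retention rule: (support, direction, passed) per gene.

    A gene passes when its larger directional support reaches ``min_support``
    ("at least 20 of the 100 iterations") and the opposite direction was
    never called significant.
    """
    support_up = np.asarray(support_up)
    support_down = np.asarray(support_down)
    support = np.maximum(support_up, support_down)
    direction = np.where(support_up >= support_down, "up", "down")
    opposite = np.minimum(support_up, support_down)
    passed = (support >= min_support) & (opposite == 0)
    return support, direction, passed


# ------------------------------------------------------------- pseudobulk NB


def _nb_loglik(k: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    inv = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(k + inv)
            - special.gammaln(inv)
            - special.gammaln(k + 1.0)
            + k * np.log(alpha * mu / (1.0 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _nb_irls(k: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
             beta0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """NB GLM (log link, fixed dispersion alpha) via IRLS; returns (beta, W)."""
    n, p = X.shape
    beta = beta0.copy() if beta0 is not None else np.zeros(p)
    if beta0 is None:
        beta[0] = math.log(max(np.mean(k / np.exp(offset)), 1e-8))
    for _ in range(25):
        eta = X @ beta + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = eta - offset + (k - mu) / mu
        XtW = X.T * w
        try:
            new = np.linalg.solve(XtW @ X + 1e-10 * np.eye(p), XtW @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    return beta, w


def median_of_ratios(pb: pd.DataFrame) -> np.ndarray:
    """DESeq-style size factors for a donors x genes count table."""
    mat = pb.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite_gene = np.isfinite(logs).all(axis=0)
    if finite_gene.sum() >= 10:
        ref = logs[:, finite_gene].mean(axis=0)
        sf = np.exp(np.median(logs[:, finite_gene] - ref[None, :], axis=1))
    else:  # too few all-positive genes; fall back to library-size ratios
        lib = mat.sum(axis=1)
        sf = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def pseudobulk_de(
    pb: pd.DataFrame,
    n_expressing: pd.Series,
    donor_groups: pd.Series,
    contrast: Contrast,
    min_nuclei: int = 20,
    fdr_max: float = 0.05,
    cluster: str | None = None,
    region: str | None = None,
) -> DEResult:
    """Negative-binomial Wald test on donor-level pseudobulk counts.

    ``pb`` is donors x genes summed raw counts for one cluster;
    ``n_expressing`` counts nuclei with nonzero expression per gene (genes
    under ``min_nuclei`` are dropped before testing).  Per gene the NB GLM
    (log link, median-of-ratios size-factor offsets) is fitted with gene-wise
    ML dispersion; with <= 4 donors per group dispersions are shrunk halfway
    (in log space) toward a mean-dispersion trend before the Wald test.
    """
    donors = pb.index
    groups = donor_groups.loc[donors]
    keep_donor = groups.isin([contrast.baseline, contrast.comparison])
    pb = pb.loc[keep_donor]
    groups = groups[keep_donor]
    n_per = groups.value_counts()
    for g in (contrast.baseline, contrast.comparison):
        if n_per.get(g, 0) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 donors in pseudobulk")

    genes = [g for g in pb.columns if n_expressing.get(g, 0) >= min_nuclei]
    pb = pb[genes]
    sf = median_of_ratios(pb)
    offset = np.log(sf)
    cond = (groups == contrast.comparison).to_numpy(float)
    X = np.column_stack([np.ones(len(pb)), cond])
    small_n = min(n_per.get(contrast.baseline, 0), n_per.get(contrast.comparison, 0)) <= 4

    K = pb.to_numpy(dtype=float)
    n_genes = K.shape[1]
    alphas = np.empty(n_genes)
    betas = np.empty((n_genes, 2))
    means = np.empty(n_genes)
    for j in range(n_genes):
        k = K[:, j]
        means[j] = max(np.mean(k / sf), 1e-8)

        def neg_profile(log_alpha: float, k=k) -> float:
            a = 10.0**log_alpha
            b, _ = _nb_irls(k, X, offset, a)
            mu = np.exp(np.clip(X @ b + offset, -30, 30))
            return -_nb_loglik(k, np.maximum(mu, 1e-10), a)

        res = optimize.minimize_scalar(
            neg_profile, bounds=(-8.0, 2.0), method="bounded",
            options={"xatol": 0.05, "maxiter": 40},
        )
        alphas[j] = 10.0 ** float(res.x)

    if small_n and n_genes >= 10:
        # moderate: shrink log-dispersion halfway toward the a/mean + b trend
        with np.errstate(divide="ignore"):
            A = np.column_stack([1.0 / means, np.ones(n_genes)])
        coef, *_ = np.linalg.lstsq(A, alphas, rcond=None)
        trend = np.maximum(A @ coef, 1e-8)
        alphas = np.exp(0.5 * np.log(np.maximum(alphas, 1e-8)) + 0.5 * np.log(trend))

    pvals = np.empty(n_genes)
    logfc = np.empty(n_genes)
    for j in range(n_genes):
        k = K[:, j]
        beta, w = _nb_irls(k, X, offset, alphas[j])
        cov = np.linalg.inv((X.T * w) @ X + 1e-10 * np.eye(2))
        se = math.sqrt(max(cov[1, 1], 1e-30))
        z = beta[1] / se
        pvals[j] = 2.0 * stats.norm.sf(abs(z))
        logfc[j] = beta[1]
        betas[j] = beta
    padj = multipletests(pvals, method="fdr_bh")[1] if n_genes else np.array([])
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "p": pvals,
            "padj": padj,
            "dispersion": alphas,
            "direction": np.where(logfc > 0, "up", "down"),
            "significant": padj < fdr_max,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DEResult(
        table=table,
        method="pseudobulk",
        contrast=contrast,
        cluster=cluster,
        region=region,
        info={"min_nuclei": min_nuclei, "n_donors": int(len(pb)),
              "dispersion_moderated": bool(small_n)},
    )


# --------------------------------------------------------------- consensus


@dataclass
class HighConfidenceSet:
    """Genes called by the mixed model and corroborated by a second method."""

    table: pd.DataFrame  # gene x (direction, mixed, bootstrap, pseudobulk, coexpr_hub)
    contrast: Contrast
    cluster: str | None = None
    region: str | None = None
    direction_conflicts: list[str] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)


def consensus_high_confidence(
    mixed: DEResult,
    bootstrap: DEResult | None = None,
    pseudobulk: DEResult | None = None,
    hub_genes: set[str] | None = None,
) -> HighConfidenceSet:
    """Intersect the mixed model with its corroborating evidence.

    A gene is included iff it is mixed-significant AND (bootstrap-supported
    OR pseudobulk-significant with the same direction OR a co-expression hub
    member).  A corroborating method that is significant with the opposite
    direction disqualifies the gene entirely (recorded in
    ``direction_conflicts``).
    """
    for other in (bootstrap, pseudobulk):
        if other is not None and other.contrast != mixed.contrast:
            raise ValueError("all inputs must share the same contrast")
    rows = []
    conflicts = []
    hub_genes = hub_genes or set()
    for gene in mixed.significant_genes:
        direction = mixed.table.loc[gene, "direction"]
        flags = {"bootstrap": False, "pseudobulk": False, "coexpr_hub": gene in hub_genes}
        conflict = False
        for name, other in (("bootstrap", bootstrap), ("pseudobulk", pseudobulk)):
            if other is None or gene not in other.table.index:
                continue
            row = other.table.loc[gene]
            if bool(row["significant"]):
                if row["direction"] == direction:
                    flags[name] = True
                else:
                    conflict = True
        if conflict:
            conflicts.append(str(gene))
            continue
        if any(flags.values()):
            rows.append({"gene": gene, "direction": direction, "mixed": True, **flags})
    table = pd.DataFrame(
        rows, columns=["gene", "direction", "mixed", "bootstrap", "pseudobulk", "coexpr_hub"]
    ).set_index("gene")
    return HighConfidenceSet(
        table=table,
        contrast=mixed.contrast,
        cluster=mixed.cluster,
        region=mixed.region,
        direction_conflicts=conflicts,
    )


def intersect_conditions(
    hc_sets: dict[str, HighConfidenceSet | set],
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """UpSet-style membership matrix over >= 2 high-confidence sets.

    Returns (membership matrix genes x sets, genes shared in all sets,
    pairwise overlap counts).
    """
    if len(hc_sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    as_sets = {
        name: (s.genes if isinstance(s, HighConfidenceSet) else set(s))
        for name, s in hc_sets.items()
    }
    universe = sorted(set().union(*as_sets.values()))
    membership = pd.DataFrame(
        {name: [g in s for g in universe] for name, s in as_sets.items()},
        index=pd.Index(universe, name="gene"),
    )
    shared = [g for g in universe if membership.loc[g].all()]
    names = list(as_sets)
    pairwise = pd.DataFrame(0, index=names, columns=names)
    for a in names:
        for b in names:
            pairwise.loc[a, b] = len(as_sets[a] & as_sets[b])
    return membership, shared, pairwise
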