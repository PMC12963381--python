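"""Marker ranking and filtering, cosine cluster matching, kNN label transfer.

Marker statistics follow single-cell convention: ``pts`` / ``pts_rest`` are the
fractions of cells expressing the gene (nonzero) inside vs outside the
cluster, the p-value is a two-sided Wilcoxon rank-sum test of the cluster
against all other cells, and logFC compares mean expression on the natural
scale with a pseudocount.  The Wilcoxon null distribution is computed exactly
(tie-aware dynamic programming over rank sums) when both groups have at most
25 observations, and by the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .data import NormalizedMatrix

EXACT_MAX_N = 25
_PSEUDOCOUNT = 1e-9


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value; exact for small groups.

    The exact path enumerates the null distribution of the rank sum (with
    average ranks for ties) by dynamic-programming convolution; the two-sided
    p doubles the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return _exact_rank_sum_p(x, y)
    return _normal_rank_sum_p(x, y)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks2 = np.round(2.0 * stats.rankdata(combined)).astype(np.int64)  # half-integer ranks x2
    w_obs = int(ranks2[:n1].sum())
    max_sum = int(ranks2.sum())
    # dp[c, s] = number of subsets of size c with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        dp[1:, r:] += dp[:-1, : max_sum + 1 - r]
    dist = dp[n1]
    total = dist.sum()
    lo = dist[: w_obs + 1].sum() / total
    hi = dist[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def _normal_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (r1 - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


@dataclass
class MarkerStats:
    """Per-cluster marker tables: gene, logFC, pts, pts_rest, p, padj."""

    tables: dict[str, pd.DataFrame]
    logfc_base: str = "natural"

    def __getitem__(self, cluster: str) -> pd.DataFrame:
        return self.tables[cluster]

    @property
    def clusters(self) -> list[str]:
        return sorted(self.tables)


def rank_markers(
    nm: NormalizedMatrix, labels: pd.Series | np.ndarray, logfc_base: str = "natural"
) -> MarkerStats:
    """One-vs-rest Wilcoxon marker ranking for every cluster.

    logFC is computed on ``expm1`` of the mean log values with a pseudocount,
    in natural log by default (``logfc_base='log2'`` switches the scale; all
    downstream thresholds then apply on that scale).
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("marker ranking requires at least 2 clusters")
    values = nm.values
    n_genes, n_cells = values.shape
    expressed = values > 0
    log = np.log2 if logfc_base == "log2" else np.log
    tables = {}
    for cluster in clusters:
        in_c = labels == cluster
        if in_c.sum() < 2:
            raise ValueError(f"cluster {cluster} has fewer than 2 cells")
        n1, n2 = int(in_c.sum()), int((~in_c).sum())
        pts = expressed[:, in_c].mean(axis=1)
        pts_rest = expressed[:, ~in_c].mean(axis=1)
        mean_in = values[:, in_c].mean(axis=1)
        mean_rest = values[:, ~in_c].mean(axis=1)
        logfc = log(
            (np.expm1(mean_in) + _PSEUDOCOUNT) / (np.expm1(mean_rest) + _PSEUDOCOUNT)
        )
        if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
            pvals = np.array(
                [_exact_rank_sum_p(values[g, in_c], values[g, ~in_c]) for g in range(n_genes)]
            )
        else:
            pvals = _vectorized_normal_p(values, in_c)
        padj = multipletests(pvals, method="fdr_bh")[1]
        tables[str(cluster)] = pd.DataFrame(
            {
                "logFC": logfc,
                "pts": pts,
                "pts_rest": pts_rest,
                "p": pvals,
                "padj": padj,
            },
            index=nm.gene_ids,
        )
    return MarkerStats(tables=tables, logfc_base=logfc_base)


def _vectorized_normal_p(values: np.ndarray, in_c: np.ndarray) -> np.ndarray:
    n_genes, n = values.shape
    n1 = int(in_c.sum())
    n2 = n - n1
    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, in_c].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    tie_term = np.empty(n_genes)
    for g in range(n_genes):
        _, counts = np.unique(values[g], return_counts=True)
        tie_term[g] = (counts.astype(np.int64) ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(n_genes)
    ok = var > 0
    z = np.zeros(n_genes)
    z[ok] = (r1[ok] - mu) / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z[ok])))
    return p


def filter_markers(
    ms: MarkerStats,
    pts_min: float = 0.2,
    pts_rest_max: float = 0.1,
    ratio_min: float = 3.0,
    logfc_min: float = 1.5,
    padj_max: float = 0.05,
    overrides: dict[str, dict[str, float]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Apply the strict marker thresholds per cluster.

    All comparisons are strict as printed: pts > pts_min, pts_rest <
    pts_rest_max, pts/pts_rest > ratio_min (pts_rest = 0 passes the ratio
    test), logFC > logfc_min, padj < padj_max.  ``overrides`` relaxes
    thresholds for named clusters (e.g. broadly expressed subtypes).  Results
    are ordered by descending logFC.
    """
    out = {}
    for cluster in ms.clusters:
        thr = {
            "pts_min": pts_min,
            "pts_rest_max": pts_rest_max,
            "ratio_min": ratio_min,
            "logfc_min": logfc_min,
            "padj_max": padj_max,
        }
        if overrides and cluster in overrides:
            thr.update(overrides[cluster])
        t = ms[cluster]
        with np.errstate(divide="ignore"):
            ratio = np.where(t["pts_rest"] > 0, t["pts"] / t["pts_rest"], np.inf)
        keep = (
            (t["pts"] > thr["pts_min"])
            & (t["pts_rest"] < thr["pts_rest_max"])
            & (ratio > thr["ratio_min"])
            & (t["logFC"] > thr["logfc_min"])
            & (t["padj"] < thr["padj_max"])
        )
        sub = t[keep].sort_values("logFC", ascending=False, kind="stable")
        out[cluster] = sub
    return out


@dataclass
class ClusterDistanceMatrix:
    """Cosine distances between reference and query cluster mean profiles."""

    distances: pd.DataFrame  # reference clusters x query clusters
    top3: dict[str, list[str]]  # query cluster -> 3 nearest reference clusters
    flagged: list[str]  # clusters with zero mean profile (distance undefined)


def cosine_cluster_distance(
    ref_nm: NormalizedMatrix,
    ref_labels,
    query_nm: NormalizedMatrix,
    query_labels,
    gene_set: list[str] | None = None,
    n_hvg: int = 3000,
    n_top_markers: int = 10,
) -> ClusterDistanceMatrix:
    """1 - cosine similarity between cluster mean expression vectors.

    The gene set defaults to the union of each dataset's highly variable genes
    (top ``n_hvg``) and the top ``n_top_markers`` filtered markers per
    cluster, intersected with the shared gene universe.  Per query cluster the
    three nearest reference clusters are reported, ties broken by cluster id.
    """
    from .qc import select_hvg

    shared = ref_nm.gene_ids.intersection(query_nm.gene_ids)
    if gene_set is None:
        genes: set[str] = set()
        for nm, labels in ((ref_nm, ref_labels), (query_nm, query_labels)):
            genes.update(select_hvg(nm, n_top=n_hvg))
            filtered = filter_markers(rank_markers(nm, labels))
            for table in filtered.values():
                genes.update(table.index[:n_top_markers].astype(str))
        gene_set = sorted(genes)
    use = [g for g in gene_set if g in set(shared)]
    if not use:
        raise ValueError("empty shared gene universe after intersection")

    def _profiles(nm: NormalizedMatrix, labels) -> pd.DataFrame:
        labels = np.asarray(labels)
        idx = nm.gene_ids.get_indexer(use)
        cols = {}
        for cluster in np.unique(labels):
            cols[str(cluster)] = nm.values[idx][:, labels == cluster].mean(axis=1)
        return pd.DataFrame(cols, index=use)

    ref_prof = _profiles(ref_nm, ref_labels)
    query_prof = _profiles(query_nm, query_labels)
    flagged = [
        c for prof in (ref_prof, query_prof) for c in prof.columns if prof[c].abs().sum() == 0
    ]
    r = ref_prof.to_numpy().T  # ref clusters x genes
    q = query_prof.to_numpy().T
    rn = np.linalg.norm(r, axis=1)
    qn = np.linalg.norm(q, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (r @ q.T) / np.outer(rn, qn)
    dist = pd.DataFrame(1.0 - sim, index=ref_prof.columns, columns=query_prof.columns)
    top3 = {}
    for qc in dist.columns:
        order = sorted(dist.index, key=lambda rc: (dist.loc[rc, qc], rc))
        top3[qc] = order[:3]
    return ClusterDistanceMatrix(distances=dist, top3=top3, flagged=flagged)


def knn_label_transfer(
    ref_nm: NormalizedMatrix,
    ref_labels,
    query_nm: NormalizedMatrix,
    n_pcs: int = 15,
    k: int = 20,
    min_confidence: float = 0.0,
) -> pd.DataFrame:
    """Project query cells into the reference PCA space and vote among the
    ``k`` nearest reference cells.

    PCA is fitted on the reference only (centering by reference means), so no
    query statistics leak into the embedding.  Ties in the vote, or a vote
    fraction below ``min_confidence``, yield "unassigned".
    """
    ref_labels = np.asarray(ref_labels)
    shared = ref_nm.gene_ids.intersection(query_nm.gene_ids)
    if len(shared) < n_pcs:
        warnings.warn(
            f"shared panel has {len(shared)} genes < n_pcs={n_pcs}; reducing", stacklevel=2
        )
        n_pcs = len(shared)
    if k > ref_nm.values.shape[1]:
        raise ValueError("k exceeds reference size")
    ref_X = ref_nm.values[ref_nm.gene_ids.get_indexer(shared)].T
    query_X = query_nm.values[query_nm.gene_ids.get_indexer(shared)].T
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=0)
    ref_pcs = pca.fit_transform(ref_X)
    query_pcs = pca.transform(query_X)
    nn = NearestNeighbors(n_neighbors=k).fit(ref_pcs)
    _, idx = nn.kneighbors(query_pcs)
    labels, confidence = [], []
    for row in idx:
        votes = pd.Series(ref_labels[row]).value_counts()
        top = votes.iloc[0]
        if (votes == top).sum() > 1:
            labels.append("unassigned")
            confidence.append(top / k)
            continue
        frac = top / k
        labels.append(votes.index[0] if frac >= max(min_confidence, 1e-12) else "unassigned")
        confidence.append(frac)
    return pd.DataFrame(
        {"label": labels, "confidence": confidence}, index=query_nm.cell_ids
    )
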