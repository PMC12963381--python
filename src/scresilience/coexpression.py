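"""Metacell-based co-expression networks, modules, kME hubs and stability.

Correlations between genes are stabilised by aggregating each group's cells
into metacells (a seed cell averaged with its k-1 nearest neighbours in the
group's PCA space, with a cap on how many cells two metacells may share).
Gene-gene |correlation| is raised to a soft power chosen for approximate
scale-free topology, converted to a topological overlap matrix (TOM), and
modules are cut from average-linkage clustering of 1-TOM at a constant
height, then merged by eigengene correlation.  Hub genes are ranked by kME,
the correlation of each gene with its module eigengene; the top-50 kME genes
per module feed the DE consensus, and module stability is a bootstrap
best-match Jaccard over metacell resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .data import NormalizedMatrix


@dataclass
class MetacellMatrix:
    """Aggregated expression (genes x metacells) with member bookkeeping."""

    values: np.ndarray
    gene_ids: pd.Index
    members: list[np.ndarray]  # per metacell: member cell indices (size k)
    groups: list[str]  # per metacell: source group label
    k: int

    @property
    def n_metacells(self) -> int:
        return self.values.shape[1]


def build_metacells(
    nm: NormalizedMatrix,
    groups,
    k: int = 25,
    min_cells: int = 50,
    max_shared: int = 10,
    n_pcs: int = 15,
    seed: int = 0,
) -> MetacellMatrix:
    """Aggregate k-nearest-neighbour cells into metacells within each group.

    Groups with fewer than ``min_cells`` cells contribute no metacells.
    Candidate seed cells are visited in a seeded random order; a candidate is
    rejected if its metacell would share more than ``max_shared`` cells with
    any accepted metacell.
    """
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    cols, members, src = [], [], []
    for group in sorted(pd.unique(groups).astype(str)):
        idx = np.flatnonzero(groups.astype(str) == group)
        if len(idx) < min_cells:
            warnings.warn(
                f"group {group!r} has {len(idx)} < {min_cells} cells; skipped",
                stacklevel=2,
            )
            continue
        X = nm.values[:, idx].T  # cells x genes
        n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
        pcs = pca.fit_transform(X)
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=min(k, len(idx))).fit(pcs)
        _, neigh = nn.kneighbors(pcs)
        order = rng.permutation(len(idx))
        accepted: list[np.ndarray] = []
        for cand in order:
            mem = neigh[cand]
            ok = True
            for prev in accepted:
                if len(np.intersect1d(mem, prev, assume_unique=False)) > max_shared:
                    ok = False
                    break
            if ok:
                accepted.append(mem)
        for mem in accepted:
            cols.append(nm.values[:, idx[mem]].mean(axis=1))
            members.append(idx[mem])
            src.append(group)
    values = np.column_stack(cols) if cols else np.zeros((nm.values.shape[0], 0))
    return MetacellMatrix(values=values, gene_ids=nm.gene_ids, members=members,
                          groups=src, k=k)


def _adjacency(values: np.ndarray, power: float) -> np.ndarray:
    """Unsigned adjacency |cor|^power over metacells; constant genes get 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return np.abs(corr) ** power


def choose_soft_power(
    mc: MetacellMatrix | np.ndarray,
    powers: range = range(1, 21),
    target_r2: float = 0.8,
    n_bins: int = 10,
    min_connectivity: float = 0.1,
    connectivity_target: float = 0.5,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose degree distribution is approximately scale-free.

    For each candidate power the scale-free fit R^2 regresses log10 p(degree)
    on log10 degree over degree bins; the returned power is the smallest one
    with R^2 >= ``target_r2``.  Powers whose mean connectivity falls below
    ``min_connectivity`` are never chosen (raising the power further empties
    the network, and the scale-free R^2 plateaus into noise there).  When no
    eligible power reaches the R^2 target, the fallback picks the smallest
    power that brings mean connectivity down to ``connectivity_target`` -
    high enough to suppress the background, as small as possible to preserve
    strong correlations; unlike the noisy R^2 argmax this rule is monotone in
    the power.  The full scan table is returned alongside.
    """
    values = mc.values if isinstance(mc, MetacellMatrix) else np.asarray(mc)
    if values.shape[0] < 30:
        raise ValueError("need at least 30 genes for a soft-power scan")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    if np.allclose(np.abs(corr), 1.0):
        raise ValueError("degenerate correlation matrix")
    acorr = np.abs(corr)
    rows = []
    for power in powers:
        adj = acorr**power
        degree = adj.sum(axis=1) - 1.0
        r2 = _scale_free_r2(degree, n_bins)
        rows.append({"power": power, "r2": r2, "mean_connectivity": degree.mean()})
    scan = pd.DataFrame(rows)
    connected = scan[scan["mean_connectivity"] >= min_connectivity]
    if len(connected) == 0:
        connected = scan.iloc[[0]]
    ok = connected[connected["r2"] >= target_r2]
    if len(ok):
        power = int(ok["power"].iloc[0])
    else:
        low = connected[connected["mean_connectivity"] <= connectivity_target]
        power = int(low["power"].iloc[0]) if len(low) else int(connected["power"].iloc[-1])
    return power, scan


def _scale_free_r2(degree: np.ndarray, n_bins: int) -> float:
    """R^2 of log10 p(k) ~ log10 k over equal-width degree bins."""
    degree = degree[degree > 0]
    if len(degree) < n_bins:
        return 0.0
    edges = np.linspace(degree.min(), degree.max(), n_bins + 1)
    which = np.clip(np.digitize(degree, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(degree[mask].mean()))
        ys.append(np.log10(mask.sum() / len(degree)))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Unsigned TOM; entries in [0, 1], diagonal exactly 1."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    degree = a.sum(axis=1)
    numer = a @ a + a
    denom = np.minimum.outer(degree, degree) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = numer / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


@dataclass
class ModuleSet:
    """Gene-module assignment with eigengenes, kME and hub rankings.

    Module 0 is the unassigned ("grey") pool.  Eigengenes are the first
    principal component of each module's standardized genes over metacells,
    sign-oriented so the mean member correlation is positive.
    """

    assignments: pd.Series  # gene -> module id (0 = grey)
    eigengenes: pd.DataFrame  # metacells x modules
    kme: pd.DataFrame = field(default_factory=pd.DataFrame)  # genes x modules
    top10: dict[int, list[str]] = field(default_factory=dict)
    top50: dict[int, list[str]] = field(default_factory=dict)
    power: int = 6

    @property
    def module_ids(self) -> list[int]:
        return sorted(m for m in self.assignments.unique() if m != 0)

    def members(self, module: int) -> list[str]:
        return list(self.assignments.index[self.assignments == module])


def detect_modules(
    mc: MetacellMatrix,
    power: int,
    min_module_size: int = 30,
    merge_height: float = 0.25,
    cut_height: float = 0.99,
    kme_rescue: float = 0.5,
) -> ModuleSet:
    """Cut modules from average-linkage clustering of the TOM dissimilarity.

    Clusters from a constant-height cut at ``cut_height`` of 1-TOM are kept
    when they have >= ``min_module_size`` genes; modules whose eigengenes
    correlate >= 1 - ``merge_height`` are merged.  Unassigned genes form
    module 0, except that a grey gene whose kME to some module eigengene
    reaches ``kme_rescue`` is reassigned to that module (the usual
    module-membership reassignment pass, which recovers weakly connected
    members the constant-height cut trims off).
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    adj = _adjacency(mc.values, power)
    tom = topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    next_id = 1
    for cl in np.unique(raw):
        mask = raw == cl
        if mask.sum() >= min_module_size:
            labels[mask] = next_id
            next_id += 1
    if next_id == 1:
        warnings.warn("no module exceeds min_module_size; all genes grey", stacklevel=2)
        assignments = pd.Series(labels, index=mc.gene_ids)
        return ModuleSet(assignments=assignments, eigengenes=pd.DataFrame(), power=power)

    labels = _merge_modules(mc.values, labels, merge_height)
    if kme_rescue is not None and kme_rescue > 0:
        eigengenes = _eigengenes(mc.values, labels)
        modules = list(eigengenes.columns)
        grey = np.flatnonzero(labels == 0)
        if len(grey) and modules:
            vals = mc.values[grey]
            kmes = np.column_stack([
                _corr_with(vals, eigengenes[m].to_numpy()) for m in modules
            ])
            best = np.argmax(np.abs(kmes), axis=1)
            for row, g in enumerate(grey):
                if abs(kmes[row, best[row]]) >= kme_rescue:
                    labels[g] = modules[best[row]]
    eigengenes = _eigengenes(mc.values, labels)
    assignments = pd.Series(labels, index=mc.gene_ids)
    ms = ModuleSet(assignments=assignments, eigengenes=eigengenes, power=power)
    compute_kme(mc, ms)
    return ms


def _corr_with(values: np.ndarray, vector: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of ``values`` (genes x n) with a vector."""
    gstd = values.std(axis=1)
    vstd = vector.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = ((values - values.mean(axis=1, keepdims=True)) @ (vector - vector.mean())) / len(vector)
        return np.where((gstd > 0) & (vstd > 0), cov / (gstd * vstd), 0.0)


def _eigengenes(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    cols = {}
    for module in sorted(set(labels) - {0}):
        sub = values[labels == module]  # genes x metacells
        std = sub.std(axis=1, keepdims=True)
        std[std == 0] = 1.0
        zs = (sub - sub.mean(axis=1, keepdims=True)) / std
        pca = PCA(n_components=1)
        eig = pca.fit_transform(zs.T).ravel()
        mean_corr = np.mean([np.corrcoef(eig, g)[0, 1] for g in sub])
        if mean_corr < 0:
            eig = -eig
        cols[module] = eig
    return pd.DataFrame(cols)


def _merge_modules(values: np.ndarray, labels: np.ndarray, merge_height: float) -> np.ndarray:
    while True:
        modules = sorted(set(labels) - {0})
        if len(modules) < 2:
            break
        eig = _eigengenes(values, labels)
        corr = eig.corr().to_numpy()
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < 1.0 - merge_height:
            break
        a, b = modules[i], modules[j]
        labels[labels == b] = a
    # relabel consecutively by size (largest = 1)
    modules = sorted(set(labels) - {0}, key=lambda m: -(labels == m).sum())
    out = np.zeros_like(labels)
    for new, old in enumerate(modules, start=1):
        out[labels == old] = new
    return out


def compute_kme(mc: MetacellMatrix, ms: ModuleSet,
                n_top: int = 10, n_retain: int = 50) -> ModuleSet:
    """kME(gene, module) = Pearson correlation with the module eigengene.

    Populates the kME matrix and the per-module top-10 hub and top-50
    retained lists (descending kME, ties broken by gene id).  Constant genes
    get kME 0 by convention.
    """
    if ms.eigengenes.empty:
        ms.kme = pd.DataFrame(index=mc.gene_ids)
        return ms
    values = mc.values
    gstd = values.std(axis=1)
    kme = {}
    for module in ms.eigengenes.columns:
        eig = ms.eigengenes[module].to_numpy()
        estd = eig.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = ((values - values.mean(axis=1, keepdims=True)) @ (eig - eig.mean())) / len(eig)
            k = np.where((gstd > 0) & (estd > 0), cov / (gstd * estd), 0.0)
        kme[module] = k
    ms.kme = pd.DataFrame(kme, index=mc.gene_ids)
    ms.top10, ms.top50 = {}, {}
    for module in ms.module_ids:
        member_genes = ms.members(module)
        ranked = sorted(member_genes, key=lambda g: (-ms.kme.loc[g, module], g))
        ms.top10[module] = ranked[:n_top]
        ms.top50[module] = ranked[:n_retain]
    return ms


def module_stability(
    mc: MetacellMatrix,
    ms: ModuleSet,
    n_boot: int = 100,
    seed: int = 0,
    min_module_size: int = 30,
    merge_height: float = 0.25,
) -> pd.Series:
    """Bootstrap stability: mean best-match Jaccard per reference module.

    Each iteration resamples metacells with replacement, re-detects modules
    at the same soft power, and records the best Jaccard overlap of each
    reference module with any resampled module.
    """
    if not ms.module_ids:
        return pd.Series(dtype=float)
    ref_members = {m: set(ms.members(m)) for m in ms.module_ids}
    rng = np.random.default_rng(seed)
    scores = {m: [] for m in ms.module_ids}
    for _ in range(n_boot):
        take = rng.integers(0, mc.n_metacells, size=mc.n_metacells)
        sub = MetacellMatrix(
            values=mc.values[:, take],
            gene_ids=mc.gene_ids,
            members=[mc.members[t] for t in take],
            groups=[mc.groups[t] for t in take],
            k=mc.k,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boot_ms = detect_modules(sub, ms.power, min_module_size, merge_height)
        boot_members = [set(boot_ms.members(m)) for m in boot_ms.module_ids]
        for m, ref in ref_members.items():
            best = 0.0
            for cand in boot_members:
                inter = len(ref & cand)
                union = len(ref | cand)
                if union and inter / union > best:
                    best = inter / union
            scores[m].append(best)
    return pd.Series({m: float(np.mean(v)) for m, v in scores.items()}, name="stability")


def module_de_summary(ms: ModuleSet, de_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per module x contrast: mean logFC over members and count of DE members."""
    rows = []
    for module in ms.module_ids:
        member_genes = ms.members(module)
        for contrast, table in de_tables.items():
            present = [g for g in member_genes if g in table.index]
            sub = table.loc[present]
            n_de = int(sub["significant"].fillna(False).sum()) if "significant" in sub else 0
            mean_lfc = float(sub["logFC"].mean()) if len(sub) else np.nan
            rows.append(
                {"module": module, "contrast": contrast,
                 "mean_logFC": mean_lfc, "n_de_members": n_de,
                 "n_members": len(member_genes)}
            )
    return pd.DataFrame(rows)
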