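"""Cell filtering, log normalization, HVG selection and pseudobulk aggregation."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import CohortDataset, NormalizedMatrix


def filter_cells(
    ds: CohortDataset, min_genes: int = 300, max_mito: float = 0.05
) -> CohortDataset:
    """Drop cells with fewer than ``min_genes`` detected genes or mitochondrial
    fraction above ``max_mito``; surviving cell order is preserved."""
    if min_genes <= 0 or max_mito <= 0:
        raise ValueError("thresholds must be positive")
    ngd = ds.cell_meta["n_genes_detected"].to_numpy()
    mito = ds.cell_meta["mito_fraction"].to_numpy()
    keep = (ngd >= min_genes) & (mito <= max_mito)
    if not keep.any():
        warnings.warn("no cells pass QC filters", stacklevel=2)
    return ds.subset_cells(keep)


def normalize_log(ds: CohortDataset) -> NormalizedMatrix:
    """Scale each cell's library to the median library size, then log1p.

    All-zero cells have no defined size factor; they are flagged (warning) and
    dropped from the output.
    """
    if ds.n_cells == 0:
        raise ValueError("empty dataset")
    libs = np.asarray(ds.counts.sum(axis=0), dtype=float).ravel()
    nonzero = libs > 0
    if not nonzero.all():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} all-zero cells from normalization",
            stacklevel=2,
        )
    libs_nz = libs[nonzero]
    median_lib = float(np.median(libs_nz))
    size_factors = libs_nz / median_lib
    dense = np.asarray(ds.counts[:, np.flatnonzero(nonzero)].todense(), dtype=float)
    values = np.log1p(dense / size_factors[None, :])
    return NormalizedMatrix(
        values=values,
        size_factors=size_factors,
        gene_ids=ds.gene_ids,
        cell_ids=ds.cell_meta.index[nonzero],
    )


def select_hvg(
    nm: NormalizedMatrix,
    n_top: int = 3000,
    dispersion_threshold: float = 0.5,
    n_bins: int = 20,
) -> list[str]:
    """Rank genes by bin-normalized dispersion and return the top ``n_top``
    among those exceeding ``dispersion_threshold``.

    Dispersion = variance / mean of the log-normalized values; genes are
    placed in ``n_bins`` equal-occupancy mean-expression bins and their
    dispersions z-scored within each bin.  Ties (and the ordering of the
    returned list) are broken lexicographically by gene id.
    """
    if nm.values.shape[1] < 2:
        raise ValueError("HVG selection needs at least 2 cells")
    mean = nm.values.mean(axis=1)
    var = nm.values.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.minimum(
        (np.arange(len(mean)) * n_bins) // max(len(mean), 1), n_bins - 1
    )
    z = np.zeros(len(mean))
    for b in np.unique(bins):
        sel = bins == b
        d = disp[sel]
        sd = d.std(ddof=0)
        z[sel] = (d - d.mean()) / sd if sd > 0 else 0.0
    qualifying = np.flatnonzero(z > dispersion_threshold)
    ranked = sorted(
        qualifying, key=lambda g: (-z[g], str(nm.gene_ids[g]))
    )
    return [str(nm.gene_ids[g]) for g in ranked[:n_top]]


def pseudobulk_aggregate(
    ds: CohortDataset, group_by: tuple[str, ...] = ("donor_id", "cluster")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum raw counts over cells of each donor x cluster group.

    Returns ``(pseudobulk, n_expressing)``: both are groups x genes, the first
    holding exact integer sums and the second the number of nuclei with
    nonzero expression (used by the pseudobulk DE gene filter).
    """
    keys = ds.cell_meta[list(group_by)].astype(str).agg("|".join, axis=1)
    codes, uniques = pd.factorize(keys, sort=True)
    n_groups = len(uniques)
    indicator = np.zeros((ds.n_cells, n_groups))
    indicator[np.arange(ds.n_cells), codes] = 1.0
    sums = (ds.counts @ indicator).T  # groups x genes
    expressing = ((ds.counts > 0).astype(np.int64) @ indicator).T
    idx = pd.Index(uniques, name="|".join(group_by))
    pb = pd.DataFrame(sums.astype(np.int64), index=idx, columns=ds.gene_ids)
    nexp = pd.DataFrame(expressing.astype(np.int64), index=idx, columns=ds.gene_ids)
    return pb, nexp
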