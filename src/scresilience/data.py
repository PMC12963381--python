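"""Core in-memory containers and their on-disk text layouts.

The common currency of the pipeline is a sparse gene-by-cell count matrix with
two annotation tables: per-cell metadata (donor, region, cluster, QC stats) and
per-donor covariates (pathology group, sex, age, APOE, assay, RIN).  Spatial
panels and fluorescence traces get their own small containers.  Everything
serialises to plain-text formats: Matrix Market for sparse counts, TSV/CSV for
tables, JSON for ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

PATHOLOGY_GROUPS = ("low", "intermediate", "high")

CELL_META_COLUMNS = [
    "donor_id",
    "region",
    "cluster",
    "n_genes_detected",
    "mito_fraction",
    "total_counts",
]
DONOR_META_COLUMNS = ["pathology_group", "sex", "age", "APOE", "assay", "RIN"]


@dataclass
class CohortDataset:
    """Sparse gene-by-cell counts plus cell- and donor-level annotations.

    ``counts`` is genes x cells (CSR, non-negative integers).  ``cell_meta`` is
    indexed by barcode and aligned with the columns of ``counts``;
    ``donor_meta`` is indexed by donor id.
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_meta: pd.DataFrame
    donor_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.cell_meta)):
            raise ValueError("counts shape does not match gene/cell annotations")
        if (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.cell_meta["donor_id"]) - set(self.donor_meta.index)
        if missing:
            raise ValueError(f"cells reference unknown donors: {sorted(missing)[:5]}")
        mf = self.cell_meta["mito_fraction"].to_numpy()
        if ((mf < 0) | (mf > 1)).any():
            raise ValueError("mito_fraction outside [0, 1]")
        ngd = self.cell_meta["n_genes_detected"].to_numpy()
        observed = np.asarray((self.counts > 0).sum(axis=0)).ravel()
        if not np.array_equal(ngd, observed):
            raise ValueError("n_genes_detected inconsistent with counts")

    def subset_cells(self, mask: np.ndarray) -> "CohortDataset":
        """Column subset preserving cell order; donor table untouched."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CohortDataset(
            counts=self.counts[:, idx].tocsr(),
            gene_ids=self.gene_ids,
            cell_meta=self.cell_meta.iloc[idx].copy(),
            donor_meta=self.donor_meta.copy(),
        )

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "counts.mtx"), self.counts.tocoo(), field="integer")
        pd.Series(self.gene_ids).to_csv(
            path / "features.tsv", sep="\t", index=False, header=False
        )
        pd.Series(self.cell_meta.index).to_csv(
            path / "barcodes.tsv", sep="\t", index=False, header=False
        )
        self.cell_meta.to_csv(path / "cell_metadata.tsv", sep="\t")
        self.donor_meta.to_csv(path / "donor_metadata.tsv", sep="\t")

    @classmethod
    def read_dir(cls, path: str | Path) -> "CohortDataset":
        path = Path(path)
        counts = sp.csr_matrix(mmread(str(path / "counts.mtx")))
        genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0]
        cell_meta = pd.read_csv(path / "cell_metadata.tsv", sep="\t", index_col=0)
        donor_meta = pd.read_csv(path / "donor_metadata.tsv", sep="\t", index_col=0)
        return cls(counts, pd.Index(genes), cell_meta, donor_meta)


@dataclass
class NormalizedMatrix:
    """Log-scale normalized expression (genes x cells) with per-cell size factors.

    ``values = log1p(counts / size_factor)`` where size factors rescale each
    library to the cohort's median library size; ``exp`` recovers the scaled
    counts exactly.
    """

    values: np.ndarray
    size_factors: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.size_factors = np.asarray(self.size_factors, dtype=np.float64)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)


@dataclass
class SpatialDataset:
    """Spatial cells with micrometer coordinates and panel-gene counts.

    Coordinates are 0-based with y increasing downward (image convention).
    """

    cells: pd.DataFrame  # index cell_id, columns x_um, y_um [, true_type]
    counts: sp.csr_matrix  # genes x cells
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")

    @property
    def total_transcripts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(path / "cells.csv")
        mmwrite(str(path / "counts.mtx"), self.counts.tocoo(), field="integer")
        pd.Series(self.gene_ids).to_csv(
            path / "panel_genes.tsv", sep="\t", index=False, header=False
        )

    @classmethod
    def read_dir(cls, path: str | Path) -> "SpatialDataset":
        path = Path(path)
        cells = pd.read_csv(path / "cells.csv", index_col=0)
        counts = sp.csr_matrix(mmread(str(path / "counts.mtx")))
        genes = pd.read_csv(path / "panel_genes.tsv", sep="\t", header=None)[0]
        return cls(cells, counts, pd.Index(genes))


@dataclass
class CalciumTraceSet:
    """Fluorescence traces sampled at a common rate, with well/field metadata."""

    traces: pd.DataFrame  # rows = samples, columns = trace ids
    rate_hz: float
    trace_meta: pd.DataFrame  # index trace_id; well_id, field_id, condition

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.traces) / self.rate_hz

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        t = np.arange(len(self.traces)) / self.rate_hz
        long = self.traces.copy()
        long.insert(0, "t_s", t)
        long = long.melt(id_vars="t_s", var_name="trace_id", value_name="F")
        long[["trace_id", "t_s", "F"]].to_csv(path / "traces.csv", index=False)
        self.trace_meta.to_csv(path / "trace_metadata.csv")

    @classmethod
    def read_dir(cls, path: str | Path, rate_hz: float) -> "CalciumTraceSet":
        path = Path(path)
        long = pd.read_csv(path / "traces.csv")
        wide = long.pivot(index="t_s", columns="trace_id", values="F")
        wide = wide.sort_index().reset_index(drop=True)
        wide.columns.name = None
        meta = pd.read_csv(path / "trace_metadata.csv", index_col=0)
        return cls(wide, rate_hz, meta)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort, for recovery tests."""

    de_genes: dict = field(default_factory=dict)  # cluster -> {gene: sign}
    comp_effects: dict = field(default_factory=dict)  # cell type -> log2 shift
    module_membership: dict = field(default_factory=dict)  # gene -> module id
    marker_genes: dict = field(default_factory=dict)  # cell type -> [genes]
    calcium_event_times: dict = field(default_factory=dict)  # trace -> [sec]

    def validate(self, gene_universe=None) -> None:
        if gene_universe is not None:
            universe = set(gene_universe)
            for cluster, genes in self.de_genes.items():
                stray = set(genes) - universe
                if stray:
                    raise ValueError(f"planted DE genes outside universe: {stray}")
        seen: dict[str, int] = {}
        for gene, module in self.module_membership.items():
            if gene in seen and seen[gene] != module:
                raise ValueError(f"gene {gene} assigned to two modules")
            seen[gene] = module

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "comp_effects": self.comp_effects,
            "module_membership": self.module_membership,
            "marker_genes": self.marker_genes,
            "calcium_event_times": self.calcium_event_times,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)
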