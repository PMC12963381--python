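"""Synthetic cohort, spatial-panel and calcium-trace generators with known truth.

The cohort generator emulates the data model the downstream analyses assume:
donor-structured negative-binomial gene counts with logistic dropout, a
Dirichlet-multinomial compositional layer whose cell-type proportions shift
with pathology group, planted differentially expressed genes, cell-type marker
genes, and latent-factor co-expression modules.  Pathology groups are scored
0 / 0.5 / 1 (low / intermediate / high) for compositional effects, so
``comp_log2fc`` is the total high-vs-low log2 shift of a type's relative
abundance; expression effects use 0 / 1 / 2 so ``de_log2fc`` is the log2
fold change of each adjacent-stage contrast (early: intermediate vs low,
late: high vs intermediate).

All randomness flows from one top-level seed through hierarchical
``SeedSequence`` substreams (one per donor), so regenerating a donor is
reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import (
    PATHOLOGY_GROUPS,
    CalciumTraceSet,
    CohortDataset,
    GroundTruth,
    SpatialDataset,
)

_COMP_SCORE = {"low": 0.0, "intermediate": 0.5, "high": 1.0}
_DE_SCORE = {"low": 0.0, "intermediate": 1.0, "high": 2.0}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``nb_dispersion`` is the negative-binomial shape theta, so a count with
    mean mu has variance mu + mu^2/theta.  ``dropout_midpoint`` is the
    (natural) log mean at which the logistic detection probability is 0.5.
    ``module_strength`` is the latent-factor loading scale (log-mean units)
    of planted co-expression modules.
    """

    n_donors_per_group: int = 10
    n_celltypes: int = 8
    baseline_props: np.ndarray | None = None
    comp_log2fc: np.ndarray | None = None
    n_genes: int = 2000
    n_de_genes: int = 0
    de_log2fc: float = 0.0
    donor_sd: float = 0.15
    nb_dispersion: float = 2.0
    dropout_midpoint: float = -2.0
    dropout_slope: float = 1.0
    n_modules: int = 0
    module_size: int = 50
    module_strength: float = 0.0
    n_cells_per_donor: int = 2000
    dm_concentration: float = 150.0
    n_marker_genes_per_type: int = 10
    marker_log2fc: float = 3.0
    n_mito_genes: int = 5
    region: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_props is None:
            self.baseline_props = np.full(self.n_celltypes, 1.0 / self.n_celltypes)
        self.baseline_props = np.asarray(self.baseline_props, dtype=float)
        if self.comp_log2fc is None:
            self.comp_log2fc = np.zeros(self.n_celltypes)
        self.comp_log2fc = np.asarray(self.comp_log2fc, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.baseline_props) != self.n_celltypes:
            raise ValueError("baseline_props length must equal n_celltypes")
        if abs(self.baseline_props.sum() - 1.0) > 1e-9:
            raise ValueError("baseline_props must sum to 1 within 1e-9")
        if (self.baseline_props <= 0).any():
            raise ValueError("baseline_props must be strictly positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name in ("n_donors_per_group", "n_celltypes", "n_genes", "n_cells_per_donor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dm_concentration <= 0:
            raise ValueError("dm_concentration must be positive")

    @property
    def celltypes(self) -> list[str]:
        return [f"T{k}" for k in range(self.n_celltypes)]

    @property
    def gene_names(self) -> pd.Index:
        names = [f"G{i:05d}" for i in range(self.n_genes - self.n_mito_genes)]
        names += [f"MT-S{i}" for i in range(self.n_mito_genes)]
        return pd.Index(names, name="gene_id")


def _draw_donor_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in PATHOLOGY_GROUPS:
        for i in range(config.n_donors_per_group):
            rows.append(
                {
                    "donor_id": f"D{group[:3]}{i:02d}",
                    "pathology_group": group,
                    "sex": rng.choice(["F", "M"]),
                    "age": float(np.clip(rng.normal(75.0, 8.0), 55.0, 95.0)),
                    "APOE": rng.choice(["E3/E3", "E3/E4", "E4/E4"], p=[0.6, 0.3, 0.1]),
                    "assay": rng.choice(["10xv2", "10xv3", "Dropseq"], p=[0.4, 0.4, 0.2]),
                    "RIN": float(np.clip(rng.normal(7.0, 0.8), 5.0, 10.0)),
                }
            )
    return pd.DataFrame(rows).set_index("donor_id")


def _donor_type_props(config: CohortConfig, group: str) -> np.ndarray:
    shifted = config.baseline_props * 2.0 ** (config.comp_log2fc * _COMP_SCORE[group])
    return shifted / shifted.sum()


def simulate_composition(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw only the compositional margin of the cohort: donor x type counts.

    Returns (counts, donor_meta); counts rows align with donor_meta rows.
    This is the same Dirichlet-multinomial layer :func:`simulate_cohort` uses,
    exposed separately so compositional studies need not synthesise expression.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    donor_meta = _draw_donor_table(config, rng)
    donor_streams = ss.spawn(len(donor_meta))
    counts = np.zeros((len(donor_meta), config.n_celltypes), dtype=np.int64)
    for d, (donor_id, row) in enumerate(donor_meta.iterrows()):
        drng = np.random.default_rng(donor_streams[d])
        p = _donor_type_props(config, row["pathology_group"])
        alpha = config.dm_concentration * p
        probs = drng.dirichlet(alpha)
        counts[d] = drng.multinomial(config.n_cells_per_donor, probs)
    table = pd.DataFrame(counts, index=donor_meta.index, columns=config.celltypes)
    return table, donor_meta


def _gene_parameters(config: CohortConfig, rng: np.random.Generator):
    """Base means, planted marker/DE/module structure over the gene universe."""
    n = config.n_genes
    base_mean = rng.lognormal(mean=np.log(0.3), sigma=1.2, size=n)
    # mitochondrial genes: moderate constant expression so mito_fraction is
    # small but nonzero for typical cells
    mito_idx = np.arange(n - config.n_mito_genes, n)
    base_mean[mito_idx] = 2.0

    gene_names = config.gene_names
    usable = np.arange(n - config.n_mito_genes)
    perm = rng.permutation(usable)
    cursor = 0

    marker_idx = {}
    for k, ct in enumerate(config.celltypes):
        take = perm[cursor : cursor + config.n_marker_genes_per_type]
        cursor += config.n_marker_genes_per_type
        marker_idx[ct] = take
    de_idx = perm[cursor : cursor + config.n_de_genes]
    cursor += config.n_de_genes
    de_signs = np.where(np.arange(config.n_de_genes) % 2 == 0, 1, -1)

    module_idx = {}
    loadings = np.zeros(n)
    module_of = np.full(n, -1)
    for m in range(config.n_modules):
        take = perm[cursor : cursor + config.module_size]
        cursor += config.module_size
        module_idx[m] = take
        # the first gene is the planted hub, with a clearly largest loading;
        # the rest taper off so kME ranking has a well-defined truth
        member_loadings = np.concatenate(
            [[1.0], np.linspace(0.7, 0.45, config.module_size - 1)]
        )
        loadings[take] = member_loadings * config.module_strength
        module_of[take] = m
    if cursor > len(usable):
        raise ValueError("n_genes too small for requested markers/DE/modules")

    # planted-structure genes sit in the moderately expressed regime so that
    # recovery measures the analysis machinery, not detection limits; markers
    # are near-exclusive (low off-type expression, elevated in their own type)
    for take in marker_idx.values():
        base_mean[take] = 0.08
    base_mean[de_idx] = np.maximum(base_mean[de_idx], 1.0)
    # module members share one moderate expression level so that kME ranking
    # reflects the planted loadings rather than per-gene sampling noise
    for take in module_idx.values():
        base_mean[take] = 2.0

    truth = GroundTruth(
        de_genes={
            ct: {gene_names[g]: int(s) for g, s in zip(de_idx, de_signs)}
            for ct in config.celltypes
        }
        if config.n_de_genes and config.de_log2fc != 0
        else {},
        comp_effects={
            ct: float(config.comp_log2fc[k])
            for k, ct in enumerate(config.celltypes)
            if config.comp_log2fc[k] != 0
        },
        module_membership={
            gene_names[g]: m for m, take in module_idx.items() for g in take
        }
        if config.module_strength > 0
        else {},
        marker_genes={ct: [gene_names[g] for g in take] for ct, take in marker_idx.items()},
    )
    return base_mean, marker_idx, de_idx, de_signs, module_idx, loadings, truth


def simulate_cohort(config: CohortConfig) -> tuple[CohortDataset, GroundTruth]:
    """Generate a full synthetic cohort with recorded ground truth.

    Per donor, cell-type counts follow a Dirichlet-multinomial around the
    group-shifted baseline proportions; per cell, gene counts are negative
    binomial with mean = base mean x marker multiplier x donor random effect x
    condition effect (planted DE genes) x module latent factor, thinned by a
    per-gene-per-cell logistic detection curve.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    donor_meta = _draw_donor_table(config, rng)
    base_mean, marker_idx, de_idx, de_signs, module_idx, loadings, truth = _gene_parameters(
        config, rng
    )

    # marker multipliers per cell type (genes x types)
    marker_mult = np.ones((config.n_genes, config.n_celltypes))
    for k, ct in enumerate(config.celltypes):
        marker_mult[marker_idx[ct], k] = 2.0 ** config.marker_log2fc

    theta = config.nb_dispersion
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    mito_mask[config.n_genes - config.n_mito_genes :] = True

    donor_streams = ss.spawn(len(donor_meta))
    blocks, meta_rows = [], []
    for d, (donor_id, row) in enumerate(donor_meta.iterrows()):
        drng = np.random.default_rng(donor_streams[d])
        p = _donor_type_props(config, row["pathology_group"])
        probs = drng.dirichlet(config.dm_concentration * p)
        type_counts = drng.multinomial(config.n_cells_per_donor, probs)
        donor_factor = float(np.exp(drng.normal(0.0, config.donor_sd)))
        t_score = _DE_SCORE[row["pathology_group"]]

        de_mult = np.ones(config.n_genes)
        if config.n_de_genes:
            de_mult[de_idx] = 2.0 ** (config.de_log2fc * t_score * de_signs)

        for k, ct in enumerate(config.celltypes):
            n_c = int(type_counts[k])
            if n_c == 0:
                continue
            mu = base_mean * marker_mult[:, k] * donor_factor * de_mult
            log_mu = np.log(mu)[:, None] * np.ones((1, n_c))
            if module_idx:
                for m, take in module_idx.items():
                    f = drng.normal(0.0, 1.0, size=n_c)
                    log_mu[take] += loadings[take][:, None] * f[None, :]
            mu_cells = np.exp(log_mu)
            counts = drng.negative_binomial(theta, theta / (theta + mu_cells))
            p_detect = 1.0 / (
                1.0 + np.exp(-(log_mu - config.dropout_midpoint) / config.dropout_slope)
            )
            keep = drng.random(mu_cells.shape) < p_detect
            counts = counts * keep
            blocks.append(sp.csc_matrix(counts))
            for j in range(n_c):
                meta_rows.append((donor_id, ct))

    counts = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((config.n_genes, 0))
    barcodes = [f"cell{i:06d}" for i in range(counts.shape[1])]
    donor_ids = [r[0] for r in meta_rows]
    clusters = [r[1] for r in meta_rows]
    total = np.asarray(counts.sum(axis=0)).ravel()
    ngd = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_counts = np.asarray(counts[mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    cell_meta = pd.DataFrame(
        {
            "donor_id": donor_ids,
            "region": config.region,
            "cluster": clusters,
            "n_genes_detected": ngd.astype(int),
            "mito_fraction": mito_frac,
            "total_counts": total.astype(int),
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    ds = CohortDataset(counts, config.gene_names, cell_meta, donor_meta)
    truth.validate(gene_universe=config.gene_names)
    return ds, truth


def simulate_spatial(
    n_cells: int,
    celltype_profiles: pd.DataFrame,
    layer_layout: Sequence[tuple[str, float, float]],
    noise_rate: float = 0.0,
    seed: int = 0,
    width_um: float = 1000.0,
) -> SpatialDataset:
    """Place cells in horizontal layer bands and draw Poisson panel counts.

    ``celltype_profiles`` is types x panel genes of expected counts per cell;
    ``layer_layout`` is a sequence of (type, y_min, y_max) bands.  Each gene
    additionally receives Poisson(``noise_rate``) uniform background
    ("spillover") counts.
    """
    if celltype_profiles.shape[1] == 0:
        raise ValueError("empty gene panel")
    if (celltype_profiles.to_numpy() < 0).any():
        raise ValueError("negative expected counts in profiles")
    if noise_rate < 0:
        raise ValueError("negative noise rate")
    for ct, *_ in layer_layout:
        if ct not in celltype_profiles.index:
            raise ValueError(f"layer type {ct} has no expression profile")

    rng = np.random.default_rng(seed)
    bands = list(layer_layout)
    band_of_cell = rng.integers(0, len(bands), size=n_cells)
    x = rng.uniform(0.0, width_um, size=n_cells)
    y = np.empty(n_cells)
    types = np.empty(n_cells, dtype=object)
    for i, b in enumerate(band_of_cell):
        ct, y0, y1 = bands[b]
        y[i] = rng.uniform(y0, y1)
        types[i] = ct
    profiles = celltype_profiles.to_numpy(dtype=float)
    type_index = {ct: k for k, ct in enumerate(celltype_profiles.index)}
    lam = profiles[[type_index[t] for t in types]]  # cells x genes
    counts = rng.poisson(lam)
    if noise_rate > 0:
        counts = counts + rng.poisson(noise_rate, size=counts.shape)
    cells = pd.DataFrame(
        {"x_um": x, "y_um": y, "true_type": types},
        index=pd.Index([f"spot{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
    return SpatialDataset(
        cells=cells,
        counts=sp.csr_matrix(counts.T),
        gene_ids=pd.Index(celltype_profiles.columns),
    )


def simulate_calcium(
    duration_s: float = 100.0,
    rate_hz: float = 5.0,
    event_times_s: Mapping[str, Sequence[float]] | Sequence[float] = (),
    event_amp: float = 0.5,
    decay_s: float = 1.0,
    drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_level: float = 1.0,
    trace_meta: pd.DataFrame | None = None,
) -> tuple[CalciumTraceSet, GroundTruth]:
    """Synthesize fluorescence traces with planted calcium transients.

    Each trace is a slowly varying baseline (sinusoidal ``drift`` fraction)
    times 1 + a sum of instantaneous-rise exponential-decay transients, plus
    Gaussian noise.  ``event_times_s`` may be a single sequence (one trace) or
    a mapping trace_id -> onset seconds.  Defaults match an acquisition of
    100 s at 5 Hz.
    """
    if decay_s <= 0:
        raise ValueError("decay_s must be positive")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if not isinstance(event_times_s, Mapping):
        event_times_s = {"trace0": list(event_times_s)}
    for tid, times in event_times_s.items():
        for t0 in times:
            if not 0.0 <= t0 <= duration_s:
                raise ValueError(f"event time {t0} outside [0, {duration_s}] in {tid}")

    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    rng = np.random.default_rng(seed)
    traces = {}
    for tid in event_times_s:
        baseline = baseline_level * (1.0 + drift * np.sin(2.0 * np.pi * t / duration_s))
        signal = np.zeros(n)
        for t0 in event_times_s[tid]:
            after = t >= t0
            signal[after] += event_amp * np.exp(-(t[after] - t0) / decay_s)
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
        traces[tid] = baseline * (1.0 + signal) + noise
    frame = pd.DataFrame(traces)
    if trace_meta is None:
        trace_meta = pd.DataFrame(
            {"well_id": "well0", "field_id": "field0", "condition": "ctrl"},
            index=pd.Index(list(traces), name="trace_id"),
        )
    truth = GroundTruth(
        calcium_event_times={tid: sorted(map(float, ts)) for tid, ts in event_times_s.items()}
    )
    return CalciumTraceSet(frame, rate_hz, trace_meta), truth
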