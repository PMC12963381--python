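"""Ensemble annotation of spatial panel data and neuronal subtype transfer.

Major cell types are called by independent classifiers — a marker-score
heuristic, graph clustering with marker-based community labels, and kNN label
transfer from a dissociated reference — whose votes are combined by strict
plurality: consensus confidence is the agreeing share of cast votes, and only
cells with confidence strictly above 0.5 are retained.  Neurons with more
than 50 transcripts additionally receive a subtype label transferred in the
reference PCA space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import kneighbors_graph

from .data import NormalizedMatrix, SpatialDataset
from .markers import knn_label_transfer


def _panel_lognorm(sd: SpatialDataset) -> NormalizedMatrix:
    """Median-library log normalization of the panel counts."""
    counts = np.asarray(sd.counts.todense(), dtype=float)
    libs = counts.sum(axis=0)
    libs[libs == 0] = 1.0
    sf = libs / np.median(libs)
    values = np.log1p(counts / sf[None, :])
    return NormalizedMatrix(values=values, size_factors=sf,
                           gene_ids=sd.gene_ids, cell_ids=sd.cells.index)


def _marker_scores(
    counts: np.ndarray, gene_ids: pd.Index, marker_map: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-cell marker score: mean count over each type's marker set."""
    if not marker_map:
        raise ValueError("empty marker map")
    scores = {}
    missing: list[str] = []
    for ctype, genes in marker_map.items():
        present = [g for g in genes if g in gene_ids]
        missing.extend(g for g in genes if g not in gene_ids)
        if not present:
            scores[ctype] = np.zeros(counts.shape[1])
            continue
        idx = gene_ids.get_indexer(present)
        scores[ctype] = counts[idx].sum(axis=0) / len(present)
    if missing:
        warnings.warn(
            f"{len(set(missing))} marker genes absent from the panel; ignored",
            stacklevel=3,
        )
    return pd.DataFrame(scores)


def heuristic_classify(
    sd: SpatialDataset, marker_map: dict[str, list[str]]
) -> pd.Series:
    """Label each cell by its highest marker score; ties or no signal -> unknown."""
    counts = np.asarray(sd.counts.todense(), dtype=float)
    scores = _marker_scores(counts, sd.gene_ids, marker_map)
    arr = scores.to_numpy()
    best = arr.max(axis=1)
    labels = []
    for i in range(arr.shape[0]):
        if best[i] <= 0 or (arr[i] == best[i]).sum() > 1:
            labels.append("unknown")
        else:
            labels.append(scores.columns[int(arr[i].argmax())])
    return pd.Series(labels, index=sd.cells.index, name="heuristic")


def cluster_annotate(
    sd: SpatialDataset,
    marker_map: dict[str, list[str]],
    resolution: float = 1.0,
    k_graph: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Community detection on the kNN expression graph + marker labelling.

    Counts are log-normalized; communities come from a seeded
    modularity-maximising partition (Leiden) of the kNN graph; each community
    takes the cell type with the highest mean marker score among its members
    (zero signal -> unknown).
    """
    if sd.counts.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    nm = _panel_lognorm(sd)
    k = min(k_graph, nm.values.shape[1] - 1)
    graph = kneighbors_graph(nm.values.T, n_neighbors=k, mode="connectivity")
    sym = graph.maximum(graph.T).tocoo()
    g = igraph.Graph(
        n=sym.shape[0], edges=list(zip(sym.row, sym.col)), directed=False
    ).simplify()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    community = np.asarray(part.membership)
    counts = np.asarray(sd.counts.todense(), dtype=float)
    scores = _marker_scores(counts, sd.gene_ids, marker_map)
    labels = np.empty(len(community), dtype=object)
    for c in np.unique(community):
        mask = community == c
        mean_scores = scores[mask].mean(axis=0)
        if mean_scores.max() <= 0:
            labels[mask] = "unknown"
        else:
            top = mean_scores[mean_scores == mean_scores.max()]
            labels[mask] = "unknown" if len(top) > 1 else mean_scores.idxmax()
    return pd.Series(labels, index=sd.cells.index, name="cluster")


@dataclass
class EnsembleAnnotation:
    """Votes, consensus, confidence and the retained flag per cell."""

    votes: pd.DataFrame  # cells x methods
    consensus: pd.Series
    confidence: pd.Series  # max vote share among cast votes
    retained: pd.Series  # confidence strictly > min_confidence
    subtype: pd.DataFrame | None = None  # label + confidence for eligible neurons
    info: dict = field(default_factory=dict)


def ensemble_vote(
    vote_sets: dict[str, pd.Series], min_confidence: float = 0.5
) -> EnsembleAnnotation:
    """Strict plurality vote over >= 2 per-cell label tables.

    "unknown" votes stay in the denominator (counting against consensus)
    unless every method abstained, in which case the cell is unknown with
    confidence 0.  Tied pluralities are not retained.
    """
    if len(vote_sets) < 2:
        raise ValueError("ensemble needs at least 2 vote sets")
    votes = pd.DataFrame(vote_sets)
    consensus, confidence, retained = [], [], []
    for _, row in votes.iterrows():
        cast = row.dropna()
        known = cast[cast != "unknown"]
        m = len(cast)
        if len(known) == 0:
            consensus.append("unknown")
            confidence.append(0.0)
            retained.append(False)
            continue
        tally = known.value_counts()
        top = tally.iloc[0]
        tied = (tally == top).sum() > 1
        conf = top / m
        consensus.append("unknown" if tied else tally.index[0])
        confidence.append(conf)
        retained.append((not tied) and conf > min_confidence)
    return EnsembleAnnotation(
        votes=votes,
        consensus=pd.Series(consensus, index=votes.index, name="consensus"),
        confidence=pd.Series(confidence, index=votes.index, name="confidence"),
        retained=pd.Series(retained, index=votes.index, name="retained"),
        info={"min_confidence": min_confidence, "methods": list(vote_sets)},
    )


def subtype_transfer(
    sd: SpatialDataset,
    reference_nm: NormalizedMatrix,
    reference_labels,
    eligible: pd.Series | None = None,
    min_transcripts: int = 50,
    n_pcs: int = 15,
    k: int = 20,
) -> pd.DataFrame:
    """kNN subtype transfer for neurons passing the transcript gate.

    Only cells flagged in ``eligible`` (e.g. neuronal consensus) with total
    transcripts strictly greater than ``min_transcripts`` receive a label;
    everything else is "unlabeled".  The shared panel restricts both datasets;
    a panel smaller than ``n_pcs`` reduces the PC count with a warning.
    """
    nm_q = _panel_lognorm(sd)
    total = sd.total_transcripts
    gate = pd.Series(total > min_transcripts, index=sd.cells.index)
    if eligible is not None:
        gate &= eligible.reindex(sd.cells.index).fillna(False)
    out = pd.DataFrame(
        {"subtype": "unlabeled", "subtype_confidence": np.nan}, index=sd.cells.index
    )
    if gate.sum() == 0:
        return out
    sub_nm = NormalizedMatrix(
        values=nm_q.values[:, gate.to_numpy()],
        size_factors=nm_q.size_factors[gate.to_numpy()],
        gene_ids=nm_q.gene_ids,
        cell_ids=nm_q.cell_ids[gate.to_numpy()],
    )
    transfer = knn_label_transfer(reference_nm, reference_labels, sub_nm,
                                  n_pcs=n_pcs, k=k)
    out.loc[transfer.index, "subtype"] = transfer["label"].to_numpy()
    out.loc[transfer.index, "subtype_confidence"] = transfer["confidence"].to_numpy()
    return out


def annotate_spatial(
    sd: SpatialDataset,
    marker_map: dict[str, list[str]],
    reference_nm: NormalizedMatrix | None = None,
    reference_labels=None,
    neuronal_types: set[str] | None = None,
    min_confidence: float = 0.5,
    min_transcripts: int = 50,
    seed: int = 0,
    extra_votes: dict[str, pd.Series] | None = None,
) -> EnsembleAnnotation:
    """End-to-end ensemble annotation of a spatial section.

    Runs the heuristic and cluster classifiers (plus kNN transfer when a
    reference is provided, and any ``extra_votes`` such as an external DNN
    classifier), takes the ensemble vote, and transfers subtypes to retained
    neuronal cells passing the transcript gate.
    """
    votes: dict[str, pd.Series] = {
        "heuristic": heuristic_classify(sd, marker_map),
        "cluster": cluster_annotate(sd, marker_map, seed=seed),
    }
    if reference_nm is not None:
        major = knn_label_transfer(reference_nm, reference_labels,
                                   _panel_lognorm(sd))
        votes["transfer"] = major["label"].rename("transfer")
    if extra_votes:
        votes.update(extra_votes)
    ann = ensemble_vote(votes, min_confidence=min_confidence)
    if reference_nm is not None:
        if neuronal_types is None:
            neuronal_types = set(np.unique(np.asarray(reference_labels)))
        eligible = ann.retained & ann.consensus.isin(sorted(neuronal_types))
        ann.subtype = subtype_transfer(
            sd, reference_nm, reference_labels, eligible=eligible,
            min_transcripts=min_transcripts,
        )
    return ann
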