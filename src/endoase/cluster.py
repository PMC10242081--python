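"""SNN-graph clustering, marker detection and cluster annotation.

Nuclei are clustered by building a k-nearest-neighbour graph on the PCA
embedding, reweighting edges by the Jaccard overlap of neighbour sets
(shared nearest neighbours), pruning weak edges, and maximising
resolution-scaled modularity with the Leiden algorithm.  Cluster-enriched
genes are found with a Wilcoxon rank-sum test subject to fold-change and
detection-fraction filters; cluster identity can be annotated by Spearman
correlation against reference pseudo-bulk profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .containers import AlleleCountMatrix, ValidationError
from .stats import bh_adjust, ranksum_pvalues

__all__ = [
    "ClusteringResult",
    "cluster_snn",
    "find_markers",
    "correlate_with_reference",
    "expressed_gene_overlap",
]


@dataclass
class ClusteringResult:
    embedding: np.ndarray
    labels: np.ndarray               # consecutive integers from 0, by size
    parameters: dict

    def label_map(self, barcodes: Sequence[str]) -> Dict[str, int]:
        return {b: int(l) for b, l in zip(barcodes, self.labels)}


def snn_graph(embedding: np.ndarray, k_neighbors: int = 20,
              prune: float = 1.0 / 15.0) -> sp.csr_matrix:
    """Shared-nearest-neighbour graph: Jaccard overlap of the k-NN sets
    (self included), pruned below ``prune``."""
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_nuclei={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors, algorithm="auto")
    nn.fit(embedding)
    _, idx = nn.kneighbors(embedding)  # includes self as the 0-distance hit
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sp.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).tocoo()
    union = 2.0 * k_neighbors - shared.data
    jaccard = shared.data / union
    keep = (jaccard >= prune) & (shared.row != shared.col)
    return sp.csr_matrix(
        (jaccard[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )


def cluster_snn(embedding: np.ndarray, k_neighbors: int = 20,
                resolution: float = 0.4, prune: float = 1.0 / 15.0,
                seed: int = 0) -> ClusteringResult:
    """Leiden modularity clustering of the SNN graph.

    Labels are relabelled by decreasing cluster size, ties broken by the
    smallest member index, so output is deterministic at a fixed seed.
    """
    graph = snn_graph(embedding, k_neighbors=k_neighbors, prune=prune)
    coo = sp.triu(graph, k=1).tocoo()
    g = igraph.Graph(
        n=graph.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=2,
    )
    raw = np.array(part.membership)
    # relabel by decreasing size (smallest member index breaks ties)
    sizes = pd.Series(raw).value_counts()
    first = {c: int(np.argmax(raw == c)) for c in sizes.index}
    order = sorted(sizes.index, key=lambda c: (-sizes[c], first[c]))
    remap = {c: i for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    return ClusteringResult(
        embedding=embedding, labels=labels,
        parameters={"k_neighbors": k_neighbors, "resolution": resolution,
                    "prune": prune, "seed": seed},
    )


def _mean_cpm_from_norm(norm_block: np.ndarray) -> np.ndarray:
    """Mean CPM per gene, back-transformed from the log10(CPM+1) layer."""
    return (10.0 ** norm_block - 1.0).mean(axis=0)


def find_markers(acm: AlleleCountMatrix, labels: np.ndarray,
                 logfc_threshold: float = 0.58, min_pct: float = 0.10,
                 specific_log2fc: float = 0.25, specific_max_pct2: float = 0.10,
                 pct_filter: str = "either") -> pd.DataFrame:
    """Cluster-vs-rest marker detection with a Wilcoxon rank-sum test.

    For each cluster, genes detected in at least ``min_pct`` of in-cluster
    (or, with ``pct_filter='either'``, out-of-cluster) nuclei whose |log2
    fold change| of mean CPM (pseudo-count 1) reaches ``logfc_threshold``
    are tested on the normalized layer; q-values are Benjamini–Hochberg
    within each cluster.  ``specific`` flags cluster-specific markers
    (log2fc > ``specific_log2fc`` and pct2 < ``specific_max_pct2``).
    """
    if acm.norm is None:
        raise ValidationError("normalized layer missing; run normalize_log_cpm")
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    X = np.asarray(acm.norm.todense())
    detected = X > 0
    out = []
    for c in uniq:
        inside = labels == c
        if inside.sum() < 3:
            warnings.warn(f"cluster {c} has fewer than 3 nuclei; markers skipped")
            continue
        pct1 = detected[inside].mean(axis=0)
        pct2 = detected[~inside].mean(axis=0)
        mean_in = _mean_cpm_from_norm(X[inside])
        mean_out = _mean_cpm_from_norm(X[~inside])
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        if pct_filter == "either":
            pct_ok = (pct1 >= min_pct) | (pct2 >= min_pct)
        elif pct_filter == "in":
            pct_ok = pct1 >= min_pct
        else:
            raise ValueError("pct_filter must be 'either' or 'in'")
        tested = pct_ok & (np.abs(log2fc) >= logfc_threshold)
        if not tested.any():
            continue
        p = ranksum_pvalues(X[inside][:, tested], X[~inside][:, tested])
        q = bh_adjust(p)
        idx = np.flatnonzero(tested)
        out.append(pd.DataFrame({
            "gene": acm.gene_ids[idx],
            "cluster": int(c),
            "log2fc": log2fc[idx],
            "pct1": pct1[idx],
            "pct2": pct2[idx],
            "p_value": p,
            "q_value": q,
            "specific": (log2fc[idx] > specific_log2fc) & (pct2[idx] < specific_max_pct2),
        }))
    if not out:
        return pd.DataFrame(columns=["gene", "cluster", "log2fc", "pct1",
                                     "pct2", "p_value", "q_value", "specific"])
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["cluster", "q_value", "gene"],
                           kind="mergesort").reset_index(drop=True)


def correlate_with_reference(acm: AlleleCountMatrix, labels: np.ndarray,
                             reference: pd.DataFrame,
                             min_shared_genes: int = 100) -> pd.DataFrame:
    """Spearman correlation of per-cluster mean normalized expression
    against reference pseudo-bulk profiles (genes × tissue columns)."""
    shared = [g for g in acm.gene_ids if g in reference.index]
    if len(shared) < min_shared_genes:
        raise ValidationError(
            f"only {len(shared)} genes shared with the reference "
            f"(minimum {min_shared_genes})"
        )
    if acm.norm is None:
        raise ValidationError("normalized layer missing; run normalize_log_cpm")
    idx = acm.gene_index(shared)
    X = np.asarray(acm.norm.todense())[:, idx]
    labels = np.asarray(labels)
    rows = {}
    for c in np.unique(labels):
        profile = X[labels == c].mean(axis=0)
        rows[int(c)] = {
            col: stats.spearmanr(profile, reference.loc[shared, col]).statistic
            for col in reference.columns
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def expressed_gene_overlap(acms: Dict[str, AlleleCountMatrix],
                           labels: Optional[Dict[str, np.ndarray]] = None,
                           expressed_min_cells: int = 5) -> pd.DataFrame:
    """Venn-region sizes of expressed-gene sets across the trio.

    A gene is expressed in a (sample, group) if detected in at least
    ``expressed_min_cells`` of that group's nuclei.  Returns one row per
    group with all seven Venn regions plus the fraction of hybrid-expressed
    genes shared with either parent.
    """
    samples = list(acms)
    universe = acms[samples[0]].gene_ids
    for s in samples[1:]:
        if not np.array_equal(acms[s].gene_ids, universe):
            raise ValidationError("gene universes differ between samples")
    if labels is None:
        labels = {s: np.zeros(acms[s].n_nuclei, dtype=int) for s in samples}
    groups = sorted(set(np.concatenate([np.unique(labels[s]) for s in samples])))
    rows = []
    for g in groups:
        sets = {}
        for s in samples:
            mask = np.asarray(labels[s]) == g
            if mask.sum() == 0:
                sets[s] = set()
                continue
            det = np.asarray(
                (acms[s].counts[mask] > 0).sum(axis=0)
            ).ravel()
            sets[s] = set(universe[det >= expressed_min_cells])
        h = sets.get("hybrid", set())
        m = sets.get("maternal_parent", set())
        p = sets.get("paternal_parent", set())
        shared = h & (m | p)
        rows.append({
            "group": g,
            "hybrid_only": len(h - m - p),
            "maternal_only": len(m - h - p),
            "paternal_only": len(p - h - m),
            "hybrid_maternal": len((h & m) - p),
            "hybrid_paternal": len((h & p) - m),
            "maternal_paternal": len((m & p) - h),
            "all_three": len(h & m & p),
            "hybrid_expressed": len(h),
            "hybrid_shared_fraction": len(shared) / len(h) if h else 0.0,
        })
    return pd.DataFrame(rows)
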