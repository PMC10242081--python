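"""Quality filtering, normalization, feature selection and PCA.

The processing chain mirrors standard droplet-data practice: nuclei with
fewer than 3,000 detected genes are removed, then genes detected in fewer
than 5 of the remaining nuclei; expression is normalised to log10(CPM+1);
the top 2,000 highly variable genes feed a 15-component PCA.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .containers import AlleleCountMatrix, ValidationError

__all__ = [
    "filter_cells_genes",
    "normalize_log_cpm",
    "select_hvg",
    "run_pca",
    "EmptyResultError",
]


class EmptyResultError(ValueError):
    """All observations were removed by a filter."""


def filter_cells_genes(acm: AlleleCountMatrix, min_genes_per_cell: int = 3000,
                       min_cells_per_gene: int = 5) -> AlleleCountMatrix:
    """Remove low-complexity nuclei, then sparsely detected genes.

    Nuclei with fewer than ``min_genes_per_cell`` detected genes are removed
    first; genes detected in fewer than ``min_cells_per_gene`` of the
    *remaining* nuclei are removed second.  "Fewer than" is strict, so a
    nucleus detecting exactly the threshold survives.  Allele layers are
    subset identically and survivor order is preserved.
    """
    keep_nuclei = np.flatnonzero(acm.genes_detected_per_nucleus() >= min_genes_per_cell)
    if keep_nuclei.size == 0:
        raise EmptyResultError(
            f"no nucleus detects >= {min_genes_per_cell} genes; "
            "lower min_genes_per_cell"
        )
    trimmed = acm.subset(nuclei=keep_nuclei)
    keep_genes = np.flatnonzero(trimmed.nuclei_detected_per_gene() >= min_cells_per_gene)
    return trimmed.subset(genes=keep_genes)


def normalize_log_cpm(acm: AlleleCountMatrix) -> AlleleCountMatrix:
    """Attach the normalized layer: log10(CPM + 1) per nucleus.

    CPM scales each nucleus's counts to one million; zero-total nuclei are
    rejected (they cannot survive the upstream filter).
    """
    totals = acm.total_counts_per_nucleus().astype(float)
    if np.any(totals == 0):
        bad = acm.barcodes[int(np.argmax(totals == 0))]
        raise ValidationError(f"nucleus {bad!r} has zero total counts")
    cpm = acm.counts.multiply(1e6 / totals[:, None]).tocsr()
    norm = cpm.copy()
    norm.data = np.log10(norm.data + 1.0)
    acm.norm = norm
    return acm


def _norm_dense(acm: AlleleCountMatrix) -> np.ndarray:
    if acm.norm is None:
        raise ValidationError("normalized layer missing; run normalize_log_cpm first")
    return np.asarray(acm.norm.todense())


def select_hvg(acm: AlleleCountMatrix, n_top: int = 2000,
               clip: float = 10.0, flavor: str = "vst") -> list[str]:
    """Rank genes by the variance of clipped, mean/variance-standardised
    raw counts and return the top ``n_top`` gene IDs.

    The expected variance at a gene's mean is taken from a quadratic fit of
    log variance on log mean across genes (a "vst"-style mean-variance
    trend on counts); standardised values are clipped at ``clip`` standard
    deviations so single outlier nuclei cannot dominate.  Ties break by
    gene index.

    ``flavor='dispersion'`` ranks instead by the variance/mean ratio of
    per-nucleus CPM, the classic dispersion-based alternative.
    """
    if n_top > acm.n_genes:
        raise ValueError(f"n_top={n_top} exceeds n_genes={acm.n_genes}")
    if flavor == "dispersion":
        totals = acm.total_counts_per_nucleus().astype(float)
        totals[totals == 0] = 1.0
        cpm = np.asarray(acm.counts.multiply(1e6 / totals[:, None]).todense())
        mean = cpm.mean(axis=0)
        disp = np.where(mean > 0, cpm.var(axis=0) / np.where(mean > 0, mean, 1.0), 0.0)
        order = np.argsort(-disp, kind="stable")
        return [acm.gene_ids[i] for i in order[:n_top]]
    if flavor != "vst":
        raise ValueError("flavor must be 'vst' or 'dispersion'")
    X = np.asarray(acm.counts.todense(), dtype=float)
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    informative = var > 0
    score = np.zeros(acm.n_genes)
    if informative.sum() >= 3:
        lm = np.log10(mean[informative] + 1e-12)
        lv = np.log10(var[informative])
        coef = np.polyfit(lm, lv, deg=2)
        expected_sd = np.sqrt(10.0 ** np.polyval(coef, np.log10(mean + 1e-12)))
        expected_sd[expected_sd == 0] = 1.0
        Z = (X - mean[None, :]) / expected_sd[None, :]
        np.clip(Z, -clip, clip, out=Z)
        score = Z.var(axis=0)
        score[~informative] = 0.0
    else:
        score = var
    # stable argsort on (-score, index) => deterministic tie-break
    order = np.argsort(-score, kind="stable")
    return [acm.gene_ids[i] for i in order[:n_top]]


def run_pca(acm: AlleleCountMatrix, genes: Sequence[str], n_pcs: int = 15,
            clip: float = 10.0) -> np.ndarray:
    """Project z-scored HVG expression onto the top principal components.

    Normalized values of the given genes are centred and unit-scaled per
    gene (clipped at |z| = ``clip``), then projected onto the leading right
    singular vectors.  The sign of each component is fixed so its
    largest-magnitude loading is positive, making the embedding
    deterministic.
    """
    if len(genes) == 0:
        raise ValueError("HVG list must be non-empty")
    if n_pcs > min(acm.n_nuclei, len(genes)):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(n_nuclei, n_genes) = "
            f"{min(acm.n_nuclei, len(genes))}"
        )
    idx = acm.gene_index(genes)
    X = _norm_dense(acm)[:, idx]
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean[None, :]) / sd[None, :]
    np.clip(Z, -clip, clip, out=Z)
    # economy SVD; deterministic LAPACK path
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt[:n_pcs]
    signs = np.sign(V[np.arange(n_pcs), np.argmax(np.abs(V), axis=1)])
    signs[signs == 0] = 1.0
    return (Z @ (V * signs[:, None]).T)


def variance_explained(embedding: np.ndarray) -> np.ndarray:
    """Per-component variance of a PCA embedding (non-increasing)."""
    return embedding.var(axis=0)
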