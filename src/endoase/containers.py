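"""Shared data containers for nucleus × gene count data.

The central object is :class:`AlleleCountMatrix`: a sparse matrix of UMI
counts per nucleus and gene, optionally carrying two allele-resolved layers
(maternal- and paternal-assigned reads) for a hybrid sample and a normalized
expression layer (log10(CPM+1)).  Nuclei are rows and genes are columns;
droplet pipelines write genes × barcodes on disk, which the readers transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["AlleleCountMatrix", "NucleusMetadata", "ValidationError"]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _as_csr(m) -> sp.csr_matrix:
    m = sp.csr_matrix(m)
    m.sum_duplicates()
    m.eliminate_zeros()
    return m


def _check_unique(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if len(set(arr)) != len(arr):
        dup = pd.Series(arr).value_counts()
        dup = dup[dup > 1].index[0]
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")
    return arr


@dataclass
class AlleleCountMatrix:
    """Sparse nucleus × gene UMI counts with optional allele layers.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, nuclei × genes.
    gene_ids, barcodes
        Ordered, duplicate-free identifiers for columns and rows.
    maternal, paternal
        Optional sparse layers of allele-assigned reads, same shape as
        ``counts``.  Only reads overlapping parental SNPs are assignable, so
        elementwise ``maternal + paternal <= counts`` must hold.
    norm
        Optional normalized-expression layer (log10(CPM+1)); filled in by
        :func:`endoase.qc.normalize_log_cpm`.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    maternal: Optional[sp.csr_matrix] = None
    paternal: Optional[sp.csr_matrix] = None
    norm: Optional[sp.csr_matrix] = None

    def __post_init__(self) -> None:
        self.counts = _as_csr(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts contain negative entries")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.barcodes = _check_unique(self.barcodes, "barcode")
        n, g = self.counts.shape
        if len(self.barcodes) != n or len(self.gene_ids) != g:
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.gene_ids)} genes"
            )
        if self.maternal is not None:
            self.maternal = _as_csr(self.maternal)
        if self.paternal is not None:
            self.paternal = _as_csr(self.paternal)
        for name in ("maternal", "paternal", "norm"):
            layer = getattr(self, name)
            if layer is not None and layer.shape != self.counts.shape:
                raise ValidationError(
                    f"{name} layer shape {layer.shape} != counts shape {self.counts.shape}"
                )
        if self.maternal is not None and self.paternal is not None:
            self._check_allele_subset()

    def _check_allele_subset(self) -> None:
        informative = self.maternal + self.paternal
        excess = (informative - self.counts).tocoo()
        if excess.nnz and excess.data.max() > 0:
            i = int(np.argmax(excess.data > 0))
            r, c = int(excess.row[i]), int(excess.col[i])
            raise ValidationError(
                "maternal + paternal exceeds total counts at "
                f"(barcode={self.barcodes[r]!r}, gene={self.gene_ids[c]!r})"
            )

    # -- basic properties -------------------------------------------------
    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def has_allele_layers(self) -> bool:
        return self.maternal is not None and self.paternal is not None

    def genes_detected_per_nucleus(self) -> np.ndarray:
        """Number of genes with count > 0 for each nucleus."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def nuclei_detected_per_gene(self) -> np.ndarray:
        """Number of nuclei with count > 0 for each gene."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def total_counts_per_nucleus(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Positions of ``genes`` in :attr:`gene_ids` (error on missing)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not present in matrix") from None

    def subset(self, nuclei=None, genes=None) -> "AlleleCountMatrix":
        """Return a copy restricted to the given row/column index arrays."""
        ni = np.arange(self.n_nuclei) if nuclei is None else np.asarray(nuclei)
        gi = np.arange(self.n_genes) if genes is None else np.asarray(genes)

        def _cut(layer):
            return None if layer is None else layer[ni][:, gi]

        return AlleleCountMatrix(
            counts=self.counts[ni][:, gi],
            gene_ids=self.gene_ids[gi],
            barcodes=self.barcodes[ni],
            maternal=_cut(self.maternal),
            paternal=_cut(self.paternal),
            norm=_cut(self.norm),
        )

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (layers carried over)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        for name in ("maternal", "paternal", "norm"):
            layer = getattr(self, name)
            if layer is not None:
                adata.layers[name] = layer.copy()
        return adata


@dataclass
class NucleusMetadata:
    """Per-nucleus bookkeeping: sample of origin, cluster, QC statistics."""

    barcode: str
    sample: str
    cluster: Optional[int] = None
    n_genes_detected: int = 0
    total_counts: int = 0

    SAMPLES = ("maternal_parent", "paternal_parent", "hybrid")

    def __post_init__(self) -> None:
        if self.sample not in self.SAMPLES:
            raise ValidationError(
                f"sample must be one of {self.SAMPLES}, got {self.sample!r}"
            )
        if self.n_genes_detected < 0 or self.total_counts < 0:
            raise ValidationError("QC statistics must be non-negative")


def metadata_table(acm: AlleleCountMatrix, sample: str,
                   clusters: Optional[dict] = None) -> pd.DataFrame:
    """Build a per-nucleus metadata frame for ``acm``.

    ``clusters`` maps barcode -> integer label; unlabelled nuclei get NA.
    """
    if sample not in NucleusMetadata.SAMPLES:
        raise ValidationError(
            f"sample must be one of {NucleusMetadata.SAMPLES}, got {sample!r}"
        )
    df = pd.DataFrame(
        {
            "barcode": list(acm.barcodes),
            "sample": sample,
            "n_genes_detected": acm.genes_detected_per_nucleus(),
            "total_counts": acm.total_counts_per_nucleus(),
        }
    )
    if clusters is not None:
        df["cluster"] = df["barcode"].map(clusters).astype("Int64")
    else:
        df["cluster"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df
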