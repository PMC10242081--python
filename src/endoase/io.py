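"""Readers and writers for the droplet-pipeline file layout.

Count matrices are Matrix Market coordinate files (``.mtx``, optionally
gzipped) in the genes × barcodes orientation used by droplet pipelines,
accompanied by one-ID-per-line gene and barcode lists.  Indices are 1-based
on disk and 0-based in memory; duplicate coordinate entries are summed.
Result tables are written as TSV.
"""

from __future__ import annotations

import gzip
import os
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import AlleleCountMatrix, ValidationError

__all__ = [
    "read_count_matrix",
    "attach_allele_layers",
    "write_count_matrix",
    "write_table",
    "read_id_list",
    "FormatError",
]

PathLike = Union[str, os.PathLike]


class FormatError(ValueError):
    """Raised for malformed or inconsistent on-disk inputs."""


def _open_maybe_gzip(path: PathLike, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_id_list(path: PathLike) -> list[str]:
    """Read one identifier per line; extra tab-separated columns (e.g. a
    10x-style feature-type column) are tolerated and ignored."""
    ids = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return ids


def _read_mtx(path: PathLike) -> sp.coo_matrix:
    try:
        with _open_maybe_gzip(path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except Exception as e:  # malformed header / body
        raise FormatError(f"cannot parse Matrix Market file {path}: {e}") from e
    return sp.coo_matrix(mat)


def read_count_matrix(matrix_path: PathLike, genes_path: PathLike,
                      barcodes_path: PathLike) -> AlleleCountMatrix:
    """Read a genes × barcodes Matrix Market triplet file into an
    :class:`AlleleCountMatrix` (transposed to nuclei × genes).

    Duplicate (row, col) entries are summed; negative entries are rejected.
    """
    genes = read_id_list(genes_path)
    barcodes = read_id_list(barcodes_path)
    mat = _read_mtx(matrix_path)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{matrix_path} declares {mat.shape[0]} rows but {genes_path} "
            f"lists {len(genes)} genes"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{matrix_path} declares {mat.shape[1]} columns but "
            f"{barcodes_path} lists {len(barcodes)} barcodes"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValidationError(f"{matrix_path} contains negative entries")
    counts = mat.T.tocsr()
    counts.sum_duplicates()
    return AlleleCountMatrix(counts=counts, gene_ids=np.array(genes, dtype=object),
                             barcodes=np.array(barcodes, dtype=object))


def attach_allele_layers(acm: AlleleCountMatrix, maternal_path: PathLike,
                         paternal_path: PathLike) -> AlleleCountMatrix:
    """Attach maternal/paternal allele-assigned read layers read from
    Matrix Market files (genes × barcodes, same dimensions as ``acm``).

    Verifies the subset invariant maternal + paternal <= counts elementwise.
    """
    layers = {}
    for name, path in (("maternal", maternal_path), ("paternal", paternal_path)):
        mat = _read_mtx(path)
        if mat.shape != (acm.n_genes, acm.n_nuclei):
            raise FormatError(
                f"{path} has shape {mat.shape}; expected "
                f"{(acm.n_genes, acm.n_nuclei)} (genes x barcodes)"
            )
        if mat.nnz and mat.data.min() < 0:
            raise ValidationError(f"{path} contains negative entries")
        layers[name] = mat.T.tocsr()
    return AlleleCountMatrix(
        counts=acm.counts, gene_ids=acm.gene_ids, barcodes=acm.barcodes,
        maternal=layers["maternal"], paternal=layers["paternal"], norm=acm.norm,
    )


def write_count_matrix(acm: AlleleCountMatrix, out_dir: PathLike,
                       prefix: str = "") -> None:
    """Write ``acm`` in the layout :func:`read_count_matrix` reads
    (genes × barcodes ``matrix.mtx`` plus ``genes.txt`` / ``barcodes.txt``;
    allele layers as ``maternal.mtx`` / ``paternal.mtx`` when present)."""
    os.makedirs(out_dir, exist_ok=True)

    def p(name: str) -> str:
        return os.path.join(os.fspath(out_dir), prefix + name)

    scipy.io.mmwrite(p("matrix.mtx"), acm.counts.T.tocoo())
    with open(p("genes.txt"), "w") as fh:
        fh.write("\n".join(map(str, acm.gene_ids)) + "\n")
    with open(p("barcodes.txt"), "w") as fh:
        fh.write("\n".join(map(str, acm.barcodes)) + "\n")
    for name in ("maternal", "paternal"):
        layer = getattr(acm, name)
        if layer is not None:
            scipy.io.mmwrite(p(f"{name}.mtx"), layer.T.tocoo())


def write_table(records: pd.DataFrame, path: PathLike,
                sort_by: Optional[list[str]] = None) -> None:
    """Write a result table as TSV: header row plus one line per record,
    floats with 6 significant digits, deterministic row order.

    ``sort_by`` names the sort key; when omitted the existing row order is
    kept (callers document their per-table sort keys).
    """
    if records is None:
        raise ValueError("records must not be None")
    df = records.copy()
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
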