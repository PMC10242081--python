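"""Dosage-aware allele-specific expression calling in triploid endosperm.

Endosperm carries two maternal genome copies and one paternal copy, so an
unbiased gene is expected to show a 2:1 maternal:paternal read ratio
(maternal fraction f0 = 2/3), not the 1:1 of diploid tissue.  Genes whose
pooled allele-informative reads deviate from f0 — by an exact two-sided
binomial test with Benjamini–Hochberg FDR — are called maternally (MEG) or
paternally (PEG) expressed, and binned into strong / intermediate / weak
bias by their maternal fraction.  Per-cluster enrichment-score profiles
describe where in the tissue each biased gene is expressed, on the total,
maternal and paternal layers separately.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AlleleCountMatrix, ValidationError
from .stats import bh_adjust

__all__ = [
    "aggregate_allelic_counts",
    "assess_ase",
    "binomial_pvalue",
    "classify_bias_strength",
    "cluster_enrichment_scores",
    "per_cluster_maternal_fraction",
]


def aggregate_allelic_counts(acm: AlleleCountMatrix,
                             nuclei_subset: Optional[np.ndarray] = None
                             ) -> pd.DataFrame:
    """Sum maternal/paternal reads per gene over a nucleus subset.

    Returns a frame with one row per gene: ``m_reads``, ``p_reads`` and
    ``n_informative_nuclei`` (nuclei contributing at least one
    allele-informative read to the gene).
    """
    if not acm.has_allele_layers():
        raise ValidationError("allele layers missing; attach maternal/paternal counts")
    if nuclei_subset is None:
        nuclei_subset = np.arange(acm.n_nuclei)
    nuclei_subset = np.asarray(nuclei_subset)
    m_layer = acm.maternal[nuclei_subset]
    p_layer = acm.paternal[nuclei_subset]
    m = np.asarray(m_layer.sum(axis=0)).ravel()
    p = np.asarray(p_layer.sum(axis=0)).ravel()
    informative = ((m_layer + p_layer) > 0).sum(axis=0)
    return pd.DataFrame({
        "gene": acm.gene_ids,
        "m_reads": m.astype(np.int64),
        "p_reads": p.astype(np.int64),
        "n_informative_nuclei": np.asarray(informative).ravel().astype(np.int64),
    })


def binomial_pvalue(m: int, n: int, f0: float, tail: str = "minlike") -> float:
    """Exact two-sided binomial p-value for m maternal reads out of n.

    ``minlike`` (default) sums the probabilities of all outcomes no more
    likely than the observed one; ``double`` doubles the smaller tail
    (capped at 1).  Both are exact — no normal approximation at any depth.
    """
    if n == 0:
        return 1.0
    if tail == "minlike":
        return stats.binomtest(int(m), int(n), f0, alternative="two-sided").pvalue
    if tail == "double":
        lower = stats.binom.cdf(m, n, f0)
        upper = stats.binom.sf(m - 1, n, f0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError("tail must be 'minlike' or 'double'")


def betabinomial_pvalue(m: int, n: int, f0: float, overdispersion: float,
                        tail: str = "minlike") -> float:
    """Two-sided beta-binomial p-value for pooled counts with
    between-nucleus allelic heterogeneity.

    The beta mixing distribution has mean ``f0`` and intra-class
    correlation ``overdispersion`` (rho in (0, 1)); rho -> 0 recovers the
    plain binomial.
    """
    if not 0.0 < overdispersion < 1.0:
        raise ValueError("overdispersion must lie in (0, 1)")
    if n == 0:
        return 1.0
    rho = overdispersion
    a = f0 * (1.0 - rho) / rho
    b = (1.0 - f0) * (1.0 - rho) / rho
    pmf = stats.betabinom.pmf(np.arange(n + 1), n, a, b)
    if tail == "minlike":
        return float(pmf[pmf <= pmf[m] * (1 + 1e-12)].sum())
    if tail == "double":
        lower = pmf[: m + 1].sum()
        upper = pmf[m:].sum()
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError("tail must be 'minlike' or 'double'")


def assess_ase(agg: pd.DataFrame, expected_fraction: float = 2.0 / 3.0,
               min_reads: int = 20, min_nuclei: int = 5,
               alpha: float = 0.05, tail: str = "minlike",
               overdispersion: float = 0.0) -> pd.DataFrame:
    """Call MEGs and PEGs from pooled allelic counts against the dosage
    expectation.

    Genes with ``m + p >= min_reads`` informative reads seen in at least
    ``min_nuclei`` nuclei are assessed; others are ``not_assessed`` and
    carry no p/q.  Assessed genes get an exact two-sided binomial p-value
    at success probability ``expected_fraction``, BH-adjusted across the
    assessed set; significant genes are called MEG or PEG by the sign of
    (maternal fraction − expected fraction), the rest ``biparental``.

    ``overdispersion`` > 0 switches to a beta-binomial test with that
    intra-class correlation, for pooled counts with strong between-nucleus
    allelic heterogeneity.
    """
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError(f"expected_fraction={expected_fraction} outside (0, 1)")
    df = agg.copy()
    total = df["m_reads"] + df["p_reads"]
    assessable = (total >= min_reads) & (df["n_informative_nuclei"] >= min_nuclei)
    df["maternal_fraction"] = np.where(total > 0, df["m_reads"] / total.where(total > 0, 1), np.nan)
    p = np.full(len(df), np.nan)
    rows = np.flatnonzero(assessable.to_numpy())
    m_arr = df["m_reads"].to_numpy()
    t_arr = total.to_numpy()
    # cache: many genes share the same (m, n)
    cache: dict = {}
    for i in rows:
        key = (int(m_arr[i]), int(t_arr[i]))
        if key not in cache:
            if overdispersion > 0:
                cache[key] = betabinomial_pvalue(
                    key[0], key[1], expected_fraction, overdispersion, tail=tail
                )
            else:
                cache[key] = binomial_pvalue(key[0], key[1], expected_fraction,
                                             tail=tail)
        p[i] = cache[key]
    q = np.full(len(df), np.nan)
    if rows.size:
        q[rows] = bh_adjust(p[rows])
    call = np.full(len(df), "not_assessed", dtype=object)
    assessed = assessable.to_numpy()
    frac = df["maternal_fraction"].to_numpy()
    sig = assessed & (q <= alpha)
    call[assessed] = "biparental"
    call[sig & (frac > expected_fraction)] = "MEG"
    call[sig & (frac < expected_fraction)] = "PEG"
    df["p_value"] = p
    df["q_value"] = q
    df["call"] = call
    df["strength"] = "none"
    df.loc[~assessed, "maternal_fraction"] = np.nan
    return df


def classify_bias_strength(res: pd.DataFrame,
                           meg_cuts: Sequence[float] = (0.95, 0.85),
                           peg_cuts: Sequence[float] = (0.05, 0.15)
                           ) -> pd.DataFrame:
    """Bin MEG/PEG calls into strong / intermediate / weak parental bias.

    MEGs: strong at maternal fraction >= ``meg_cuts[0]``, intermediate in
    [``meg_cuts[1]``, ``meg_cuts[0]``), weak below.  PEGs mirror on low
    fractions.  Non-calls keep strength ``none``.
    """
    if not (meg_cuts[0] > meg_cuts[1]):
        raise ValueError("meg_cuts must be (strong, intermediate) with strong > intermediate")
    if not (peg_cuts[0] < peg_cuts[1]):
        raise ValueError("peg_cuts must be (strong, intermediate) with strong < intermediate")
    df = res.copy()
    f = df["maternal_fraction"]
    strength = np.full(len(df), "none", dtype=object)
    meg = df["call"] == "MEG"
    peg = df["call"] == "PEG"
    strength[meg & (f >= meg_cuts[0])] = "strong"
    strength[meg & (f >= meg_cuts[1]) & (f < meg_cuts[0])] = "intermediate"
    strength[meg & (f < meg_cuts[1])] = "weak"
    strength[peg & (f <= peg_cuts[0])] = "strong"
    strength[peg & (f > peg_cuts[0]) & (f <= peg_cuts[1])] = "intermediate"
    strength[peg & (f > peg_cuts[1])] = "weak"
    df["strength"] = strength
    return df


def _zscore_across_clusters(mat: np.ndarray) -> np.ndarray:
    """Z-score each row across its columns (population SD); constant rows
    become all zeros."""
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    out = np.zeros_like(mat, dtype=float)
    nz = sd[:, 0] > 0
    out[nz] = (mat[nz] - mean[nz]) / sd[nz]
    return out


def _allele_log_cpm(layer, acm: AlleleCountMatrix) -> np.ndarray:
    """log10(CPM+1) of an allele layer, normalised per nucleus on the
    allele-informative total (maternal + paternal reads)."""
    totals = np.asarray((acm.maternal + acm.paternal).sum(axis=1)).ravel().astype(float)
    totals[totals == 0] = 1.0
    cpm = np.asarray(layer.multiply(1e6 / totals[:, None]).todense())
    return np.log10(cpm + 1.0)


def cluster_enrichment_scores(acm: AlleleCountMatrix, labels: np.ndarray,
                              genes: Sequence[str]) -> pd.DataFrame:
    """Per-gene, per-cluster enrichment scores on the total and allelic
    layers.

    The enrichment score of a gene is its mean expression per cluster,
    z-scored across clusters; ``es_diff = es_maternal - es_paternal``
    highlights where the allelic imbalance itself varies across the tissue.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("enrichment scores need at least 2 clusters")
    if acm.norm is None:
        raise ValidationError("normalized layer missing; run normalize_log_cpm")
    if not acm.has_allele_layers():
        raise ValidationError("allele layers missing")
    present = [g for g in genes if g in set(acm.gene_ids)]
    missing = set(genes) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} genes absent from matrix; skipped")
    if not present:
        return pd.DataFrame(columns=["gene", "cluster", "es_total",
                                     "es_maternal", "es_paternal", "es_diff"])
    idx = acm.gene_index(present)
    total = np.asarray(acm.norm.todense())[:, idx]
    mat = _allele_log_cpm(acm.maternal, acm)[:, idx]
    pat = _allele_log_cpm(acm.paternal, acm)[:, idx]

    def cluster_means(X):
        return np.column_stack([X[labels == c].mean(axis=0) for c in uniq])

    es_total = _zscore_across_clusters(cluster_means(total))
    es_m = _zscore_across_clusters(cluster_means(mat))
    es_p = _zscore_across_clusters(cluster_means(pat))
    rows = []
    for gi, g in enumerate(present):
        for ci, c in enumerate(uniq):
            rows.append({
                "gene": g, "cluster": int(c),
                "es_total": es_total[gi, ci],
                "es_maternal": es_m[gi, ci],
                "es_paternal": es_p[gi, ci],
                "es_diff": es_m[gi, ci] - es_p[gi, ci],
            })
    return pd.DataFrame(rows)


def per_cluster_maternal_fraction(acm: AlleleCountMatrix, labels: np.ndarray,
                                  genes: Sequence[str],
                                  min_reads: int = 20) -> pd.DataFrame:
    """Cluster × gene maternal fractions from per-cluster pooled reads.

    Cluster/gene cells with fewer than ``min_reads`` informative reads are
    reported as missing (NaN), not zero.
    """
    if not acm.has_allele_layers():
        raise ValidationError("allele layers missing")
    labels = np.asarray(labels)
    idx = acm.gene_index(genes)
    rows = {}
    for c in np.unique(labels):
        sel = np.flatnonzero(labels == c)
        m = np.asarray(acm.maternal[sel][:, idx].sum(axis=0)).ravel().astype(float)
        p = np.asarray(acm.paternal[sel][:, idx].sum(axis=0)).ravel().astype(float)
        total = m + p
        frac = np.where(total >= min_reads, m / np.where(total > 0, total, 1.0), np.nan)
        rows[int(c)] = frac
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(genes)).sort_index()
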