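"""Parent/hybrid differential expression and heterosis classification.

Within each nucleus cluster, genes are compared pairwise among the two
parents and their F1 hybrid (fold-change filter plus Wilcoxon rank-sum
test on per-nucleus CPM).  Differentially expressed genes are placed in one
of five expression-pattern classes relative to the lower parent (LP), the
higher parent (HP) and a fold factor k:

    BLP  f1 < LP/k            below lower parent
    BMP  LP/k <= f1 < LP      below mid-parents
    MPV  LP <= f1 <= HP       similar to mid-parents
    OMP  HP < f1 < k*HP       over mid-parents
    OHP  f1 >= k*HP           over higher parents

which is the unique ordering-consistent partition of (0, inf) for LP <= HP.
Genes are further classified as additive (F1 at the mid-parent value),
dominant (F1 matching one parent while the parents differ) or overdominant
(F1 outside the parental range).

Because the three libraries are sequenced to different depths *and*
composition (strongly induced genes inflate a sample's total), per-nucleus
CPM values are rescaled by median-of-ratios sample factors before testing —
the same normalisation idea the standard count-based DE tools apply.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import AlleleCountMatrix, ValidationError
from .stats import bh_adjust, ranksum_pvalues

__all__ = [
    "pairwise_deg",
    "classify_expression_pattern",
    "classify_heterosis_mode",
    "heterosis_modes_table",
    "summarize_pattern_fractions",
    "trio_heterosis_analysis",
    "median_ratio_factors",
]

PATTERNS = ("BLP", "BMP", "MPV", "OMP", "OHP")
MODES = ("additive", "dominant", "overdominant")


def dense_cpm(acm: AlleleCountMatrix) -> np.ndarray:
    """Per-nucleus CPM as a dense float32 array."""
    totals = acm.total_counts_per_nucleus().astype(float)
    totals[totals == 0] = 1.0
    return np.asarray(
        acm.counts.multiply(1e6 / totals[:, None]).todense(), dtype=np.float32
    )


def median_ratio_factors(means: Dict[str, np.ndarray],
                         min_mean: float = 1.0) -> Dict[str, float]:
    """Median-of-ratios scale factors that put samples on a common scale.

    The reference is the geometric mean of the per-sample mean CPM over
    genes expressed (mean >= ``min_mean``) in every sample; each sample's
    factor is the median of reference/sample ratios over those genes.
    Identical samples get factor 1.
    """
    names = list(means)
    stacked = np.vstack([np.asarray(means[s], dtype=float) for s in names])
    shared = (stacked >= min_mean).all(axis=0)
    if shared.sum() < 10:
        return {s: 1.0 for s in names}
    log_ref = np.log(stacked[:, shared]).mean(axis=0)
    return {
        s: float(np.exp(np.median(log_ref - np.log(stacked[i, shared]))))
        for i, s in enumerate(names)
    }


def _group_indices(labels: Optional[np.ndarray], n: int, clusters) -> Dict:
    """Map group key -> row indices.  'all' always included."""
    groups = {"all": np.arange(n)}
    if labels is not None and clusters != ("all",):
        labels = np.asarray(labels)
        wanted = np.unique(labels) if clusters is None else clusters
        for c in wanted:
            if c == "all":
                continue
            groups[int(c)] = np.flatnonzero(labels == int(c))
    return groups


def pairwise_deg(acm_a: AlleleCountMatrix, acm_b: AlleleCountMatrix,
                 labels_a: Optional[np.ndarray] = None,
                 labels_b: Optional[np.ndarray] = None,
                 comparison: str = "A-vs-B",
                 clusters=None, fc_threshold: float = 1.5,
                 alpha: float = 0.05, min_nuclei: int = 3,
                 pseudocount: float = 1.0,
                 normalize_composition: bool = True) -> pd.DataFrame:
    """Per-cluster differential expression between two samples.

    Fold change is the ratio of (mean scaled CPM + pseudocount); the test is
    a two-sided Wilcoxon rank-sum on per-nucleus scaled CPM with BH FDR per
    group.  A gene is significant when |fold change| exceeds
    ``fc_threshold`` and q <= ``alpha``.  Groups with fewer than
    ``min_nuclei`` nuclei on either side are skipped with a warning; the
    pooled group ``all`` is always evaluated.
    """
    if not np.array_equal(acm_a.gene_ids, acm_b.gene_ids):
        raise ValidationError("gene universes differ between samples")
    cpm_a = dense_cpm(acm_a)
    cpm_b = dense_cpm(acm_b)
    groups_a = _group_indices(labels_a, acm_a.n_nuclei, clusters)
    groups_b = _group_indices(labels_b, acm_b.n_nuclei, clusters)
    out = []
    for key in groups_a:
        if key not in groups_b:
            continue
        ia, ib = groups_a[key], groups_b[key]
        if len(ia) < min_nuclei or len(ib) < min_nuclei:
            warnings.warn(
                f"cluster {key} has <{min_nuclei} nuclei on one side; skipped"
            )
            continue
        A, B = cpm_a[ia].astype(float), cpm_b[ib].astype(float)
        if normalize_composition:
            factors = median_ratio_factors({"a": A.mean(axis=0), "b": B.mean(axis=0)})
            A = A * factors["a"]
            B = B * factors["b"]
        log2fc = np.log2((A.mean(axis=0) + pseudocount)
                         / (B.mean(axis=0) + pseudocount))
        p = ranksum_pvalues(A, B)
        q = bh_adjust(p)
        sig = (np.abs(log2fc) > np.log2(fc_threshold)) & (q <= alpha)
        out.append(pd.DataFrame({
            "gene": acm_a.gene_ids,
            "cluster": str(key),
            "comparison": comparison,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "significant": sig,
        }))
    if not out:
        return pd.DataFrame(columns=["gene", "cluster", "comparison",
                                     "log2fc", "p_value", "q_value", "significant"])
    return pd.concat(out, ignore_index=True)


def classify_expression_pattern(p1_mean: float, p2_mean: float,
                                f1_mean: float, k: float = 3.0) -> str:
    """Assign the five-way expression-pattern class from mean expression.

    LP and HP are the order statistics of the two parent means (which
    parent is higher is irrelevant); the partition is total and disjoint
    over f1 in (0, inf) for LP > 0.
    """
    if k <= 1:
        raise ValueError("fold factor k must exceed 1")
    lp, hp = sorted((float(p1_mean), float(p2_mean)))
    if lp <= 0:
        raise ValueError("lower-parent mean must be positive for pattern classification")
    f1 = float(f1_mean)
    if f1 < lp / k:
        return "BLP"
    if f1 < lp:
        return "BMP"
    if f1 <= hp:
        return "MPV"
    if f1 < k * hp:
        return "OMP"
    return "OHP"


def _welch_midparent_pvalues(F, P1, P2):
    """Two-sided z-test of mean(F1) against the mid-parent value, with the
    parent-mean uncertainty propagated into the standard error."""
    mf, m1, m2 = F.mean(axis=0), P1.mean(axis=0), P2.mean(axis=0)
    vf = F.var(axis=0, ddof=1) / F.shape[0]
    v1 = P1.var(axis=0, ddof=1) / P1.shape[0]
    v2 = P2.var(axis=0, ddof=1) / P2.shape[0]
    se = np.sqrt(vf + 0.25 * (v1 + v2))
    mp = 0.5 * (m1 + m2)
    p = np.ones_like(mf, dtype=float)
    ok = se > 0
    z = np.zeros_like(mf, dtype=float)
    z[ok] = (mf[ok] - mp[ok]) / se[ok]
    p[ok] = 2.0 * sps.norm.sf(np.abs(z[ok]))
    return p


def heterosis_modes_table(f1_cpm: np.ndarray, p1_cpm: np.ndarray,
                          p2_cpm: np.ndarray, genes: Sequence[str],
                          alpha: float = 0.05,
                          method: str = "test") -> pd.DataFrame:
    """Vectorised additive/dominant/overdominant classification.

    Inputs are per-nucleus (scaled) CPM matrices for the hybrid and both
    parents over the same gene columns.  With the default test-based
    decision rules:

    * overdominant — F1 differs from both parents and its mean lies outside
      the parental range;
    * additive — F1 differs from both parents (which themselves differ),
      lies between them, and does not differ from the mid-parent value;
    * dominant — the parents differ and F1 matches exactly one of them;
    * otherwise unclassified.

    ``method='distance'`` replaces the tests with a point-estimate
    heuristic: F1 outside the parental range by more than 20% of the
    parental span is overdominant; otherwise the nearest of the
    mid-parent, lower-parent and higher-parent values decides.
    """
    mf = f1_cpm.mean(axis=0)
    m1 = p1_cpm.mean(axis=0)
    m2 = p2_cpm.mean(axis=0)
    lo = np.minimum(m1, m2)
    hi = np.maximum(m1, m2)
    mode = np.full(len(mf), "unclassified", dtype=object)
    if method == "test":
        sig1 = ranksum_pvalues(f1_cpm, p1_cpm) < alpha
        sig2 = ranksum_pvalues(f1_cpm, p2_cpm) < alpha
        parents_differ = ranksum_pvalues(p1_cpm, p2_cpm) < alpha
        mp_differs = _welch_midparent_pvalues(f1_cpm, p1_cpm, p2_cpm) < alpha
        both = sig1 & sig2
        outside = (mf > hi) | (mf < lo)
        mode[both & outside] = "overdominant"
        mode[both & ~outside & ~mp_differs & parents_differ] = "additive"
        mode[parents_differ & (sig1 ^ sig2)] = "dominant"
    elif method == "distance":
        span = hi - lo
        ok = span > 0
        mp = 0.5 * (lo + hi)
        outside = ok & ((mf > hi + 0.2 * span) | (mf < lo - 0.2 * span))
        mode[outside] = "overdominant"
        inside = ok & ~outside
        d = np.vstack([np.abs(mf - mp), np.abs(mf - lo), np.abs(mf - hi)])
        nearest = np.array(["additive", "dominant", "dominant"], dtype=object)
        mode[inside] = nearest[np.argmin(d, axis=0)][inside]
    else:
        raise ValueError("method must be 'test' or 'distance'")
    return pd.DataFrame({"gene": list(genes), "mode": mode,
                         "f1_mean": mf, "p1_mean": m1, "p2_mean": m2})


def classify_heterosis_mode(f1_values, p1_values, p2_values,
                            alpha: float = 0.05) -> str:
    """Single-gene wrapper around :func:`heterosis_modes_table`."""
    f1 = np.asarray(f1_values, dtype=float)[:, None]
    p1 = np.asarray(p1_values, dtype=float)[:, None]
    p2 = np.asarray(p2_values, dtype=float)[:, None]
    if min(len(f1), len(p1), len(p2)) < 3:
        warnings.warn("fewer than 3 nuclei in a group; mode unclassified")
        return "unclassified"
    return heterosis_modes_table(f1, p1, p2, ["g"], alpha=alpha)["mode"].iloc[0]


def summarize_pattern_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster fractions over the five patterns and the three modes.

    Pattern fractions sum to 1 per cluster; mode fractions sum to 1 over
    classified (non-``unclassified``) records.  Empty clusters are omitted.
    """
    rows = []
    for cluster, sub in records.groupby("cluster"):
        if len(sub) == 0:
            continue
        row = {"cluster": cluster, "n_genes": len(sub)}
        for pat in PATTERNS:
            row[f"frac_{pat}"] = (sub["pattern"] == pat).mean()
        classified = sub[sub["mode"].isin(MODES)]
        for mode in MODES:
            row[f"frac_{mode}"] = (
                (classified["mode"] == mode).mean() if len(classified) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def trio_heterosis_analysis(matrices: Dict[str, AlleleCountMatrix],
                            labels: Optional[Dict[str, np.ndarray]] = None,
                            clusters=None, fc_threshold: float = 1.5,
                            alpha: float = 0.05, k: float = 3.0,
                            min_nuclei: int = 3):
    """Run the full trio comparison: pairwise DEGs, five-pattern classes
    and heterosis modes, per cluster and pooled.

    Returns ``(deg_table, pattern_table, fraction_summary)``.  Patterns and
    modes are assigned only to genes significant in at least one pairwise
    comparison within the group, with a positive lower-parent mean.
    """
    mat = matrices["maternal_parent"]
    pat = matrices["paternal_parent"]
    hyb = matrices["hybrid"]
    lab = labels or {}
    pairs = [
        ("P1-vs-P2", mat, pat, "maternal_parent", "paternal_parent"),
        ("F1-vs-P1", hyb, mat, "hybrid", "maternal_parent"),
        ("F1-vs-P2", hyb, pat, "hybrid", "paternal_parent"),
    ]
    deg = pd.concat(
        [
            pairwise_deg(a, b, lab.get(sa), lab.get(sb), comparison=name,
                         clusters=clusters, fc_threshold=fc_threshold,
                         alpha=alpha, min_nuclei=min_nuclei)
            for name, a, b, sa, sb in pairs
        ],
        ignore_index=True,
    )

    cpm = {s: dense_cpm(m) for s, m in matrices.items()}
    groups = {
        s: _group_indices(lab.get(s), matrices[s].n_nuclei, clusters)
        for s in matrices
    }
    pattern_rows = []
    for key in groups["hybrid"]:
        if not all(key in groups[s] and len(groups[s][key]) >= min_nuclei
                   for s in matrices):
            continue
        sub = {s: cpm[s][groups[s][key]].astype(float) for s in matrices}
        factors = median_ratio_factors(
            {s: sub[s].mean(axis=0) for s in matrices}
        )
        for s in matrices:
            sub[s] = sub[s] * factors[s]
        deg_here = deg[(deg["cluster"] == str(key)) & deg["significant"]]
        deg_genes = sorted(set(deg_here["gene"]))
        if not deg_genes:
            continue
        gi = mat.gene_index(deg_genes)
        modes = heterosis_modes_table(
            sub["hybrid"][:, gi], sub["maternal_parent"][:, gi],
            sub["paternal_parent"][:, gi], deg_genes, alpha=alpha,
        )
        m1 = sub["maternal_parent"][:, gi].mean(axis=0)
        m2 = sub["paternal_parent"][:, gi].mean(axis=0)
        f1 = sub["hybrid"][:, gi].mean(axis=0)
        for j, g in enumerate(deg_genes):
            lp, hp = sorted((m1[j], m2[j]))
            if lp <= 0:
                continue
            pattern_rows.append({
                "gene": g, "cluster": str(key),
                "lp": lp, "hp": hp, "f1": f1[j],
                "pattern": classify_expression_pattern(m1[j], m2[j], f1[j], k=k),
                "mode": modes["mode"].iloc[j],
            })
    patterns = pd.DataFrame(
        pattern_rows,
        columns=["gene", "cluster", "lp", "hp", "f1", "pattern", "mode"],
    )
    summary = summarize_pattern_fractions(patterns) if len(patterns) else pd.DataFrame()
    return deg, patterns, summary
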