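"""Gene-set over-representation by the hypergeometric (one-tailed Fisher)
test with Benjamini–Hochberg FDR.

For a universe of N annotated genes, a term with M member genes and a query
of n genes overlapping the term in m genes, the enrichment p-value is the
exact upper tail P(X >= m) of a hypergeometric(N, M, n) variable — the
probability of drawing at least m term genes when sampling n genes without
replacement from the universe.  Terms at q <= 0.05 (default) are reported
as enriched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gene_sets",
    "write_gene_sets",
    "hypergeom_pvalue",
    "bh_fdr",
    "enrich",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Flat term -> members annotation with an explicit universe."""

    sets: Dict[str, Tuple[str, frozenset]]   # term_id -> (name, members)
    universe: frozenset

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"term {term!r} has {len(stray)} members outside the universe"
                )

    def __len__(self) -> int:
        return len(self.sets)


def read_gene_sets(path, universe: Optional[Iterable[str]] = None) -> GeneSetCollection:
    """Parse a GMT file: term_id <tab> description <tab> member genes.

    The universe defaults to the union of all members; duplicate genes
    within a term are dropped with a warning; malformed lines raise with
    their line number.
    """
    sets: Dict[str, Tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    f">=1 member (got {len(fields)} fields)"
                )
            term, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if len(set(members)) != len(members):
                warnings.warn(f"term {term!r} has duplicate members; deduplicated")
            sets[term] = (desc, frozenset(members))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    if universe is None:
        uni = frozenset().union(*(m for _, m in sets.values()))
    else:
        uni = frozenset(universe)
    return GeneSetCollection(sets=sets, universe=uni)


def write_gene_sets(sets: Dict[str, Tuple[str, Sequence[str]]], path) -> None:
    """Write a term -> (description, members) mapping as GMT."""
    with open(path, "w") as fh:
        for term in sorted(sets):
            desc, members = sets[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def hypergeom_pvalue(N: int, n: int, M: int, m: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= m).

    N: universe size; n: query size; M: term size; m: overlap.  Evaluated
    through log-gamma binomial coefficients, so it is stable at genome
    scale; returns 1 for m = 0 (the empty sum).
    """
    for name, v in (("N", N), ("n", n), ("M", M), ("m", m)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name}={v} must be a non-negative integer")
    if m > min(n, M) or n > N or M > N:
        raise ValueError(
            f"inconsistent counts: need m <= min(n, M) and n, M <= N "
            f"(got N={N}, n={n}, M={M}, m={m})"
        )
    if m == 0:
        return 1.0
    # scipy parameterisation: population N, successes M, draws n
    return float(stats.hypergeom.sf(m - 1, N, M, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    return bh_adjust(p_values)


def enrich(query_genes: Iterable[str], collection: GeneSetCollection,
           fdr_threshold: float = 0.05, min_overlap: int = 1) -> pd.DataFrame:
    """Test every term for over-representation of the query.

    Query genes outside the universe are dropped (logged); terms with
    overlap below ``min_overlap`` are not tested.  Returns a frame sorted
    by q then p then term, with the four counts of the hypergeometric test
    (N, n, M, m) alongside p, q and the ``enriched`` flag.
    """
    query = set(query_genes)
    in_universe = query & collection.universe
    dropped = len(query) - len(in_universe)
    if dropped:
        logger.info("%d query genes outside the universe were dropped", dropped)
    if not in_universe:
        raise ValueError("no query gene overlaps the annotation universe")
    N = len(collection.universe)
    n = len(in_universe)
    rows = []
    for term, (name, members) in collection.sets.items():
        m = len(in_universe & members)
        if m < min_overlap:
            continue
        rows.append({
            "term_id": term, "term_name": name,
            "N": N, "n": n, "M": len(members), "m": m,
            "p_value": hypergeom_pvalue(N, n, len(members), m),
        })
    if not rows:
        return pd.DataFrame(columns=["term_id", "term_name", "N", "n", "M",
                                     "m", "p_value", "q_value", "enriched"])
    res = pd.DataFrame(rows)
    res["q_value"] = bh_fdr(res["p_value"].to_numpy())
    res["enriched"] = res["q_value"] <= fdr_threshold
    return res.sort_values(["q_value", "p_value", "term_id"],
                           kind="mergesort").reset_index(drop=True)
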