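"""Hypergeometric gene-set over-representation with BH FDR.

For a universe of N annotated genes, a term with M members and a query of
n genes overlapping it in m, the p-value is the exact hypergeometric
upper tail P(X >= m); terms at q <= 0.05 are enriched.  Here the query is
the set of planted parent-vs-parent fold-change genes, and the annotation
is built from the simulator's ground truth plus random background terms.
"""

from endoase import SimConfig, simulate_trio
from endoase.enrich import GeneSetCollection, enrich, hypergeom_pvalue
from endoase.simulate import ground_truth_gene_sets

# worked example: universe 20, query 5, term 5, overlap 3
print(f"P(X >= 3 | N=20, n=5, M=5) = {hypergeom_pvalue(20, 5, 5, 3):.6f} "
      "(= 1126/15504)")

trio = simulate_trio(SimConfig(n_nuclei_per_sample=100, n_genes=3000,
                               n_pattern_genes_per_class=30, seed=5))
sets = ground_truth_gene_sets(trio.truth, n_random=15, seed=5)
collection = GeneSetCollection(
    sets={k: (d, frozenset(m)) for k, (d, m) in sets.items()},
    universe=frozenset(trio.matrices["hybrid"].gene_ids),
)

query = [g for g, c in trio.truth.pattern_class_of_gene.items() if c != "none"]
res = enrich(query, collection)
print(f"\nquery: {len(query)} planted fold-change genes; "
      f"{int(res['enriched'].sum())} of {len(res)} terms enriched at q<=0.05:")
cols = ["term_id", "m", "M", "p_value", "q_value"]
print(res[res["enriched"]][cols].to_string(index=False))
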