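"""Five-way expression-pattern classification and heterosis modes.

DEGs among the trio are placed relative to the lower parent (LP) and
higher parent (HP) with fold factor k=3: BLP < LP/k <= BMP < LP <= MPV
<= HP < OMP < k*HP <= OHP, and classified as additive (F1 at the
mid-parent value), dominant (F1 matches one parent) or overdominant
(F1 outside the parental range).
"""

import pandas as pd

from endoase import SimConfig, simulate_trio
from endoase.heterosis import classify_expression_pattern, trio_heterosis_analysis

# the partition on a worked example: parents at 10 and 20
for f1 in (2, 5, 15, 45, 70):
    print(f"parents (10, 20), F1 = {f1:>2} -> "
          f"{classify_expression_pattern(10, 20, f1)}")

trio = simulate_trio(SimConfig(n_nuclei_per_sample=300, n_genes=4000,
                               n_pattern_genes_per_class=40,
                               n_mode_genes_per_class=40, seed=4))
deg, patterns, summary = trio_heterosis_analysis(trio.matrices)

p12 = deg[(deg["comparison"] == "P1-vs-P2") & (deg["cluster"] == "all")]
print(f"\nsignificant parent-vs-parent DEGs: {int(p12['significant'].sum())}")

pooled = patterns[patterns["cluster"] == "all"]
print("\npattern classes among DEGs:")
print(pooled["pattern"].value_counts().to_string())
print("\nheterosis modes among DEGs:")
print(pooled["mode"].value_counts().to_string())

truth = trio.truth
planted = {g: c for g, c in truth.pattern_class_of_gene.items() if c != "none"}
assigned = pooled.set_index("gene")["pattern"]
acc = sum(assigned.get(g) == c for g, c in planted.items()) / len(planted)
print(f"\nplanted pattern-class recovery: {acc:.1%} of {len(planted)} genes")
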