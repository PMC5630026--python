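"""Permutation enrichment of TE subfamilies within CREs.

Every CRE is re-placed uniformly on its own chromosome 1,000 times; a
subfamily is enriched when the observed count of CREs covered >= 20% by
its intervals exceeds the shuffle null (empirical p, BH, FDR < 1%).
"""

from crevol import SimConfig, simulate_bundle
from crevol.enrichment import enrichment_test

bundle = simulate_bundle(SimConfig(n_cres=400, n_genes=100, seed=19))

res = enrichment_test(
    bundle.cre_bed,
    bundle.te_annotation,
    genome_sizes=bundle.genome_sizes["human"],
    n_shuffles=1000,
    seed=19,
)

cols = ["subfamily", "observed", "null_mean", "fold", "empirical_p", "padj", "enriched"]
print(res.table[cols].to_string(index=False, float_format="{:.4g}".format))
n_enr = int(res.table["enriched"].sum())
print("\nthe generator plants TEs inside CREs far more often than chance,")
print(f"so all subfamilies show fold >> 1 and {n_enr} of {len(res.table)} clear")
print(f"FDR < 1%; the floor of the empirical p is 1/{res.n_shuffles + 1}.")
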