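"""Map human CREs to their orthologs and measure sequence divergence.

Each human CRE interval is projected through the alignment blocks into
the five other species; divergence counts mismatches per aligned column
(human-gap columns excluded) over the CRE plus 500 bp flanks.
"""

import pandas as pd

from crevol import SimConfig, simulate_bundle
from crevol.orthology import flag_divergence_outliers, map_interval, pairwise_divergence

bundle = simulate_bundle(SimConfig(n_cres=100, n_genes=50, seed=7))

records = []
n_six_way = 0
for _, row in bundle.cre_bed.iterrows():
    oset = map_interval((row["chrom"], row["start"], row["end"]),
                        bundle.blocks, cre_id=row["name"])
    if oset.six_way:
        n_six_way += 1
        records.append(pairwise_divergence(oset))

print(f"six-way-alignable CREs: {n_six_way}/{len(bundle.cre_bed)}")

divergence = flag_divergence_outliers(pd.concat(records, ignore_index=True))
by_species = divergence.groupby("species")["divergence"].mean().sort_values()
print("\nmean divergence to human (mismatches per compared column):")
for sp, d in by_species.items():
    print(f"  {sp:12s} {d:.4f}")
print("\nchimp sits near 1% and the strepsirrhines near 15%, increasing")
print("with phylogenetic distance; outlier CREs are flagged per species")
print(f"(here {int(divergence['outlier'].sum())} records flagged by the Grubbs screen).")
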