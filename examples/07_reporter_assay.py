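"""Reporter-assay analysis: rank-sum tests against the empty-vector control.

Constructs with activity distributions significantly different from the
control (Wilcoxon rank-sum, exact for small n) are classified as
activators or repressors by their median ratio.
"""

import numpy as np
import pandas as pd

from crevol.reporter import analyze_reporter, wilcoxon_vs_control

p = wilcoxon_vs_control([1, 2, 3], [4, 5, 6])
print(f"fully separated 3v3 example: exact two-sided p = {p}  (2 of C(6,3)=20 orderings)")

rng = np.random.default_rng(0)
rows = [{"construct_id": "ctrl", "replicate": r,
         "activity": rng.lognormal(0, 0.15), "is_control": True} for r in range(6)]
effects = {"ltr_like": 4.0, "sva_like": 0.25, "dead": 1.0}
for name, mult in effects.items():
    for r in range(6):
        rows.append({"construct_id": name, "replicate": r,
                     "activity": mult * rng.lognormal(0, 0.15), "is_control": False})

res = analyze_reporter(pd.DataFrame(rows))
print("\nper-construct results (six replicates each):")
print(res[["construct_id", "median_activity", "median_control", "p", "direction"]]
      .to_string(index=False, float_format="{:.4g}".format))
print("\nthe 4x construct is an activator, the 0.25x construct a repressor,")
print("and the null construct stays non-significant.")
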