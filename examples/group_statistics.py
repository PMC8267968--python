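"""Compare genotype groups on an extracted ERG feature table.

Builds a small two-group cohort, runs the one-way ANOVA and
Kruskal–Wallis designs with Bonferroni-adjusted pairwise post-hocs,
and prints the star-annotated results.
"""

import numpy as np
import pandas as pd

from retphen import stats as rs

rng = np.random.default_rng(3)
table = pd.DataFrame({
    "genotype": ["+/+"] * 6 + ["-/-"] * 6,
    "b_absolute": np.concatenate([rng.normal(450, 40, 6), rng.normal(35, 10, 6)]),
})

for design in ("oneway", "nonparametric"):
    res = rs.compare_groups(table, "b_absolute", "genotype", design=design)
    print(f"{design}:")
    print(rs.results_table(res).to_string(index=False,
                                          float_format=lambda v: f"{v:.3g}"))
    print()
print("Both designs call the knockout's b-wave collapse significant: the ANOVA")
print("reaches **** (p <= 1e-4), while the rank test bottoms out at ** because")
print("a Mann-Whitney U with n = 6 per group cannot produce a smaller p-value.")
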