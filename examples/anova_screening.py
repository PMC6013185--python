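"""Per-feature ANOVA screening with Benjamini-Hochberg FDR control.

Screens one simulated dataset at n = 100 and reports how many truly
differential, correlated-null, and noise features pass each threshold.
"""

import numpy as np

from omicscreen import ScenarioSpec, anova_screen, simulate_dataset

spec = ScenarioSpec(rho=0.4, n_total=100, seed=7)
ds = simulate_dataset(spec)
res = anova_screen(ds.values, ds.labels)

diff = ds.truth.effect_size != 0
noise = ds.truth.category == "noise"
for name, sel in [("raw p < 0.05", res.selected_raw05),
                  ("FDR < 0.05", res.selected_fdr05),
                  ("FDR < 0.20", res.selected_fdr20)]:
    print(f"{name:12s}: {sel.sum():3d} selected "
          f"({sel[diff].sum()}/12 differential, "
          f"{sel[noise].sum()}/100 noise)")
# The unadjusted screen keeps ~5% of the noise features (the per-test
# Type I error); BH adjustment removes nearly all of them while keeping
# most of the planted medium/large effects.
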