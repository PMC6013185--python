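"""Apply the selection methods to a feature table on disk.

Emulates the real-data workflow: a wide CSV (features x samples) plus a
two-column label file, with the BH adjustment applied separately within
two feature strata (e.g. positive/negative ionization modes).  Here the
table is a simulated stand-in written to a temporary directory.
"""

import tempfile
from pathlib import Path

import pandas as pd

from omicscreen import ScenarioSpec, apply_to_table, simulate_dataset

spec = ScenarioSpec(rho=0.4, n_total=100, seed=5)
ds = simulate_dataset(spec)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    fids = [f"met_{i:03d}" for i in range(ds.p)]
    sids = [f"s{j:02d}" for j in range(ds.n)]
    pd.DataFrame(ds.values.T, index=fids, columns=sids).to_csv(
        tmp / "table.csv", index_label="feature_id")
    pd.DataFrame({"sample": sids, "group": ds.labels}).to_csv(
        tmp / "labels.tsv", sep="\t", index=False, header=False)
    # split features into two strata, adjusted separately
    strata = ["pos" if i % 2 == 0 else "neg" for i in range(ds.p)]
    pd.DataFrame({"feature": fids, "stratum": strata}).to_csv(
        tmp / "strata.tsv", sep="\t", index=False, header=False)

    lists, overlap = apply_to_table(
        tmp / "table.csv", tmp / "labels.tsv",
        ["anova_fdr20", "enet:0.5", "enet:1.0"],
        strata_path=tmp / "strata.tsv",
    )

for method, feats in lists.items():
    print(f"{method}: {len(feats)} features selected")
print("\npairwise overlap counts (the Venn table):")
print(overlap)
# The overlap table shows how much the ANOVA and penalized-regression
# selections agree; neither set generally contains the other.
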