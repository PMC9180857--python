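"""Homogeneous-group lettering and treatment ordination.

For each enzyme, Tukey's test at P = 0.01 across all 24 treatment cells
assigns compact letters (cells sharing a letter do not differ significantly;
'a' marks the highest mean).  A z-scored PCA of the cell-mean enzyme matrix
ordinates the treatments.
"""

from pathlib import Path

import pandas as pd

from soilecotox.cli_io import read_tidy_table, write_tidy_table
from soilecotox.group_stats import GroupedMeasurements, letters_table, pca

study = Path("results/study")
if not study.exists():
    raise SystemExit("results/study/ missing - run analysis/01_simulate_study.py first")

enz = read_tidy_table(study / "enzymes.tsv")
enz["cell"] = enz["contamination"] + "." + enz["amendment"] + "." + enz["crop"]

frames = []
for var, sub in enz.groupby("variable", sort=False):
    gm = GroupedMeasurements.from_tidy(sub, group_col="cell")
    tab = letters_table(gm, alpha=0.01)
    tab.insert(0, "variable", var)
    frames.append(tab)
letters = pd.concat(frames, ignore_index=True)
write_tidy_table(letters, "results/stats/letters.tsv")

deh = letters[letters.variable == "deh"].sort_values("mean", ascending=False)
print("dehydrogenase homogeneous groups (Tukey, P = 0.01), top and bottom cells:")
for _, row in pd.concat([deh.head(3), deh.tail(3)]).iterrows():
    print(f"  {row['group']:15s} mean={row['mean']:.2f}  {row['letters']}")
n_distinct = letters.groupby("variable")["letters"].nunique()
print("distinct letter classes per enzyme:", dict(n_distinct))

cell_means = (
    enz.groupby(["cell", "variable"], observed=True)["value"].mean().unstack("variable")
)
res = pca(cell_means.to_numpy(), n_components=2)
scores = pd.DataFrame(res.scores, columns=["PC1", "PC2"], index=cell_means.index).reset_index()
write_tidy_table(scores, "results/stats/pca_scores.tsv")
print(
    "PCA of cell-mean enzyme activities: "
    f"PC1 {100 * res.explained_variance_ratio[0]:.1f}%, "
    f"PC2 {100 * res.explained_variance_ratio[1]:.1f}% of variance"
)
print("wrote results/stats/ (letters, PCA scores)")
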