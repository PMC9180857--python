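"""Compute every ecotoxicology index from the simulated study tables.

Reads results/study/ (run 01_simulate_study.py first) and assembles the full
index report: influence factors of the xenobiotics (IF_X), of humic acid
(IF_H) and of the crops (IF_P) on each enzyme and microbial group, plant
tolerance indices (TI), the BA21 fertility index, shoot:root ratios (PR) and
the colony-development (CD) / ecophysiological-diversity (EP) kinetics.
"""

from pathlib import Path

from soilecotox.cli_io import read_tidy_table, write_tidy_table
from soilecotox.ecotox_indices import build_index_report

study = Path("results/study")
if not study.exists():
    raise SystemExit("results/study/ missing - run analysis/01_simulate_study.py first")

design = read_tidy_table(study / "design.tsv")
report = build_index_report(
    design,
    enzyme_table=read_tidy_table(study / "enzymes.tsv"),
    colony_table=read_tidy_table(study / "colonies.tsv"),
    biomass_table=read_tidy_table(study / "biomass.tsv"),
)
write_tidy_table(report, "results/indices/index_report.tsv")

ifx = report.query("index == 'IF_X'").groupby("contamination")["value"].mean()
print("mean IF_X across variables and strata (IF < 1 = inhibition):")
for level in ("B", "Zn", "B_Zn"):
    print(f"  {level:5s} {ifx[level]:.3f}")
ti = report.query("index == 'TI' and variable == 'aerial_mass'").groupby("contamination")["value"].mean()
print("mean aerial-part tolerance index (TI < 100 = inhibitory):")
for level, v in ti.items():
    print(f"  {level:5s} {v:.1f}")
ba = report.query("index == 'BA21'")
print(f"BA21 range over treatment cells: {ba['value'].min():.1f} - {ba['value'].max():.1f}")
cd = report.query("index == 'CD'").groupby("contamination")["value"].mean()
print("mean colony-development index by contamination:", {k: round(v, 1) for k, v in cd.items()})
print(f"wrote results/indices/index_report.tsv ({len(report)} rows)")
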