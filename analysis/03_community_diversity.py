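"""Community analytics of the simulated OTU table.

Aggregates the OTU table to genus rank, computes per-sample Shannon-Wiener
and Simpson diversity, applies the >=1 % dominance filter, partitions genera
into unique and shared sets across contamination levels, and exports the
decimal-log matrix used for heatmap rendering.
"""

from pathlib import Path

import pandas as pd

from soilecotox.cli_io import read_count_table, write_tidy_table
from soilecotox.community_diversity import (
    UNASSIGNED,
    aggregate_by_rank,
    diversity_table,
    filter_minor_taxa,
    heatmap_matrix,
    relative_abundance,
    taxon_partition,
)

study = Path("results/study/otu_table.tsv")
if not study.exists():
    raise SystemExit("results/study/ missing - run analysis/01_simulate_study.py first")

table = read_count_table(study)
genera = aggregate_by_rank(table, "genus")

div = diversity_table(genera)
write_tidy_table(div, "results/diversity/diversity.tsv")
print("alpha diversity per contamination level (H in nats, D = 1 - sum p^2):")
for _, row in div.iterrows():
    print(f"  {row['sample']:5s} H={row['H']:.3f}  D={row['D']:.3f}")

props = relative_abundance(genera)
groups: dict[str, set] = {}
for s in genera.samples:
    kept = filter_minor_taxa(props[[s]], 0.01) - {UNASSIGNED}
    groups.setdefault(genera.sample_groups.get(s, s), set()).update(kept)
part = taxon_partition(groups)
rows = [
    {"subset": "+".join(sorted(cell)), "taxon": t}
    for cell, taxa in sorted(part.cells.items(), key=lambda kv: sorted(kv[0]))
    for t in sorted(taxa)
]
write_tidy_table(pd.DataFrame(rows, columns=["subset", "taxon"]), "results/diversity/partition.tsv")
print("genera unique to one contamination level (>=1% filter):")
for level, taxa in part.unique.items():
    if taxa:
        print(f"  {level:5s} {', '.join(sorted(taxa))}")
print(f"shared by all levels: {len(part.shared_all)} genera")

hm = heatmap_matrix(genera)
hm.index.name = "taxon_id"
write_tidy_table(hm.reset_index(), "results/diversity/heatmap_log10.tsv")
print("wrote results/diversity/ (diversity, partition, log10 heatmap matrix)")
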