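"""OTU-table analytics: abundance, rank aggregation, diversity, taxon partitions.

The central container is :class:`OtuTable`, a taxa x samples count matrix with a
three-rank lineage (phylum, class, genus) per taxon.  Everything downstream of
sequencing and taxonomic classification happens here: relative abundances,
aggregation to a taxonomic rank, the >=1 % dominance filter, Shannon-Wiener and
Simpson alpha diversity, unique/shared taxon partitioning across treatment
groups, and the decimal-log matrix used for heatmap export.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "genus")
UNASSIGNED = "unassigned"

__all__ = [
    "OtuTable",
    "DiversityResult",
    "TaxonPartition",
    "relative_abundance",
    "aggregate_by_rank",
    "filter_minor_taxa",
    "diversity_indices",
    "diversity_table",
    "taxon_partition",
    "heatmap_matrix",
]


@dataclass
class OtuTable:
    """Taxa x samples count matrix with per-taxon lineage.

    Parameters
    ----------
    counts
        Non-negative integer matrix, taxa as rows (index = taxon ids, unique),
        samples as columns.
    lineage
        One row per taxon (same index as ``counts``) with columns
        ``phylum``, ``class``, ``genus``; missing values become ``unassigned``.
    sample_groups
        Optional mapping of sample label to treatment group (e.g. the
        contamination level), used by group-wise operations.
    """

    counts: pd.DataFrame
    lineage: pd.DataFrame
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 1:
            raise ValueError("OtuTable needs at least one sample")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate taxon ids: {list(dupes)}")
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.index[(self.counts < 0).any(axis=1)]
            raise ValueError(f"negative counts for taxa: {list(bad)}")
        lineage = self.lineage.reindex(self.counts.index)
        for rank in RANKS:
            if rank not in lineage.columns:
                lineage[rank] = UNASSIGNED
        lineage = lineage[list(RANKS)].fillna(UNASSIGNED)
        lineage = lineage.replace("", UNASSIGNED)
        self.lineage = lineage
        self._validate_lineage()

    def _validate_lineage(self) -> None:
        # A named genus under an unassigned class (or class under unassigned
        # phylum) is suspicious but may be genuine in reference taxonomies:
        # warn, never rewrite.
        holes = (self.lineage["phylum"].eq(UNASSIGNED) & self.lineage["class"].ne(UNASSIGNED)) | (
            self.lineage["class"].eq(UNASSIGNED) & self.lineage["genus"].ne(UNASSIGNED)
        )
        if holes.any():
            warnings.warn(
                f"{int(holes.sum())} taxa have a named lower rank under an "
                "unassigned higher rank; lineages left as given",
                UserWarning,
                stacklevel=3,
            )

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def sample_counts(self, sample: str) -> np.ndarray:
        return self.counts[sample].to_numpy()


@dataclass(frozen=True)
class DiversityResult:
    """Alpha diversity of one sample: Shannon-Wiener H and Simpson D."""

    H: float
    D: float


@dataclass(frozen=True)
class TaxonPartition:
    """Venn-style partition of taxa across sample groups.

    ``cells`` maps each non-empty subset of groups (as a frozenset) to the taxa
    present in exactly those groups; ``unique`` and ``shared_all`` are the two
    cells of most interest, exposed directly.
    """

    unique: dict[str, set[str]]
    shared_all: set[str]
    cells: dict[frozenset, set[str]]


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample proportions; columns sum to 1.

    Raises ``ValueError`` for a sample with zero total count.
    """
    totals = table.counts.sum(axis=0)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(f"samples with zero total count: {list(empty.index)}")
    return table.counts / totals


def aggregate_by_rank(table: OtuTable, rank: str) -> OtuTable:
    """Sum counts over taxa sharing a rank label; totals are conserved exactly.

    All ``unassigned`` labels at the rank pool into one bin.  The returned
    table's taxon ids are the rank labels; lineage keeps the ranks at or above
    ``rank`` and marks lower ranks unassigned.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = table.lineage[rank].to_numpy()
    agg = table.counts.groupby(labels, sort=True).sum()
    agg.index.name = table.counts.index.name
    keep = RANKS[: RANKS.index(rank) + 1]
    lineage = (
        table.lineage.groupby(labels, sort=True)
        .first()[list(keep)]
        .reindex(agg.index)
    )
    lineage[rank] = agg.index  # the bin label, incl. pooled "unassigned"
    for lower in RANKS[RANKS.index(rank) + 1 :]:
        lineage[lower] = UNASSIGNED
    # a pooled "unassigned" bin may mix phyla; its higher ranks are unknown
    if UNASSIGNED in lineage.index:
        lineage.loc[UNASSIGNED, [c for c in keep if c != rank]] = UNASSIGNED
    return OtuTable(counts=agg, lineage=lineage, sample_groups=dict(table.sample_groups))


def filter_minor_taxa(proportions: pd.DataFrame, threshold: float = 0.01) -> set[str]:
    """Taxa reaching ``threshold`` proportion in at least one sample (inclusive).

    ``threshold`` must lie strictly inside (0, 1).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    retained = proportions.index[(proportions >= threshold).any(axis=1)]
    return set(retained)


def diversity_indices(
    counts: np.ndarray | pd.Series | list,
    *,
    shannon_base: float = math.e,
    simpson_form: str = "gini",
) -> DiversityResult:
    """Shannon-Wiener and Simpson diversity of one sample's count vector.

    H = -sum p_i log p_i with 0*log 0 := 0 (natural log by default).  The
    Simpson index is reported in the Gini-Simpson complement form
    D = 1 - sum p_i^2 by default, so higher values mean higher diversity;
    ``simpson_form`` may be ``"gini"``, ``"dominance"`` (sum p^2) or
    ``"inverse"`` (1 / sum p^2).
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("sample total must be positive")
    p = x[x > 0] / total
    h = float(-(p * (np.log(p) / math.log(shannon_base))).sum())
    sum_p2 = float((p**2).sum())
    if simpson_form == "gini":
        d = 1.0 - sum_p2
    elif simpson_form == "dominance":
        d = sum_p2
    elif simpson_form == "inverse":
        d = 1.0 / sum_p2
    else:
        raise ValueError(f"unknown simpson_form {simpson_form!r}")
    return DiversityResult(H=h, D=d)


def diversity_table(table: OtuTable, **kwargs) -> pd.DataFrame:
    """Per-sample H and D as a tidy frame (sample, H, D)."""
    rows = [
        {"sample": s, **vars(diversity_indices(table.sample_counts(s), **kwargs))}
        for s in table.samples
    ]
    return pd.DataFrame(rows, columns=["sample", "H", "D"])


def taxon_partition(groups: dict[str, set[str]]) -> TaxonPartition:
    """Set-algebra partition of taxa by group membership.

    ``groups`` maps a group label to the retained taxon set of that group
    (typically presence after the >=1 % filter).  Every taxon lands in exactly
    one cell keyed by the frozenset of groups containing it.
    """
    if len(groups) < 2:
        raise ValueError("taxon_partition needs at least 2 groups")
    membership: dict[str, set[str]] = {}
    for g, taxa in groups.items():
        for t in taxa:
            membership.setdefault(t, set()).add(g)
    cells: dict[frozenset, set[str]] = {}
    for t, gs in membership.items():
        cells.setdefault(frozenset(gs), set()).add(t)
    unique = {g: cells.get(frozenset({g}), set()) for g in groups}
    shared_all = cells.get(frozenset(groups), set())
    return TaxonPartition(unique=unique, shared_all=shared_all, cells=cells)


def heatmap_matrix(
    table: OtuTable,
    *,
    mode: str = "sentinel",
    sentinel: float = np.nan,
) -> pd.DataFrame:
    """Decimal-log abundance matrix for heatmap rendering.

    ``mode="sentinel"`` (default) maps positive counts to log10(count) and zero
    counts to ``sentinel`` (NaN by default, never -inf); ``mode="log1p"`` uses
    the floor form log10(count + 1) everywhere.
    """
    c = table.counts.to_numpy(dtype=float)
    if mode == "sentinel":
        with np.errstate(divide="ignore"):
            m = np.where(c > 0, np.log10(np.where(c > 0, c, 1.0)), sentinel)
    elif mode == "log1p":
        m = np.log10(c + 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(m, index=table.taxa, columns=table.samples)
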