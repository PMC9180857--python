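"""OTU-table analytics: abundance, aggregation, filtering, diversity, partitions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilecotox.community_diversity import (
    OtuTable,
    aggregate_by_rank,
    diversity_indices,
    filter_minor_taxa,
    heatmap_matrix,
    relative_abundance,
    taxon_partition,
)


def random_table(rng, n_taxa=12, n_samples=4):
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(n_taxa, n_samples)),
        index=pd.Index([f"t{i}" for i in range(n_taxa)], name="taxon_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
    lineage = pd.DataFrame(
        {
            "phylum": [f"P{i % 3}" for i in range(n_taxa)],
            "class": [f"C{i % 5}" for i in range(n_taxa)],
            "genus": [f"g{i}" for i in range(n_taxa)],
        },
        index=counts.index,
    )
    return OtuTable(counts=counts, lineage=lineage)


class TestRelativeAbundance:
    def test_hand_values(self, small_otu_table):
        props = relative_abundance(small_otu_table)
        assert props.loc["t1", "s1"] == pytest.approx(0.25)
        assert props.loc["t2", "s1"] == pytest.approx(0.75)
        assert props.loc["t4", "s3"] == pytest.approx(1.0)
        assert np.allclose(props.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_sample_rejected(self, small_otu_table):
        counts = small_otu_table.counts.copy()
        counts["s4"] = 0
        table = OtuTable(counts=counts, lineage=small_otu_table.lineage)
        with pytest.raises(ValueError, match="s4"):
            relative_abundance(table)


class TestAggregateByRank:
    def test_hand_summation(self, small_otu_table):
        phyla = aggregate_by_rank(small_otu_table, "phylum")
        assert phyla.counts.loc["P1", "s1"] == 100  # 25 + 75
        assert phyla.counts.loc["P2", "s2"] == 80  # 20 + 0 + 60

    def test_genus_aggregation_of_genus_table_is_identity(self, small_otu_table):
        g = aggregate_by_rank(small_otu_table, "genus")
        expected = small_otu_table.counts.copy()
        expected.index = small_otu_table.lineage["genus"]
        assert g.counts.sort_index().equals(expected.sort_index())

    def test_totals_conserved_on_random_tables(self, rng):
        for _ in range(1000):
            table = random_table(rng, n_taxa=int(rng.integers(2, 15)))
            for rank in ("phylum", "class", "genus"):
                agg = aggregate_by_rank(table, rank)
                assert (agg.counts.sum(axis=0) == table.counts.sum(axis=0)).all()

    def test_unassigned_pooled(self, small_otu_table):
        lineage = small_otu_table.lineage.copy()
        lineage.loc["t1", "phylum"] = "unassigned"
        lineage.loc["t3", "phylum"] = "unassigned"
        with pytest.warns(UserWarning, match="unassigned"):
            table = OtuTable(counts=small_otu_table.counts, lineage=lineage)
        agg = aggregate_by_rank(table, "phylum")
        assert agg.counts.loc["unassigned", "s2"] == 10 + 20

    def test_unknown_rank_rejected(self, small_otu_table):
        with pytest.raises(ValueError, match="order"):
            aggregate_by_rank(small_otu_table, "order")


class TestFilterMinorTaxa:
    def test_threshold_comparison(self):
        props = pd.DataFrame({"s": [0.90, 0.095, 0.005]}, index=["A", "B", "C"])
        assert filter_minor_taxa(props, 0.01) == {"A", "B"}

    def test_exactly_at_threshold_retained(self):
        props = pd.DataFrame({"s": [0.99, 0.01]}, index=["A", "B"])
        assert filter_minor_taxa(props, 0.01) == {"A", "B"}

    def test_any_sample_suffices(self):
        props = pd.DataFrame({"s1": [0.999, 0.001], "s2": [0.95, 0.05]}, index=["A", "B"])
        assert filter_minor_taxa(props, 0.01) == {"A", "B"}

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_bounds(self, bad):
        props = pd.DataFrame({"s": [1.0]}, index=["A"])
        with pytest.raises(ValueError):
            filter_minor_taxa(props, bad)


class TestDiversityIndices:
    @pytest.mark.parametrize(
        "counts, h, d",
        [
            ([7], 0.0, 0.0),
            ([5, 5, 5, 5], math.log(4), 0.75),
            ([1, 1, 2], 1.039721, 0.625),
        ],
    )
    def test_hand_values(self, counts, h, d):
        res = diversity_indices(counts)
        assert res.H == pytest.approx(h, abs=1e-6)
        assert res.D == pytest.approx(d, abs=1e-9)

    def test_brute_force_oracle(self, rng):
        # independent two-pass oracle in plain Python
        for _ in range(1000):
            counts = rng.integers(0, 50, size=int(rng.integers(1, 20)))
            if counts.sum() == 0:
                continue
            total = int(counts.sum())
            h = d2 = 0.0
            for c in counts:
                if c > 0:
                    p = c / total
                    h -= p * math.log(p)
                    d2 += p * p
            res = diversity_indices(counts)
            assert res.H == pytest.approx(h, abs=1e-10)
            assert res.D == pytest.approx(1 - d2, abs=1e-10)

    def test_agrees_with_skbio(self, rng):
        """Cross-check against the independent scikit-bio implementation."""
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        for _ in range(50):
            counts = rng.integers(1, 200, size=10)
            res = diversity_indices(counts)
            assert res.H == pytest.approx(float(skbio_alpha.shannon(counts, base=math.e)), abs=1e-10)
            # skbio's simpson is the Gini-Simpson complement form
            assert res.D == pytest.approx(float(skbio_alpha.simpson(counts)), abs=1e-10)

    def test_zero_count_taxon_changes_nothing(self):
        a = diversity_indices([4, 3, 2])
        b = diversity_indices([4, 3, 2, 0])
        assert b.H == pytest.approx(a.H, abs=1e-12)
        assert b.D == pytest.approx(a.D, abs=1e-12)

    def test_maximal_iff_uniform(self):
        uniform = diversity_indices([10] * 8)
        assert uniform.H == pytest.approx(math.log(8), abs=1e-12)
        skewed = diversity_indices([17, 10, 10, 10, 10, 10, 10, 3])
        assert skewed.H < uniform.H

    def test_simpson_forms(self):
        counts = [1, 1, 2]
        assert diversity_indices(counts, simpson_form="dominance").D == pytest.approx(0.375)
        assert diversity_indices(counts, simpson_form="inverse").D == pytest.approx(1 / 0.375)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diversity_indices([])
        with pytest.raises(ValueError):
            diversity_indices([0, 0])


class TestTaxonPartition:
    def test_unique_and_shared(self):
        groups = {
            "C": {"a", "b", "c"},
            "B": {"a", "b", "Novosphingobium", "Luteibacter"},
            "Zn": {"a", "b", "c", "Lapilicoccus"},
        }
        part = taxon_partition(groups)
        assert part.unique["B"] == {"Novosphingobium", "Luteibacter"}
        assert part.unique["Zn"] == {"Lapilicoccus"}
        assert part.unique["C"] == set()
        assert part.shared_all == {"a", "b"}
        # cells form a partition of the union
        union = set().union(*groups.values())
        assert set().union(*part.cells.values()) == union
        total = sum(len(v) for v in part.cells.values())
        assert total == len(union)

    def test_identical_groups(self):
        groups = {"X": {"a", "b"}, "Y": {"a", "b"}}
        part = taxon_partition(groups)
        assert part.shared_all == {"a", "b"}
        assert all(not u for u in part.unique.values())

    def test_disjoint_groups(self):
        groups = {g: {f"{g}{i}" for i in range(3)} for g in "WXYZ"}
        part = taxon_partition(groups)
        assert part.shared_all == set()
        assert part.unique == groups

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            taxon_partition({"only": {"a"}})


class TestHeatmapMatrix:
    def test_log10_with_sentinel(self, small_otu_table):
        m = heatmap_matrix(small_otu_table)
        assert m.loc["t4", "s3"] == pytest.approx(2.0)
        assert m.loc["t2", "s1"] == pytest.approx(math.log10(75))
        assert np.isnan(m.loc["t3", "s1"])  # zero count -> sentinel, never -inf

    def test_count_one_and_custom_sentinel(self, small_otu_table):
        counts = small_otu_table.counts.copy()
        counts.loc["t1", "s1"] = 1
        table = OtuTable(counts=counts, lineage=small_otu_table.lineage)
        m = heatmap_matrix(table, sentinel=-1.0)
        assert m.loc["t1", "s1"] == 0.0
        assert m.loc["t3", "s1"] == -1.0

    def test_log1p_mode(self, small_otu_table):
        m = heatmap_matrix(small_otu_table, mode="log1p")
        assert m.loc["t3", "s1"] == 0.0
        assert m.loc["t4", "s3"] == pytest.approx(math.log10(101))


class TestOtuTableValidation:
    def test_negative_counts_rejected(self, small_otu_table):
        counts = small_otu_table.counts.copy()
        counts.loc["t1", "s1"] = -5
        with pytest.raises(ValueError, match="t1"):
            OtuTable(counts=counts, lineage=small_otu_table.lineage)

    def test_duplicate_taxa_rejected(self, small_otu_table):
        counts = small_otu_table.counts.copy()
        counts.index = pd.Index(["t1", "t1", "t3", "t4", "t5"], name="taxon_id")
        with pytest.raises(ValueError, match="duplicate"):
            OtuTable(counts=counts, lineage=small_otu_table.lineage)

    def test_lineage_gap_warns_not_rewrites(self, small_otu_table):
        lineage = small_otu_table.lineage.copy()
        lineage.loc["t1", "class"] = "unassigned"  # genus g1 under unassigned class
        with pytest.warns(UserWarning, match="unassigned"):
            table = OtuTable(counts=small_otu_table.counts, lineage=lineage)
        assert table.lineage.loc["t1", "genus"] == "g1"
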