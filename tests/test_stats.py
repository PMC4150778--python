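"""Concentration statistics: direct implementations and the fast engine."""

import numpy as np
import pytest

from cofunc.engine import QUANTITIES, PermutationEngine
from cofunc.genome import GeneRecord, GenomeLayout
from cofunc.groups import FunctionalGroup, GroupCollection
from cofunc.permutation import permute_layout
from cofunc.stats import (
    STATISTICS,
    StatisticUndefinedError,
    chromosome_count_histogram,
    chromosomes_involved,
    compute_statistic,
    cumulative_chromosome_curve,
    group_mean_distances,
    mean_chromosome_count,
    mean_of_group_means,
    pair_distances,
)


class TestChromosomeDispersal:
    def test_single_chromosome_group(self, toy_layout):
        g = FunctionalGroup("G", "pathway", frozenset({"a", "b", "c"}))
        assert chromosomes_involved(g, toy_layout) == 1

    def test_three_chromosome_group(self, toy_layout):
        g = FunctionalGroup("G", "pathway", frozenset({"a", "d", "f"}))
        assert chromosomes_involved(g, toy_layout) == 3

    def test_unmapped_group_errors(self, toy_layout):
        g = FunctionalGroup("G", "pathway", frozenset({"x", "y"}))
        with pytest.raises(StatisticUndefinedError):
            chromosomes_involved(g, toy_layout)

    def test_mean_count(self, toy_layout):
        coll = GroupCollection(
            "pathway",
            (
                FunctionalGroup("G1", "pathway", frozenset({"a", "b"})),   # 1
                FunctionalGroup("G2", "pathway", frozenset({"a", "d", "f"})),  # 3
            ),
        )
        assert mean_chromosome_count(coll, toy_layout) == 2.0

    def test_histogram_and_cumulative(self, toy_layout):
        coll = GroupCollection(
            "pathway",
            (
                FunctionalGroup("G1", "pathway", frozenset({"a", "b"})),
                FunctionalGroup("G2", "pathway", frozenset({"f", "g"})),
                FunctionalGroup("G3", "pathway", frozenset({"a", "d"})),
            ),
        )
        f = chromosome_count_histogram(coll, toy_layout)
        assert f[1] == 2 and f[2] == 1 and f.sum() == 3
        assert list(cumulative_chromosome_curve(coll, toy_layout)) == [0, 2, 3, 3]


class TestGroupDistances:
    def test_linear_intra_mean(self, toy_layout):
        coll = GroupCollection(
            "pathway",
            (FunctionalGroup("G", "pathway", frozenset({"a", "b", "c"})),),
        )
        recs = group_mean_distances(coll, toy_layout, "linear", "intra_only")
        # midpoints 200/600/1000 -> pair distances 400, 800, 400
        assert recs[0].d_i == pytest.approx(np.mean([400, 800, 400]))
        assert recs[0].n_pairs == 3

    def test_cross_chromosome_group_omitted(self, toy_layout):
        coll = GroupCollection(
            "pathway",
            (
                FunctionalGroup("G1", "pathway", frozenset({"a", "d"})),  # inter only
                FunctionalGroup("G2", "pathway", frozenset({"a", "b"})),
            ),
        )
        recs = group_mean_distances(coll, toy_layout, "linear", "intra_only")
        assert [r.group_id for r in recs] == ["G2"]

    def test_all_groups_omitted_errors(self, toy_layout):
        coll = GroupCollection(
            "ppi", (FunctionalGroup("G1", "ppi", frozenset({"a", "d"})),)
        )
        with pytest.raises(StatisticUndefinedError):
            group_mean_distances(coll, toy_layout, "linear", "intra_only")

    def test_mean_of_group_means_unweighted(self):
        from cofunc.stats import GroupDistanceRecord

        recs = [
            GroupDistanceRecord("A", 100.0, 10, "all", "linear"),
            GroupDistanceRecord("B", 300.0, 1, "all", "linear"),
        ]
        assert mean_of_group_means(recs) == 200.0

    def test_pair_table_row_counts(self, toy_layout):
        coll = GroupCollection(
            "pathway",
            (
                FunctionalGroup("G1", "pathway", frozenset({"a", "d", "f"})),
                FunctionalGroup("G2", "pathway", frozenset({"a", "d"})),
            ),
        )
        table = pair_distances(coll, toy_layout, "linear", "all")
        # linear distances undefined across chromosomes -> all pairs excluded
        assert len(table) == 0
        coll2 = GroupCollection(
            "pathway",
            (
                FunctionalGroup("G1", "pathway", frozenset({"a", "b", "c"})),
                FunctionalGroup("G2", "pathway", frozenset({"a", "b"})),
            ),
        )
        table2 = pair_distances(coll2, toy_layout, "linear", "intra_only")
        assert len(table2) == 4  # C(3,2) + 1; shared pair appears per group
        assert (table2.groupby("group_id").size() == [3, 1]).all()


class TestEngineAgainstDirectImplementation:
    def test_all_statistics_match_on_permuted_layouts(self, small_study):
        _, layout, collection, cmap = small_study
        rng = np.random.default_rng(9)
        for trial in range(5):
            scheme = "global" if trial % 2 else "within_chromosome"
            lay = permute_layout(layout, scheme, rng) if trial else layout
            eng = PermutationEngine(lay, collection, cmap)
            for name, spec in STATISTICS.items():
                fast = spec.reduce(eng.observed([spec.quantity])[spec.quantity])
                slow = compute_statistic(name, lay, collection, cmap)
                assert fast == pytest.approx(slow, abs=1e-9), name

    def test_replicate_evaluation_matches_naive_on_draws(self, small_study):
        """Engine-evaluated permutations equal naive statistics on the
        object-level permuted layout built from the same assignment."""
        _, layout, collection, cmap = small_study
        eng = PermutationEngine(layout, collection, cmap)
        genes = list(layout.iter_genes())
        loci = layout.loci()
        rng = np.random.default_rng(11)
        for _ in range(3):
            loc = eng.permutation("global", rng)
            rebuilt = GenomeLayout(
                [
                    GeneRecord(genes[g].gene_id, *loci[loc[g]])
                    for g in range(len(genes))
                ]
            )
            vals = eng.evaluate(loc, list(QUANTITIES))
            for name, spec in STATISTICS.items():
                fast = spec.reduce(vals[spec.quantity])
                slow = compute_statistic(name, rebuilt, collection, cmap)
                assert fast == pytest.approx(slow, abs=1e-9), name

    def test_intra_pair_count_invariant_under_within_scheme(self, small_study):
        _, layout, collection, cmap = small_study
        eng = PermutationEngine(layout, collection, None)
        base = eng.observed(["linear_group_means"])["linear_group_means"]
        base_defined = ~np.isnan(base)
        for q in eng.sample("within_chromosome", 25, 4, ["linear_group_means"]):
            assert np.array_equal(
                ~np.isnan(q["linear_group_means"]), base_defined
            )

    def test_statistics_are_pure(self, small_study):
        _, layout, collection, cmap = small_study
        a = compute_statistic("spatial_all_group_mean", layout, collection, cmap)
        b = compute_statistic("spatial_all_group_mean", layout, collection, cmap)
        assert a == b
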