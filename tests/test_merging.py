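"""Cross-dataset merging, overlap matrices, genome metrics, sharing and sweeps."""

from __future__ import annotations

import pytest

from conftest import make_dataset, make_index, rank_ids
from paracluster.chaining import Chain, detect_chains_all
from paracluster.merging import (
    OrthologMap,
    cluster_sharing,
    dataset_overlap_matrix,
    family_clustering_fractions,
    genome_metrics,
    merge_across_datasets,
    paraclusters_from_frame,
    paraclusters_to_frame,
    species_specific_fraction,
    threshold_sweep,
)
from paracluster.significance import filter_significant, score_chains


def chain(dataset, ranks, term="T", chrom="chr1"):
    return Chain(
        dataset_name=dataset,
        chromosome=chrom,
        member_ranks=tuple(ranks),
        common_terms=frozenset({term}),
        p_value=1e-9,
        e_value=1e-5,
    )


class TestMergeAcrossDatasets:
    def test_identical_chains_merge_into_one(self):
        index = make_index(10)
        merged = merge_across_datasets(
            {"d1": [chain("d1", (2, 3, 4))], "d2": [chain("d2", (2, 3, 4))]}, index
        )
        (pc,) = merged
        assert pc.member_gene_ids == frozenset(rank_ids([2, 3, 4]))
        assert set(pc.contributing) == {"d1", "d2"}

    def test_overlapping_chains_take_union(self):
        index = make_index(10)
        merged = merge_across_datasets(
            {"d1": [chain("d1", range(1, 6))], "d2": [chain("d2", range(5, 10))]},
            index,
        )
        (pc,) = merged
        assert pc.member_gene_ids == frozenset(rank_ids(range(1, 10)))
        assert (pc.start_rank, pc.end_rank) == (1, 9)

    def test_disjoint_chains_stay_separate(self):
        index = make_index(10)
        merged = merge_across_datasets(
            {"d1": [chain("d1", (1, 3))], "d2": [chain("d2", (2, 4))]}, index
        )
        assert len(merged) == 2

    def test_merge_is_transitive(self):
        index = make_index(12)
        merged = merge_across_datasets(
            {
                "d1": [chain("d1", (1, 2))],
                "d2": [chain("d2", (2, 5))],
                "d3": [chain("d3", (5, 9))],
            },
            index,
        )
        (pc,) = merged
        assert pc.member_ranks == (1, 2, 5, 9)

    def test_interstitial_in_one_dataset_member_in_another(self):
        # rank 3 is interstitial for d1's chain but a member of d2's:
        # after merging it must be a member, not an interstitial
        index = make_index(10)
        merged = merge_across_datasets(
            {"d1": [chain("d1", (2, 4))], "d2": [chain("d2", (3, 4))]}, index
        )
        (pc,) = merged
        assert pc.member_ranks == (2, 3, 4)
        assert pc.interstitial_gene_ids == ()

    def test_interstitials_recomputed_over_merged_span(self):
        index = make_index(10)
        merged = merge_across_datasets({"d1": [chain("d1", (2, 5))]}, index)
        (pc,) = merged
        assert pc.interstitial_gene_ids == tuple(rank_ids([3, 4]))

    def test_paracluster_table_round_trip(self):
        index = make_index(10)
        merged = merge_across_datasets(
            {"d1": [chain("d1", (1, 2)), chain("d1", (6, 8))]}, index
        )
        back = paraclusters_from_frame(paraclusters_to_frame(merged))
        assert [(p.member_ranks, p.contributing) for p in back] == [
            (p.member_ranks, p.contributing) for p in merged
        ]


class TestOverlapMatrix:
    def test_single_dataset_diagonal(self):
        index = make_index(10)
        mat = dataset_overlap_matrix({"d1": [chain("d1", (1, 2, 3))]}, index)
        assert mat.shape == (1, 1)
        assert mat.loc["d1", "d1"] == 3

    def test_identical_chains_give_equal_cells(self):
        index = make_index(10)
        mat = dataset_overlap_matrix(
            {"d1": [chain("d1", (1, 2))], "d2": [chain("d2", (1, 2))]}, index
        )
        assert (mat.to_numpy() == 2).all()

    def test_matches_set_intersection_oracle(self, small_sim_parts):
        _, index, datasets = small_sim_parts
        chains = detect_chains_all(index, datasets)
        significant = {
            n: filter_significant(score_chains(c, datasets[n], index.N))
            for n, c in chains.items()
        }
        mat = dataset_overlap_matrix(significant, index)
        gene_sets = {
            n: {g for c in cs for g in c.member_gene_ids(index)}
            for n, cs in significant.items()
        }
        for a in mat.index:
            for b in mat.columns:
                assert mat.loc[a, b] == len(gene_sets[a] & gene_sets[b])
        assert (mat.to_numpy() == mat.to_numpy().T).all()


class TestGenomeMetrics:
    def test_percent_of_single_cluster(self):
        index = make_index(100)
        merged = merge_across_datasets({"d": [chain("d", (1, 2, 3))]}, index)
        summary = genome_metrics(merged, {"d": [chain("d", (1, 2, 3))]}, index)
        assert summary.merged_percent == pytest.approx(3.0)
        assert summary.merged_count == 1

    def test_size_distribution_and_cumulative(self):
        index = make_index(100)
        chains = {"d": [chain("d", (1, 2)), chain("d", (10, 11, 13, 14))]}
        merged = merge_across_datasets(chains, index)
        summary = genome_metrics(merged, chains, index)
        dist = summary.size_distribution.set_index("size_l")
        assert dist.loc[2, "cluster_count"] == 1
        assert dist.loc[4, "cluster_count"] == 1
        assert dist.loc[4, "genes_incl_interstitial"] == 5  # one interstitial at 12
        assert dist["cumulative_percent"].iloc[-1] == pytest.approx(
            summary.merged_percent
        )

    def test_adjacency_fractions(self):
        # members at ranks 1,2,14: two genes adjacent to a co-member, the
        # third is 12 away (outside the within-10 window)
        index = make_index(100)
        chains = {"d": [chain("d", (1, 2, 14))]}
        merged = merge_across_datasets(chains, index)
        summary = genome_metrics(merged, chains, index)
        assert summary.percent_adjacent == pytest.approx(2.0)
        assert summary.percent_within_10 == pytest.approx(2.0)

    def test_merged_genes_at_least_each_dataset(self, small_sim_parts):
        _, index, datasets = small_sim_parts
        chains = detect_chains_all(index, datasets)
        significant = {
            n: filter_significant(score_chains(c, datasets[n], index.N))
            for n, c in chains.items()
        }
        merged = merge_across_datasets(significant, index)
        summary = genome_metrics(merged, significant, index)
        assert (
            summary.per_dataset["genes_in_paraclusters"].max() <= summary.merged_genes
        )


class TestFamilyClusteringFractions:
    def test_fraction_bounds(self):
        index = make_index(30)
        ds = make_dataset(
            [(g, "F4") for g in rank_ids(range(1, 5))]
            + [(g, "F10") for g in rank_ids(range(10, 20))]
        )
        merged = merge_across_datasets({"d": [chain("d", (1, 2, 3, 4))]}, index)
        table, hist = family_clustering_fractions(ds, merged)
        t = table.set_index("family")
        assert t.loc["F4", "fraction"] == 1.0
        assert t.loc["F10", "fraction"] == 0.0
        # only F10 reaches the size-10 histogram, in the lowest bin
        assert hist["family_count"].sum() == 1
        assert hist.set_index("percent_clustered").loc["0-10%", "family_count"] == 1


class TestClusterSharing:
    def test_empty_map_all_specific(self):
        index = make_index(10)
        clusters = merge_across_datasets({"d": [chain("d", (1, 2))]}, index)
        shared, specific = cluster_sharing(clusters, clusters, OrthologMap(set()))
        assert (shared, specific) == (0.0, 1.0)

    def test_perfect_map_all_shared(self):
        index = make_index(10)
        clusters = merge_across_datasets({"d": [chain("d", (1, 2))]}, index)
        omap = OrthologMap({(g, g, "inparalog") for g in rank_ids([1, 2])})
        shared, specific = cluster_sharing(clusters, clusters, omap)
        assert (shared, specific) == (1.0, 0.0)

    def test_monotone_in_added_pairs(self):
        index = make_index(20)
        a = merge_across_datasets(
            {"d": [chain("d", (1, 2)), chain("d", (5, 6)), chain("d", (9, 10))]}, index
        )
        b = merge_across_datasets({"d": [chain("d", (15, 16))]}, index)
        pairs = [
            ("g001", "g015", "inparalog"),
            ("g005", "g016", "inparalog"),
            ("g009", "g015", "inparalog"),
        ]
        previous = 0.0
        for upto in range(len(pairs) + 1):
            shared, _ = cluster_sharing(a, b, OrthologMap(set(pairs[:upto])))
            assert shared >= previous
            previous = shared
        assert previous == 1.0

    def test_out_paralogs_do_not_count_for_inparalog_sharing(self):
        index = make_index(10)
        a = merge_across_datasets({"d": [chain("d", (1, 2))]}, index)
        omap = OrthologMap({("g001", "g001", "outparalog")})
        shared, _ = cluster_sharing(a, a, omap)
        assert shared == 0.0
        shared_out, _ = cluster_sharing(a, a, omap, relations=("outparalog",))
        assert shared_out == 1.0

    def test_species_specific_fraction(self):
        index = make_index(10)
        a = merge_across_datasets(
            {"d": [chain("d", (1, 2)), chain("d", (5, 6))]}, index
        )
        partner = merge_across_datasets({"d": [chain("d", (1, 2))]}, index)
        omap = OrthologMap({("g001", "g001", "inparalog")})
        frac = species_specific_fraction(a, {"b": partner}, {"b": omap})
        assert frac == 0.5

    def test_unknown_relation_rejected(self):
        with pytest.raises(ValueError, match="relation"):
            OrthologMap({("a", "b", "cousin")})


class TestThresholdSweep:
    def test_totals_non_decreasing_and_limits(self, small_sim_parts):
        _, index, datasets = small_sim_parts
        thresholds = [0.01, 0.05, 0.1, 0.15, 1e9]
        table = threshold_sweep(index, datasets, thresholds)
        for name, grp in table.groupby("dataset"):
            genes = grp.sort_values("threshold")["genes_in_paraclusters"].tolist()
            assert genes == sorted(genes)
        # at a huge threshold every chain passes
        chains = detect_chains_all(index, datasets)
        for name, cs in chains.items():
            total = len(
                {
                    g
                    for c in cs
                    for g in c.member_gene_ids(index)
                }
            )
            row = table[(table.dataset == name) & (table.threshold == 1e9)]
            assert int(row["genes_in_paraclusters"].iloc[0]) == total

    def test_unsorted_thresholds_rejected(self, small_sim_parts):
        _, index, datasets = small_sim_parts
        with pytest.raises(ValueError, match="ascending"):
            threshold_sweep(index, datasets, [0.1, 0.01])
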