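"""Synthetic-genome generator: determinism, ledger exactness, mixture shape."""

from __future__ import annotations

import numpy as np
import pytest

from paracluster.chaining import detect_chains_all
from paracluster.genome_model import term_frequencies
from paracluster.merging import merge_across_datasets
from paracluster.significance import filter_significant, score_chains
from paracluster.simulate import (
    PlantedClusterSpec,
    SimConfig,
    TruthLedger,
    default_chromosome_sizes,
    generate_genome,
    generate_ortholog_map,
    random_planted_specs,
)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        config = SimConfig(
            n_genes=800,
            chromosome_sizes=(500, 300),
            planted_clusters=(PlantedClusterSpec(4), PlantedClusterSpec(3, gaps=(2,))),
            seed=5,
        )
        a = generate_genome(config)
        b = generate_genome(config)
        assert a.genes.equals(b.genes)
        assert a.annotations.equals(b.annotations)
        assert a.pairs.equals(b.pairs)
        assert a.ledger == b.ledger

    def test_different_seeds_differ(self):
        base = dict(n_genes=800, chromosome_sizes=(500, 300))
        a = generate_genome(SimConfig(seed=1, **base))
        b = generate_genome(SimConfig(seed=2, **base))
        assert not a.genes.equals(b.genes)


class TestLedgerExactness:
    def test_emitted_frequencies_equal_family_sizes_minus_dropout(self):
        sim = generate_genome(
            SimConfig(n_genes=1500, chromosome_sizes=(1000, 500), dropout=0.2, seed=3)
        )
        index = sim.index()
        datasets = sim.datasets(index)
        for name in ("ensembl_family", "scop"):
            ds = datasets[name]
            dropped = set(sim.ledger.dropped[name])
            for fam, members in sim.ledger.families.items():
                expected = sum(1 for g in members if g not in dropped)
                assert ds.freq.get(fam, 0) == expected
            for dom, carriers in sim.ledger.hf_carriers.items():
                expected = sum(1 for g in carriers if g not in dropped)
                if name == "scop":
                    assert ds.freq.get(dom, 0) == expected
                else:
                    assert dom not in ds.freq

    def test_pair_dataset_components_equal_surviving_families(self):
        sim = generate_genome(
            SimConfig(n_genes=1200, chromosome_sizes=(1200,), dropout=0.15, seed=4)
        )
        index = sim.index()
        ds = sim.datasets(index)["ensembl_paralogs"]
        dropped = set(sim.ledger.dropped["ensembl_paralogs"])
        expected_sizes = sorted(
            kept
            for members in sim.ledger.families.values()
            if (kept := sum(1 for g in members if g not in dropped)) >= 2
        )
        assert sorted(ds.freq.values()) == expected_sizes

    def test_ledger_json_round_trip(self, tmp_path):
        sim = generate_genome(SimConfig(n_genes=500, chromosome_sizes=(500,), seed=6))
        path = sim.ledger.to_json(tmp_path / "ledger.json")
        back = TruthLedger.from_json(path)
        assert back == sim.ledger


class TestFamilyMixture:
    def test_all_singletons_share_nothing(self):
        config = SimConfig(
            n_genes=400,
            chromosome_sizes=(400,),
            singleton_fraction=1.0,
            high_frequency_domains=(),
            dropout=0.0,
            seed=1,
        )
        sim = generate_genome(config)
        freq = term_frequencies(sim.datasets(sim.index())["interpro"].terms)
        assert set(freq.values()) == {1}
        assert sim.pairs.empty

    def test_mixture_shape_matches_configuration(self):
        sim = generate_genome(SimConfig(seed=8))  # default 20k-gene conditions
        sizes = np.array([len(v) for v in sim.ledger.families.values()])
        n = sim.ledger.n_genes
        singleton_genes = (sizes == 1).sum()
        # configured singleton fraction, within sampling/rounding slack
        assert singleton_genes / n == pytest.approx(0.683, abs=0.02)
        multi = sizes[sizes >= 2]
        planted = sum(1 for f in sim.ledger.families if f.startswith("PFAM"))
        assert planted == 0
        assert 2.5 < multi.mean() < 4.5  # mostly small families
        assert multi.max() <= 100
        large = (multi > 10).sum()
        assert 0 < large / len(multi) < 0.12  # a thin heavy tail exists

    def test_chromosome_sizes_partition_and_include_micro(self):
        sizes = default_chromosome_sizes(20_000)
        assert sum(sizes) == 20_000
        assert min(sizes) < 50  # micro-chromosomes present

    def test_planted_specs_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            PlantedClusterSpec(1)
        with pytest.raises(ValueError, match="boundaries"):
            PlantedClusterSpec(2, gaps=(1, 1))
        with pytest.raises(ValueError, match="exceed"):
            SimConfig(n_genes=10, chromosome_sizes=(10,),
                      planted_clusters=(PlantedClusterSpec(11),))

    def test_infeasible_layout_rejected(self):
        # both clusters are wider than any chromosome
        config = SimConfig(
            n_genes=52,
            chromosome_sizes=(26, 26),
            planted_clusters=(
                PlantedClusterSpec(27),
                PlantedClusterSpec(25),
            ),
            high_frequency_domains=(),
            seed=0,
        )
        with pytest.raises(ValueError, match="could not place"):
            generate_genome(config)


class TestPlantedClusters:
    def test_tandem_array_recovered_end_to_end(self):
        config = SimConfig(
            n_genes=600,
            chromosome_sizes=(600,),
            planted_clusters=(PlantedClusterSpec(5),),
            high_frequency_domains=(),
            dropout=0.0,
            seed=2,
        )
        sim = generate_genome(config)
        (rec,) = sim.ledger.planted
        assert rec["end_rank"] - rec["start_rank"] + 1 == 5
        index = sim.index()
        datasets = sim.datasets(index)
        chains = detect_chains_all(index, datasets)
        sig = {
            n: filter_significant(score_chains(c, datasets[n], index.N))
            for n, c in chains.items()
        }
        merged = merge_across_datasets(sig, index)
        planted_members = set(rec["member_gene_ids"])
        assert any(pc.member_gene_ids == frozenset(planted_members) for pc in merged)

    def test_gapped_layout_matches_spec(self):
        config = SimConfig(
            n_genes=500,
            chromosome_sizes=(500,),
            planted_clusters=(PlantedClusterSpec(4, gaps=(2, 3)),),
            seed=9,
        )
        sim = generate_genome(config)
        (rec,) = sim.ledger.planted
        ranks = rec["member_ranks"]
        assert len(ranks) == 4
        assert rec["end_rank"] - rec["start_rank"] + 1 == 4 + 2 + 3
        internal = np.diff(ranks) - 1
        assert sorted(int(x) for x in internal if x > 0) == [2, 3]

    def test_nested_cluster_placed_inside_host_gap(self):
        config = SimConfig(
            n_genes=500,
            chromosome_sizes=(500,),
            planted_clusters=(
                PlantedClusterSpec(4, gaps=(10,)),
                PlantedClusterSpec(3, nested_in=0),
            ),
            seed=12,
        )
        sim = generate_genome(config)
        host, guest = sim.ledger.planted
        assert host["start_rank"] < guest["start_rank"]
        assert guest["end_rank"] < host["end_rank"]
        host_members = set(host["member_ranks"])
        assert not host_members & set(guest["member_ranks"])

    def test_random_specs_within_requested_ranges(self):
        rng = np.random.default_rng(0)
        specs = random_planted_specs(50, rng, members=(3, 20), gap_length=(1, 5))
        assert len(specs) == 50
        assert all(3 <= s.n_members <= 20 for s in specs)
        assert all(1 <= g <= 5 for s in specs for g in s.gaps)


class TestOrthologMap:
    def _two_ledgers(self, n_clusters=20):
        specs = tuple(PlantedClusterSpec(3) for _ in range(n_clusters))
        base = dict(
            n_genes=800, chromosome_sizes=(800,), planted_clusters=specs,
            high_frequency_domains=(),
        )
        a = generate_genome(SimConfig(seed=21, **base))
        b = generate_genome(SimConfig(seed=22, **base))
        return a.ledger, b.ledger

    def test_zero_fraction_empty_map(self):
        la, lb = self._two_ledgers()
        omap = generate_ortholog_map(la, lb, 0.0, seed=1)
        assert omap.pairs == set()
        assert la.conserved_clusters == []

    def test_full_fraction_links_every_cluster(self):
        la, lb = self._two_ledgers()
        omap = generate_ortholog_map(la, lb, 1.0, seed=1)
        assert la.conserved_clusters == list(range(20))
        linked_a = {a for a, _, _ in omap.pairs}
        for rec in la.planted:
            assert set(rec["member_gene_ids"]) <= linked_a

    def test_partial_fraction_binomial_and_flagged(self):
        la, lb = self._two_ledgers(n_clusters=50)
        omap = generate_ortholog_map(la, lb, 0.4, seed=3)
        k = len(la.conserved_clusters)
        assert 10 <= k <= 30  # within ~3 sd of Binomial(50, 0.4)
        linked_a = {a for a, _, _ in omap.pairs}
        expected = {
            g
            for i in la.conserved_clusters
            for g in la.planted[i]["member_gene_ids"]
        }
        assert linked_a == expected
        assert all(rel == "inparalog" for _, _, rel in omap.pairs)
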