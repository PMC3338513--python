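"""Shared fixtures and tiny-genome builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from paracluster.genome_model import AnnotationDataset, GenomeIndex, build_gene_index
from paracluster.simulate import SimConfig, generate_genome, random_planted_specs


def make_index(chrom_sizes, start_step: int = 100) -> GenomeIndex:
    """A genome of consecutive genes g001, g002, ... over the given chromosomes.

    ``chrom_sizes`` is either an int (one chromosome) or a mapping
    chromosome -> gene count; gene ids are global and sequential in rank order.
    """
    if isinstance(chrom_sizes, int):
        chrom_sizes = {"chr1": chrom_sizes}
    records = []
    i = 0
    for chrom, count in chrom_sizes.items():
        for j in range(count):
            i += 1
            records.append(
                {
                    "gene_id": f"g{i:03d}",
                    "chromosome": chrom,
                    "start": (j + 1) * start_step,
                    "end": (j + 1) * start_step + start_step // 2,
                }
            )
    return build_gene_index(records, list(chrom_sizes))


def make_dataset(assignments, name: str = "ds", index=None) -> AnnotationDataset:
    """Dataset from (gene_id, term) pairs; gene ids as produced by make_index."""
    return AnnotationDataset.from_assignments(name, assignments, index=index)


def rank_ids(ranks) -> list[str]:
    return [f"g{r:03d}" for r in ranks]


@pytest.fixture(scope="session")
def small_sim():
    """A 2,000-gene genome with 10 planted clusters, shared across tests."""
    rng = np.random.default_rng(11)
    config = SimConfig(
        n_genes=2000,
        chromosome_sizes=(700, 500, 400, 250, 120, 30),
        planted_clusters=random_planted_specs(10, rng, members=(3, 8), gap_length=(1, 3)),
        high_frequency_domains=(("HF_DOM", 60),),
        seed=11,
    )
    return generate_genome(config)


@pytest.fixture(scope="session")
def small_sim_parts(small_sim):
    index = small_sim.index()
    datasets = small_sim.datasets(index)
    return small_sim, index, datasets
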