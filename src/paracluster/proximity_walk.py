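"""Chromosome-walk proximity statistics and permuted-genome baselines.

The walk evaluates each gene in succession and asks whether the gene *n*
positions further along the same chromosome shares at least one annotation
term. Span uses the convention that n = 2 means adjacent genes, so the rank
offset is d = n - 1. Each related forward pair is counted once, pairs never
straddle a chromosome boundary.

The null model permutes gene order without disturbing annotations: genes are
shuffled genome-wide into the fixed positional slots (chromosome sizes are
preserved), each gene keeping its term set. Averaging several permuted genomes
yields a nearly flat baseline whose slight negative slope reflects the finite
size of individual chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import AnnotationDataset, Gene, GenomeIndex

__all__ = [
    "OVERFLOW",
    "WalkProfile",
    "PermutationBaseline",
    "relatedness_profile",
    "nearest_related_histogram",
    "permute_gene_order",
    "permutation_baseline",
    "walk_profile_frame",
    "nearest_histogram_frame",
]

#: histogram key for genes with no related gene within the search cap
OVERFLOW = -1


@dataclass
class WalkProfile:
    dataset_name: str
    max_span: int
    counts_by_span: dict[int, int]
    nearest_histogram: dict[int, int] = field(default_factory=dict)
    n_genes_evaluated: int = 0

    def total_related_pairs(self) -> int:
        return sum(self.counts_by_span.values())


@dataclass
class PermutationBaseline:
    profiles: list[WalkProfile]
    mean_counts_by_span: dict[int, float]
    mean_nearest_histogram: dict[int, float]
    n_permutations: int
    seed: int


def _related_forward_pairs(
    index: GenomeIndex, dataset: AnnotationDataset, max_span: int
) -> set[tuple[int, int]]:
    """All forward rank pairs (a < b) on one chromosome, rank offset
    b - a <= max_span - 1, sharing at least one term.

    Term-centric: only genuinely related pairs are touched, which is far
    cheaper than the naive all-pairs scan for sparse term sharing. Pairs
    sharing several terms are deduplicated by the set.
    """
    pairs: set[tuple[int, int]] = set()
    max_offset = max_span - 1
    spans = index.chromosome_spans
    carriers = dataset.carriers_by_term(index)
    # carriers are globally sorted ranks; split at chromosome boundaries
    boundaries = sorted(hi for (_, hi) in spans.values())
    import bisect

    for ranks in carriers.values():
        n = len(ranks)
        for i, a in enumerate(ranks):
            # last rank of a's chromosome
            chrom_hi = boundaries[bisect.bisect_left(boundaries, a)]
            for j in range(i + 1, n):
                b = ranks[j]
                if b - a > max_offset or b > chrom_hi:
                    break
                pairs.add((a, b))
    return pairs


def relatedness_profile(
    index: GenomeIndex, dataset: AnnotationDataset, max_span: int = 100
) -> WalkProfile:
    """Counts of term-sharing forward gene pairs at every span n in 2..max_span."""
    if max_span < 2:
        raise ValueError("max_span must be >= 2")
    pairs = _related_forward_pairs(index, dataset, max_span)
    counts = {n: 0 for n in range(2, max_span + 1)}
    for a, b in pairs:
        counts[b - a + 1] += 1
    nearest = nearest_related_histogram(index, dataset, max_span)
    return WalkProfile(
        dataset_name=dataset.name,
        max_span=max_span,
        counts_by_span=counts,
        nearest_histogram=nearest,
        n_genes_evaluated=index.N,
    )


def nearest_related_histogram(
    index: GenomeIndex, dataset: AnnotationDataset, max_span: int = 100
) -> dict[int, int]:
    """Per-gene distance (rank difference, both directions, same chromosome)
    to the closest term-sharing gene.

    The search is capped at a rank difference of max_span - 1 (the distance of
    a pair at span max_span); genes with no related gene within the cap -- in
    particular unannotated genes -- fall in the ``OVERFLOW`` bin. Every gene of
    the genome is evaluated.
    """
    cap = max_span - 1
    best = np.full(index.N + 1, np.iinfo(np.int64).max, dtype=np.int64)
    carriers = dataset.carriers_by_term(index)
    chrom_of = [g.chromosome for g in index.genes]
    for ranks in carriers.values():
        for i, r in enumerate(ranks):
            if i > 0:
                prev = ranks[i - 1]
                if chrom_of[prev - 1] == chrom_of[r - 1]:
                    d = r - prev
                    if d < best[r]:
                        best[r] = d
                    if d < best[prev]:
                        best[prev] = d
    hist: dict[int, int] = {}
    overflow = 0
    for rank in range(1, index.N + 1):
        d = int(best[rank])
        if d <= cap:
            hist[d] = hist.get(d, 0) + 1
        else:
            overflow += 1
    hist[OVERFLOW] = overflow
    return hist


def permute_gene_order(index: GenomeIndex, seed: int | np.random.Generator) -> GenomeIndex:
    """Randomly reassign genes to the N positional slots.

    Slot attributes (chromosome and coordinates) stay fixed, so chromosome
    sizes and the within-chromosome coordinate order are preserved; genes carry
    their identities (and hence annotations) into their new slots.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(index.N)
    genes = index.genes
    out = []
    for slot, src in enumerate(perm):
        slot_gene = genes[slot]
        moved = genes[src]
        out.append(
            Gene(
                gene_id=moved.gene_id,
                chromosome=slot_gene.chromosome,
                start=slot_gene.start,
                end=slot_gene.end,
                strand=moved.strand,
                rank=slot_gene.rank,
                chrom_rank=slot_gene.chrom_rank,
            )
        )
    return GenomeIndex(out, index.chromosome_order)


def permutation_baseline(
    index: GenomeIndex,
    dataset: AnnotationDataset,
    n_permutations: int = 10,
    max_span: int = 100,
    seed: int = 0,
) -> PermutationBaseline:
    """Average relatedness profile over seeded permuted genomes."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_permutations):
        permuted = permute_gene_order(index, rng)
        profiles.append(relatedness_profile(permuted, dataset, max_span))
    mean_counts = {
        n: float(np.mean([p.counts_by_span[n] for p in profiles]))
        for n in range(2, max_span + 1)
    }
    keys = sorted({k for p in profiles for k in p.nearest_histogram})
    mean_nearest = {
        k: float(np.mean([p.nearest_histogram.get(k, 0) for p in profiles]))
        for k in keys
    }
    return PermutationBaseline(
        profiles=profiles,
        mean_counts_by_span=mean_counts,
        mean_nearest_histogram=mean_nearest,
        n_permutations=n_permutations,
        seed=seed,
    )


def walk_profile_frame(
    profile: WalkProfile, baseline: PermutationBaseline | None = None
) -> pd.DataFrame:
    spans = sorted(profile.counts_by_span)
    df = pd.DataFrame(
        {
            "span": spans,
            "observed_count": [profile.counts_by_span[n] for n in spans],
        }
    )
    if baseline is not None:
        df["permuted_mean"] = [baseline.mean_counts_by_span.get(n, 0.0) for n in spans]
    return df


def nearest_histogram_frame(
    profile: WalkProfile, baseline: PermutationBaseline | None = None
) -> pd.DataFrame:
    keys = sorted(k for k in profile.nearest_histogram if k != OVERFLOW)
    rows = [(k, profile.nearest_histogram[k]) for k in keys]
    rows.append(("overflow", profile.nearest_histogram.get(OVERFLOW, 0)))
    df = pd.DataFrame(rows, columns=["distance", "count"])
    if baseline is not None:
        vals = [baseline.mean_nearest_histogram.get(k, 0.0) for k in keys]
        vals.append(baseline.mean_nearest_histogram.get(OVERFLOW, 0.0))
        df["permuted_mean"] = vals
    return df
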