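"""Cross-dataset merging of significant chains and genome summary metrics.

No single annotation source sees every cluster: a family may be unannotated in
one dataset, split across terms in another, or statistically out of reach for
a prolific domain. A gene is therefore considered clustered when *any* dataset
reports it so: significant chains whose member-gene sets intersect are merged
(transitively) into paraclusters. Merging is by member intersection, not by
genomic interval overlap, so nested clusters of unrelated families stay
separate.

The module also computes the standard genome-wide summaries: per-dataset and
merged cluster/gene counts, cluster-size distributions (size = l, the paralog
count, not the span), dataset overlap matrices, adjacency fractions, family
clustering fractions, cross-species cluster sharing through in-paralog maps,
and expectation-threshold sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .chaining import Chain, ChainingConfig, detect_chains_all
from .genome_model import AnnotationDataset, GenomeIndex
from .significance import filter_significant, score_chains

__all__ = [
    "Paracluster",
    "GenomeSummary",
    "OrthologMap",
    "merge_across_datasets",
    "dataset_overlap_matrix",
    "genome_metrics",
    "family_clustering_fractions",
    "cluster_sharing",
    "species_specific_fraction",
    "threshold_sweep",
    "paraclusters_to_frame",
    "paraclusters_from_frame",
]

RELATIONS = ("inparalog", "ortholog", "outparalog")


@dataclass(frozen=True)
class Paracluster:
    """A merged cluster: union of members of intersecting significant chains."""

    cluster_id: str
    chromosome: str
    start_rank: int
    end_rank: int
    member_gene_ids: frozenset[str]
    member_ranks: tuple[int, ...]
    interstitial_gene_ids: tuple[str, ...]
    contributing: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def l(self) -> int:
        return len(self.member_ranks)

    @property
    def k(self) -> int:
        return self.end_rank - self.start_rank + 1


def merge_across_datasets(
    chains_by_dataset: Mapping[str, Sequence[Chain]], index: GenomeIndex
) -> list[Paracluster]:
    """Merge significant chains into paraclusters.

    Chains are merged (transitively) whenever their member-gene sets intersect;
    members are the union, interstitials are recomputed over the merged span --
    a gene interstitial for one dataset but member for another ends up a
    member.
    """
    graph = nx.Graph()
    chain_lookup: dict[str, tuple[str, Chain]] = {}
    for name, chains in chains_by_dataset.items():
        for chain in chains:
            node = ("chain", name, chain.chain_id)
            graph.add_node(node)
            chain_lookup[node] = (name, chain)
            for r in chain.member_ranks:
                graph.add_edge(node, ("gene", r))

    clusters: list[Paracluster] = []
    for component in nx.connected_components(graph):
        chain_nodes = [n for n in component if n[0] == "chain"]
        if not chain_nodes:
            continue
        member_ranks = sorted({n[1] for n in component if n[0] == "gene"})
        contributing: dict[str, list[str]] = {}
        for node in chain_nodes:
            name, chain = chain_lookup[node]
            contributing.setdefault(name, []).append(chain.chain_id)
        lo, hi = member_ranks[0], member_ranks[-1]
        members = frozenset(index.gene_at(r).gene_id for r in member_ranks)
        interstitials = tuple(
            index.gene_at(r).gene_id
            for r in range(lo, hi + 1)
            if r not in set(member_ranks)
        )
        clusters.append(
            Paracluster(
                cluster_id="",  # assigned after sorting
                chromosome=index.chromosome_of_rank(lo),
                start_rank=lo,
                end_rank=hi,
                member_gene_ids=members,
                member_ranks=tuple(member_ranks),
                interstitial_gene_ids=interstitials,
                contributing={k: tuple(sorted(v)) for k, v in contributing.items()},
            )
        )
    clusters.sort(key=lambda c: c.start_rank)
    width = max(4, len(str(len(clusters))))
    return [
        Paracluster(
            cluster_id=f"PC{i + 1:0{width}d}",
            chromosome=c.chromosome,
            start_rank=c.start_rank,
            end_rank=c.end_rank,
            member_gene_ids=c.member_gene_ids,
            member_ranks=c.member_ranks,
            interstitial_gene_ids=c.interstitial_gene_ids,
            contributing=c.contributing,
        )
        for i, c in enumerate(clusters)
    ]


def _dataset_gene_sets(
    chains_by_dataset: Mapping[str, Sequence[Chain]], index: GenomeIndex
) -> dict[str, set[str]]:
    return {
        name: {g for c in chains for g in c.member_gene_ids(index)}
        for name, chains in chains_by_dataset.items()
    }


def dataset_overlap_matrix(
    chains_by_dataset: Mapping[str, Sequence[Chain]], index: GenomeIndex
) -> pd.DataFrame:
    """Symmetric matrix of clustered genes shared between dataset pairs.

    Cell (i, j) counts genes in significant chains of dataset i that are also
    in significant chains of dataset j; the diagonal holds dataset totals.
    """
    genes = _dataset_gene_sets(chains_by_dataset, index)
    names = sorted(genes)
    data = [[len(genes[a] & genes[b]) for b in names] for a in names]
    return pd.DataFrame(data, index=names, columns=names)


@dataclass
class GenomeSummary:
    """Per-dataset and merged genome clustering metrics."""

    N: int
    per_dataset: pd.DataFrame  # dataset, paracluster_count, genes, percent
    merged_count: int
    merged_genes: int
    merged_percent: float
    size_distribution: pd.DataFrame
    percent_adjacent: float
    percent_within_10: float

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "per_dataset": self.per_dataset.to_dict("records"),
            "merged": {
                "paracluster_count": self.merged_count,
                "genes_in_paraclusters": self.merged_genes,
                "percent_genes_in_paraclusters": self.merged_percent,
            },
            "percent_adjacent": self.percent_adjacent,
            "percent_within_10": self.percent_within_10,
        }


def _adjacency_percents(
    paraclusters: Sequence[Paracluster], N: int, near: int = 10
) -> tuple[float, float]:
    adjacent = 0
    within = 0
    for pc in paraclusters:
        ranks = pc.member_ranks
        for i, r in enumerate(ranks):
            d_prev = r - ranks[i - 1] if i > 0 else None
            d_next = ranks[i + 1] - r if i < len(ranks) - 1 else None
            dmin = min(d for d in (d_prev, d_next) if d is not None)
            if dmin == 1:
                adjacent += 1
            if dmin <= near:
                within += 1
    return 100.0 * adjacent / N, 100.0 * within / N


def genome_metrics(
    paraclusters: Sequence[Paracluster],
    chains_by_dataset: Mapping[str, Sequence[Chain]],
    index: GenomeIndex,
) -> GenomeSummary:
    """Counts, percents, size distributions and adjacency fractions.

    Cluster size is l, the number of paralog members, not the span k. The
    cumulative percent column of the size distribution reaches the merged
    percent of clustered genes at the largest size.
    """
    N = index.N
    genes = _dataset_gene_sets(chains_by_dataset, index)
    per_rows = [
        {
            "dataset": name,
            "paracluster_count": len(chains_by_dataset[name]),
            "genes_in_paraclusters": len(genes[name]),
            "percent_genes_in_paraclusters": 100.0 * len(genes[name]) / N,
        }
        for name in sorted(chains_by_dataset)
    ]
    merged_genes = len({g for pc in paraclusters for g in pc.member_gene_ids})
    merged_percent = 100.0 * merged_genes / N

    by_size: dict[int, list[Paracluster]] = {}
    for pc in paraclusters:
        by_size.setdefault(pc.l, []).append(pc)
    rows = []
    cumulative = 0
    for size in sorted(by_size):
        pcs = by_size[size]
        genes_excl = sum(pc.l for pc in pcs)
        genes_incl = sum(pc.k for pc in pcs)
        cumulative += genes_excl
        rows.append(
            {
                "size_l": size,
                "cluster_count": len(pcs),
                "genes_excl_interstitial": genes_excl,
                "genes_incl_interstitial": genes_incl,
                "cumulative_percent": 100.0 * cumulative / N,
            }
        )
    size_distribution = pd.DataFrame(
        rows,
        columns=[
            "size_l",
            "cluster_count",
            "genes_excl_interstitial",
            "genes_incl_interstitial",
            "cumulative_percent",
        ],
    )
    pct_adjacent, pct_within = (
        _adjacency_percents(paraclusters, N) if paraclusters else (0.0, 0.0)
    )
    return GenomeSummary(
        N=N,
        per_dataset=pd.DataFrame(per_rows),
        merged_count=len(paraclusters),
        merged_genes=merged_genes,
        merged_percent=merged_percent,
        size_distribution=size_distribution,
        percent_adjacent=pct_adjacent,
        percent_within_10=pct_within,
    )


def family_clustering_fractions(
    dataset: AnnotationDataset,
    paraclusters: Sequence[Paracluster],
    min_family_size_for_histogram: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family clustering fractions and the grouped histogram for large families.

    Returns (per-family table, decile histogram restricted to families with at
    least ``min_family_size_for_histogram`` members).
    """
    clustered = {g for pc in paraclusters for g in pc.member_gene_ids}
    carriers: dict[str, set[str]] = {}
    for gene, terms in dataset.terms.items():
        for t in terms:
            carriers.setdefault(t, set()).add(gene)
    rows = []
    for term in sorted(carriers):
        members = carriers[term]
        in_clusters = len(members & clustered)
        rows.append(
            {
                "family": term,
                "size": len(members),
                "members_in_clusters": in_clusters,
                "fraction": in_clusters / len(members),
            }
        )
    table = pd.DataFrame(rows, columns=["family", "size", "members_in_clusters", "fraction"])
    large = table[table["size"] >= min_family_size_for_histogram]
    bins = [i / 10 for i in range(11)]
    labels = [f"{10 * i}-{10 * (i + 1)}%" for i in range(10)]
    if len(large):
        cut = pd.cut(large["fraction"], bins=bins, labels=labels, include_lowest=True)
        counts = cut.value_counts().reindex(labels, fill_value=0)
    else:
        counts = pd.Series([0] * 10, index=labels)
    histogram = pd.DataFrame(
        {"percent_clustered": labels, "family_count": counts.to_numpy()}
    )
    return table, histogram


@dataclass
class OrthologMap:
    """Cross-species gene relations (in-paralog / ortholog / out-paralog)."""

    pairs: set[tuple[str, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {rel for (_, _, rel) in self.pairs if rel not in RELATIONS}
        if bad:
            raise ValueError(f"unknown relation(s): {sorted(bad)}; allowed: {RELATIONS}")

    def partners(self, relations: Iterable[str] = ("inparalog",)) -> dict[str, set[str]]:
        rels = set(relations)
        out: dict[str, set[str]] = {}
        for a, b, rel in self.pairs:
            if rel in rels:
                out.setdefault(a, set()).add(b)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "relation"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologMap":
        return cls(
            pairs={
                (str(r.gene_a), str(r.gene_b), str(r.relation))
                for r in df.itertuples(index=False)
            }
        )


def _cluster_member_sets(clusters: Sequence[Paracluster | frozenset]) -> list[frozenset]:
    return [
        c.member_gene_ids if isinstance(c, Paracluster) else frozenset(c)
        for c in clusters
    ]


def cluster_sharing(
    clusters_a: Sequence[Paracluster | frozenset],
    clusters_b: Sequence[Paracluster | frozenset],
    ortholog_map: OrthologMap,
    relations: Iterable[str] = ("inparalog",),
) -> tuple[float, float]:
    """Fraction of A's clusters shared with B, and the complement.

    A cluster of species A is shared with species B when at least one of its
    members has a relation partner (in-paralog by default) inside any cluster
    of B. With a single partner species, specific = 1 - shared.
    """
    sets_a = _cluster_member_sets(clusters_a)
    if not sets_a:
        return 0.0, 0.0
    b_genes = set().union(*_cluster_member_sets(clusters_b)) if clusters_b else set()
    partners = ortholog_map.partners(relations)
    shared = sum(
        1
        for members in sets_a
        if any(partners.get(g, set()) & b_genes for g in members)
    )
    frac = shared / len(sets_a)
    return frac, 1.0 - frac


def species_specific_fraction(
    clusters_a: Sequence[Paracluster | frozenset],
    partner_clusters: Mapping[str, Sequence[Paracluster | frozenset]],
    ortholog_maps: Mapping[str, OrthologMap],
    relations: Iterable[str] = ("inparalog",),
) -> float:
    """Fraction of A's clusters with no in-paralog clustered in *any* partner species."""
    sets_a = _cluster_member_sets(clusters_a)
    if not sets_a:
        return 0.0
    specific = 0
    partner_data = [
        (
            ortholog_maps[sp].partners(relations),
            set().union(*_cluster_member_sets(cls)) if len(cls) else set(),
        )
        for sp, cls in partner_clusters.items()
    ]
    for members in sets_a:
        shared_anywhere = any(
            any(partners.get(g, set()) & genes for g in members)
            for partners, genes in partner_data
        )
        if not shared_anywhere:
            specific += 1
    return specific / len(sets_a)


def threshold_sweep(
    index: GenomeIndex,
    datasets: Mapping[str, AnnotationDataset],
    thresholds: Sequence[float],
    config: ChainingConfig | None = None,
    scored_chains: Mapping[str, Sequence[Chain]] | None = None,
) -> pd.DataFrame:
    """Clustered-gene totals per dataset and merged, at each expectation threshold.

    Chains are detected and scored once (the chain set does not depend on the
    threshold); each threshold refilters and remerges. Thresholds must be
    sorted ascending; totals are then non-decreasing by the nesting of the
    significant sets.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    if scored_chains is None:
        raw = detect_chains_all(index, datasets, config)
        scored_chains = {
            name: score_chains(chains, datasets[name], index.N)
            for name, chains in raw.items()
        }
    rows = []
    for thr in thresholds:
        significant = {
            name: filter_significant(chains, thr)
            for name, chains in scored_chains.items()
        }
        genes = _dataset_gene_sets(significant, index)
        for name in sorted(significant):
            rows.append(
                {
                    "threshold": thr,
                    "dataset": name,
                    "paracluster_count": len(significant[name]),
                    "genes_in_paraclusters": len(genes[name]),
                }
            )
        merged = merge_across_datasets(significant, index)
        merged_genes = len({g for pc in merged for g in pc.member_gene_ids})
        rows.append(
            {
                "threshold": thr,
                "dataset": "merged",
                "paracluster_count": len(merged),
                "genes_in_paraclusters": merged_genes,
            }
        )
    return pd.DataFrame(rows)


def paraclusters_to_frame(paraclusters: Sequence[Paracluster]) -> pd.DataFrame:
    rows = []
    for pc in paraclusters:
        rows.append(
            {
                "cluster_id": pc.cluster_id,
                "chromosome": pc.chromosome,
                "start_rank": pc.start_rank,
                "end_rank": pc.end_rank,
                "l": pc.l,
                "k": pc.k,
                "members": ",".join(sorted(pc.member_gene_ids)),
                "member_ranks": ",".join(map(str, pc.member_ranks)),
                "interstitials": ",".join(pc.interstitial_gene_ids),
                "contributing": ";".join(
                    f"{ds}={'|'.join(ids)}" for ds, ids in sorted(pc.contributing.items())
                ),
            }
        )
    columns = [
        "cluster_id", "chromosome", "start_rank", "end_rank", "l", "k",
        "members", "member_ranks", "interstitials", "contributing",
    ]
    return pd.DataFrame(rows, columns=columns)


def paraclusters_from_frame(df: pd.DataFrame) -> list[Paracluster]:
    out = []
    for r in df.itertuples(index=False):
        contributing: dict[str, tuple[str, ...]] = {}
        if isinstance(r.contributing, str) and r.contributing:
            for part in r.contributing.split(";"):
                ds, ids = part.split("=", 1)
                contributing[ds] = tuple(ids.split("|"))
        interstitials: tuple[str, ...] = ()
        if isinstance(r.interstitials, str) and r.interstitials:
            interstitials = tuple(r.interstitials.split(","))
        out.append(
            Paracluster(
                cluster_id=str(r.cluster_id),
                chromosome=str(r.chromosome),
                start_rank=int(r.start_rank),
                end_rank=int(r.end_rank),
                member_gene_ids=frozenset(str(r.members).split(",")),
                member_ranks=tuple(int(x) for x in str(r.member_ranks).split(",")),
                interstitial_gene_ids=interstitials,
                contributing=contributing,
            )
        )
    return out
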