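"""Greedy chaining of annotation-sharing genes along chromosomes.

A chain is a candidate cluster: l paralog members spread over a span of k
genes (interstitial genes included in k). Chains are built per dataset by a
forward scan of each chromosome:

* a chain opens at the first gene, in rank order, that carries at least one
  term and is not already in a chain;
* from the last member the scan looks ahead for the nearest gene sharing at
  least one term of the chain's current *common subset* (the least common set
  of terms shared by all members so far); on admission the common subset is
  intersected with the new member's terms, so it can shrink but never empties;
* a run of more than ``max_gap`` consecutive non-member genes closes the chain
  at its last member;
* every gene joins at most one chain per dataset (first come, first served --
  the scan is order dependent by construction);
* only chains with l >= 2 are reported; k is measured first member to last
  member, so chains never begin or end on an interstitial gene, and never
  cross a chromosome boundary.

Gap lengths are *effective*: a maximal run of consecutive interstitial genes
that are all members of one other chain (a nested tandem array of a different
family) counts as a single gap space. Because effective gaps depend on the
chains themselves, chaining is re-run with the previous round's chain
membership until chain boundaries reach a fixed point (bounded iterations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genome_model import AnnotationDataset, GenomeIndex

__all__ = [
    "Chain",
    "ChainingConfig",
    "detect_chains",
    "detect_chains_all",
    "collapse_nested_gaps",
    "build_chain_membership",
    "chains_to_frame",
    "chains_from_frame",
]


@dataclass(frozen=True)
class ChainingConfig:
    """Chaining parameters.

    ``max_gap`` is the longest tolerated effective run of interstitial genes
    (default 15). ``max_gaps`` caps the number of gaps per chain (None =
    unlimited; the cap exists for runtime control only, it is not needed for
    correctness). ``collapse_nested`` enables the nested-array gap collapsing
    with a fixed-point re-run bounded by ``max_collapse_iterations``.
    """

    max_gap: int = 15
    max_gaps: int | None = None
    collapse_nested: bool = True
    max_collapse_iterations: int = 5

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class Chain:
    """A candidate cluster of l members over a span of k genes.

    ``gaps`` holds (gap_start_rank, effective_length) per internal gap; raw
    gap lengths are recoverable from consecutive member ranks. ``p_value`` /
    ``e_value`` are filled by the significance module.
    """

    dataset_name: str
    chromosome: str
    member_ranks: tuple[int, ...]
    common_terms: frozenset[str]
    gaps: tuple[tuple[int, int], ...] = ()
    p_value: float | None = None
    e_value: float | None = None
    m_used: int | None = None
    term_used: str | None = None

    @property
    def start_rank(self) -> int:
        return self.member_ranks[0]

    @property
    def end_rank(self) -> int:
        return self.member_ranks[-1]

    @property
    def l(self) -> int:
        return len(self.member_ranks)

    @property
    def k(self) -> int:
        return self.end_rank - self.start_rank + 1

    @property
    def chain_id(self) -> str:
        return f"{self.dataset_name}:{self.chromosome}:{self.start_rank}"

    def member_gene_ids(self, index: GenomeIndex) -> tuple[str, ...]:
        return tuple(index.gene_at(r).gene_id for r in self.member_ranks)

    def interstitial_ranks(self) -> tuple[int, ...]:
        members = set(self.member_ranks)
        return tuple(
            r for r in range(self.start_rank, self.end_rank + 1) if r not in members
        )


def detect_chains(
    index: GenomeIndex,
    dataset: AnnotationDataset,
    config: ChainingConfig | None = None,
    membership: Mapping[int, frozenset[str]] | None = None,
) -> list[Chain]:
    """Single forward chaining pass over all chromosomes for one dataset.

    ``membership`` maps rank -> chain ids from a previous pass (all datasets);
    when given, runs of interstitial genes sharing one such chain are collapsed
    to an effective gap length of 1. Without it gap lengths are raw.
    """
    config = config or ChainingConfig()
    rank_terms = dataset.rank_term_sets(index)
    chains: list[Chain] = []
    for chrom in index.chromosome_order:
        lo, hi = index.chromosome_spans[chrom]
        chains.extend(
            _scan_chromosome(rank_terms, chrom, lo, hi, dataset.name, config, membership)
        )
    return chains


def _scan_chromosome(
    rank_terms: Sequence[frozenset[str]],
    chrom: str,
    first_rank: int,
    last_rank: int,
    dataset_name: str,
    config: ChainingConfig,
    membership: Mapping[int, frozenset[str]] | None,
) -> list[Chain]:
    max_gap = config.max_gap
    chains: list[Chain] = []
    assigned: set[int] = set()
    for seed in range(first_rank, last_rank + 1):
        if seed in assigned:
            continue
        seed_terms = rank_terms[seed - 1]
        if not seed_terms:
            continue
        common = set(seed_terms)
        members = [seed]
        gaps: list[tuple[int, int]] = []
        last = seed
        while True:
            found = None
            eff = 0
            run_tokens: frozenset[str] | None = None
            j = last + 1
            while j <= last_rank:
                terms = rank_terms[j - 1]
                if j not in assigned and terms and not common.isdisjoint(terms):
                    found = j
                    break
                # interstitial: accumulate effective gap length, collapsing
                # runs of genes that all belong to one other chain
                tokens = membership.get(j) if membership is not None else None
                if run_tokens and tokens:
                    joint = run_tokens & tokens
                    if joint:
                        run_tokens = joint
                        j += 1
                        continue
                eff += 1
                run_tokens = tokens if tokens else None
                if eff > max_gap:
                    break
                j += 1
            if found is None:
                break
            if found > last + 1:
                if config.max_gaps is not None and len(gaps) >= config.max_gaps:
                    break
                gaps.append((last + 1, eff))
            common &= rank_terms[found - 1]
            assert common, "admission rule guarantees a non-empty common subset"
            members.append(found)
            last = found
        if len(members) >= 2:
            assigned.update(members)
            chains.append(
                Chain(
                    dataset_name=dataset_name,
                    chromosome=chrom,
                    member_ranks=tuple(members),
                    common_terms=frozenset(common),
                    gaps=tuple(gaps),
                )
            )
    return chains


def build_chain_membership(
    chains_by_dataset: Mapping[str, Sequence[Chain]],
) -> dict[int, frozenset[str]]:
    """Map member rank -> ids of every chain (any dataset) containing it."""
    acc: dict[int, set[str]] = {}
    for chains in chains_by_dataset.values():
        for chain in chains:
            for r in chain.member_ranks:
                acc.setdefault(r, set()).add(chain.chain_id)
    return {r: frozenset(s) for r, s in acc.items()}


def _boundary_signature(chains_by_dataset: Mapping[str, Sequence[Chain]]):
    return {
        name: tuple(sorted((c.chromosome, c.member_ranks) for c in chains))
        for name, chains in chains_by_dataset.items()
    }


def collapse_nested_gaps(
    chains_by_dataset: Mapping[str, Sequence[Chain]],
    index: GenomeIndex,
    datasets: Mapping[str, AnnotationDataset],
    config: ChainingConfig | None = None,
) -> dict[str, list[Chain]]:
    """Re-run chaining with nested-array gap collapsing to a fixed point.

    Interstitial runs nested inside a gap are collapsed to one gap space when
    all their genes belong to a single chain of the previous round, whatever
    dataset that chain came from. Iterates until chain boundaries are stable or
    the iteration cap is reached (then warns and keeps the last result).
    """
    config = config or ChainingConfig()
    current = {name: list(chains) for name, chains in chains_by_dataset.items()}
    signature = _boundary_signature(current)
    for _ in range(config.max_collapse_iterations):
        membership = build_chain_membership(current)
        nxt = {
            name: detect_chains(index, datasets[name], config, membership)
            for name in current
        }
        nxt_signature = _boundary_signature(nxt)
        if nxt_signature == signature:
            return nxt
        current, signature = nxt, nxt_signature
    warnings.warn(
        "nested-gap collapsing did not reach a fixed point within "
        f"{config.max_collapse_iterations} iterations; keeping last stable result",
        stacklevel=2,
    )
    return current


def detect_chains_all(
    index: GenomeIndex,
    datasets: Mapping[str, AnnotationDataset],
    config: ChainingConfig | None = None,
) -> dict[str, list[Chain]]:
    """Chaining for every dataset, with nested-gap collapsing if enabled."""
    config = config or ChainingConfig()
    chains = {name: detect_chains(index, ds, config) for name, ds in datasets.items()}
    if config.collapse_nested:
        chains = collapse_nested_gaps(chains, index, datasets, config)
    return chains


# ---------------------------------------------------------------------------
# chain table I/O (TSV)
# ---------------------------------------------------------------------------


def chains_to_frame(
    chains: Sequence[Chain], index: GenomeIndex | None = None
) -> pd.DataFrame:
    rows = []
    for c in sorted(chains, key=lambda c: (c.dataset_name, c.start_rank)):
        rows.append(
            {
                "dataset": c.dataset_name,
                "chromosome": c.chromosome,
                "start_rank": c.start_rank,
                "end_rank": c.end_rank,
                "l": c.l,
                "k": c.k,
                "member_ranks": ",".join(map(str, c.member_ranks)),
                "members": ",".join(c.member_gene_ids(index)) if index else "",
                "common_terms": ",".join(sorted(c.common_terms)),
                "gaps": ";".join(f"{s}:{e}" for s, e in c.gaps),
                "m_used": c.m_used if c.m_used is not None else "",
                "term_used": c.term_used or "",
                "p_value": c.p_value if c.p_value is not None else "",
                "e_value": c.e_value if c.e_value is not None else "",
            }
        )
    columns = [
        "dataset", "chromosome", "start_rank", "end_rank", "l", "k",
        "member_ranks", "members", "common_terms", "gaps",
        "m_used", "term_used", "p_value", "e_value",
    ]
    return pd.DataFrame(rows, columns=columns)


def chains_from_frame(df: pd.DataFrame) -> list[Chain]:
    chains = []
    for r in df.itertuples(index=False):
        gaps: tuple[tuple[int, int], ...] = ()
        if isinstance(r.gaps, str) and r.gaps:
            gaps = tuple(
                (int(s), int(e)) for s, e in (g.split(":") for g in r.gaps.split(";"))
            )
        def _opt(value, cast):
            if value is None or (isinstance(value, str) and value == ""):
                return None
            if isinstance(value, float) and pd.isna(value):
                return None
            return cast(value)

        chains.append(
            Chain(
                dataset_name=str(r.dataset),
                chromosome=str(r.chromosome),
                member_ranks=tuple(int(x) for x in str(r.member_ranks).split(",")),
                common_terms=frozenset(str(r.common_terms).split(",")),
                gaps=gaps,
                m_used=_opt(r.m_used, lambda v: int(float(v))),
                term_used=_opt(r.term_used, str),
                p_value=_opt(r.p_value, float),
                e_value=_opt(r.e_value, float),
            )
        )
    return chains
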