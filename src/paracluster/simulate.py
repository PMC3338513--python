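"""Seeded synthetic genomes with a ground-truth ledger.

The generator emulates the empirical structure of an annotated vertebrate
genome at the level this package cares about: ~20k protein-coding genes over a
skewed set of chromosomes (micro-chromosomes included), a singleton-dominated
family-size mixture (about two thirds of genes are the only member of their
family; multi-member families average ~3 genes with a small heavy tail of very
large families), planted clusters laid down contiguously or with prescribed
gaps (optionally nested inside another cluster's gap), prolific domains
carried by hundreds of dispersed genes, and several annotation datasets that
each miss a fraction of the true assignments (per-dataset dropout) -- the
reason merging across datasets recovers clusters any single one misses.

Everything is deterministic under the config seed, and a :class:`TruthLedger`
records exactly what was planted so every pipeline stage can be checked
without downloads. No sequence-level realism is attempted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    AnnotationDataset,
    GenomeIndex,
    annotation_datasets_from_frame,
    build_gene_index,
    pairs_to_families,
    paralog_pair_sets_from_frame,
    write_annotation_table,
    write_gene_table,
    write_paralog_pairs,
)
from .merging import OrthologMap

__all__ = [
    "DEFAULT_DATASET_NAMES",
    "PlantedClusterSpec",
    "SimConfig",
    "TruthLedger",
    "SimulatedGenome",
    "generate_genome",
    "random_planted_specs",
    "generate_ortholog_map",
    "default_chromosome_sizes",
]

DEFAULT_DATASET_NAMES = (
    "ensembl_paralogs",
    "ensembl_family",
    "panther",
    "scop",
    "interpro",
)
#: datasets that additionally carry the prolific (high-frequency) domain terms
HF_DATASET_NAMES = ("scop", "interpro")

# relative gene counts per chromosome, loosely following a mammalian genome,
# plus two micro-chromosomes to exercise boundary handling
_CHROM_WEIGHTS = (
    2000, 1250, 1050, 760, 880, 1030, 910, 680, 780, 730,
    1300, 1030, 330, 620, 600, 850, 1200, 280, 1400, 540,
    230, 440, 850, 60, 20, 8,
)


def default_chromosome_sizes(n_genes: int) -> tuple[int, ...]:
    """Skewed chromosome gene counts summing exactly to ``n_genes``."""
    weights = np.asarray(_CHROM_WEIGHTS, dtype=float)
    raw = weights / weights.sum() * n_genes
    sizes = np.floor(raw).astype(int)
    sizes = np.maximum(sizes, 1)
    # largest-remainder correction to hit the exact total
    deficit = n_genes - int(sizes.sum())
    order = np.argsort(-(raw - np.floor(raw)))
    i = 0
    while deficit != 0 and i < 10 * len(sizes):
        j = order[i % len(sizes)]
        step = 1 if deficit > 0 else -1
        if sizes[j] + step >= 1:
            sizes[j] += step
            deficit -= step
        i += 1
    return tuple(int(s) for s in sizes)


@dataclass(frozen=True)
class PlantedClusterSpec:
    """One planted cluster: ``n_members`` genes of a private family.

    ``gaps`` are runs of interstitial background genes inserted between random
    member boundaries; ``nested_in`` (an index into the planted list) places
    the whole cluster inside a sufficiently long gap of an earlier cluster.
    """

    n_members: int
    gaps: tuple[int, ...] = ()
    nested_in: int | None = None

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("a planted cluster needs at least 2 members")
        if len(self.gaps) > self.n_members - 1:
            raise ValueError("more gaps than member boundaries")
        if any(g < 1 for g in self.gaps):
            raise ValueError("gap lengths must be >= 1")

    @property
    def span(self) -> int:
        return self.n_members + sum(self.gaps)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic genome.

    Defaults are calibrated to the annotated human genome: 20k genes, 68.3%
    singleton families, multi-member families averaging ~3 genes with ~3% of
    them large (heavy tail), five annotation datasets with 10% per-dataset
    dropout, and two prolific domains on dispersed genes.
    """

    n_genes: int = 20_000
    chromosome_sizes: tuple[int, ...] | None = None
    singleton_fraction: float = 0.683
    family_geom_p: float = 0.5
    large_family_fraction: float = 0.03
    large_family_offset: int = 10
    large_family_geom_p: float = 0.12
    max_family_size: int = 100
    planted_clusters: tuple[PlantedClusterSpec, ...] = ()
    dataset_names: tuple[str, ...] = DEFAULT_DATASET_NAMES
    dropout: float = 0.1
    high_frequency_domains: tuple[tuple[str, int], ...] = (
        ("HF_IGDOM", 400),
        ("HF_ZNF", 250),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ValueError("singleton_fraction must be in [0, 1]")
        planted = sum(s.span for s in self.planted_clusters)
        if planted > self.n_genes:
            raise ValueError("planted clusters exceed the genome size")

    def resolved_chromosome_sizes(self) -> tuple[int, ...]:
        if self.chromosome_sizes is not None:
            if sum(self.chromosome_sizes) != self.n_genes:
                raise ValueError("chromosome_sizes must sum to n_genes")
            return tuple(self.chromosome_sizes)
        return default_chromosome_sizes(self.n_genes)


@dataclass
class TruthLedger:
    """Exact record of what the generator emitted."""

    seed: int
    n_genes: int
    chromosome_sizes: tuple[int, ...]
    dataset_names: tuple[str, ...]
    dropout: float
    families: dict[str, list[str]]  # family term -> true member gene ids
    planted: list[dict]  # family, chromosome, ranks, gene ids, span
    hf_carriers: dict[str, list[str]]  # prolific domain -> carrier gene ids
    dropped: dict[str, list[str]]  # dataset -> gene ids unannotated there
    conserved_clusters: list[int] = field(default_factory=list)

    def planted_member_ids(self) -> set[str]:
        return {g for rec in self.planted for g in rec["member_gene_ids"]}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        payload = json.loads(Path(path).read_text())
        payload["chromosome_sizes"] = tuple(payload["chromosome_sizes"])
        payload["dataset_names"] = tuple(payload["dataset_names"])
        return cls(**payload)


@dataclass
class SimulatedGenome:
    """Generator output: tables in exactly the formats the readers consume."""

    genes: pd.DataFrame
    annotations: pd.DataFrame
    pairs: pd.DataFrame
    ledger: TruthLedger

    def index(self) -> GenomeIndex:
        return build_gene_index(self.genes)

    def datasets(self, index: GenomeIndex | None = None) -> dict[str, AnnotationDataset]:
        """Term-based datasets plus the pair-derived paralogy dataset."""
        index = index or self.index()
        out = annotation_datasets_from_frame(self.annotations, index)
        for name, pairset in paralog_pair_sets_from_frame(self.pairs).items():
            out[name] = pairs_to_families(pairset, index)
        # keep the configured roster order
        return {name: out[name] for name in self.ledger.dataset_names if name in out}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": write_gene_table(self.genes, outdir / "genes.tsv"),
            "annotations": write_annotation_table(
                self.annotations, outdir / "annotations.tsv"
            ),
            "pairs": write_paralog_pairs(self.pairs, outdir / "paralog_pairs.tsv"),
            "ledger": self.ledger.to_json(outdir / "ledger.json"),
        }
        return paths


def random_planted_specs(
    n: int,
    rng: np.random.Generator,
    members: tuple[int, int] = (3, 20),
    max_n_gaps: int = 3,
    gap_length: tuple[int, int] = (1, 5),
) -> tuple[PlantedClusterSpec, ...]:
    """Draw ``n`` planted-cluster specs (member counts, gapped layouts)."""
    specs = []
    for _ in range(n):
        l = int(rng.integers(members[0], members[1] + 1))
        n_gaps = int(rng.integers(0, min(max_n_gaps, l - 1) + 1))
        gaps = tuple(
            int(rng.integers(gap_length[0], gap_length[1] + 1)) for _ in range(n_gaps)
        )
        specs.append(PlantedClusterSpec(n_members=l, gaps=gaps))
    return tuple(specs)


def _sample_family_sizes(rng: np.random.Generator, config: SimConfig, budget: int) -> list[int]:
    """Multi-member family sizes filling ``budget`` genes exactly."""
    sizes: list[int] = []
    remaining = budget
    while remaining >= 2:
        if rng.random() < config.large_family_fraction:
            size = config.large_family_offset + int(rng.geometric(config.large_family_geom_p))
        else:
            size = 1 + int(rng.geometric(config.family_geom_p))
        size = max(2, min(size, config.max_family_size, remaining))
        if remaining - size == 1:  # avoid stranding a single gene
            size += 1 if size < min(config.max_family_size, remaining) else -1
        sizes.append(size)
        remaining -= size
    return sizes


def _place_planted(
    rng: np.random.Generator,
    config: SimConfig,
    chrom_bounds: list[tuple[int, int]],
) -> tuple[np.ndarray, list[dict]]:
    """Lay planted clusters into the slot array.

    Returns (slot state, placement records). Slot state: -1 free, -2 reserved
    interstitial inside a planted window, >= 0 planted member of that cluster.
    """
    n = config.n_genes
    state = np.full(n, -1, dtype=np.int64)
    records: list[dict] = []
    order = sorted(
        range(len(config.planted_clusters)),
        key=lambda i: (config.planted_clusters[i].nested_in is not None, i),
    )
    for ci in order:
        spec = config.planted_clusters[ci]
        # member offsets within the window: gaps inserted at random distinct
        # internal boundaries
        boundaries = rng.choice(
            np.arange(1, spec.n_members), size=len(spec.gaps), replace=False
        ) if spec.gaps else np.array([], dtype=int)
        gap_at = dict(zip(sorted(int(b) for b in boundaries), spec.gaps))
        offsets = []
        pos = 0
        for mi in range(spec.n_members):
            if mi in gap_at:
                pos += gap_at[mi]
            offsets.append(pos)
            pos += 1
        span = spec.span

        placed = False
        for _ in range(2000):
            if spec.nested_in is not None:
                host = next((r for r in records if r["_index"] == spec.nested_in), None)
                if host is None:
                    raise ValueError(
                        f"planted cluster {ci} nests in {spec.nested_in}, "
                        "which is not placed"
                    )
                host_gaps = [
                    (s, ln) for (s, ln) in host["gap_slots"] if ln >= span
                ]
                if not host_gaps:
                    raise ValueError(
                        f"planted cluster {ci} does not fit any gap of its host"
                    )
                gs, glen = host_gaps[int(rng.integers(len(host_gaps)))]
                start = gs + int(rng.integers(glen - span + 1))
                window = state[start : start + span]
                ok = bool(np.all(window == -2))
            else:
                # chromosomes drawn in proportion to their gene counts
                weights = np.array([hi - lo + 1 for lo, hi in chrom_bounds], dtype=float)
                chrom = int(rng.choice(len(chrom_bounds), p=weights / weights.sum()))
                lo, hi = chrom_bounds[chrom]
                if hi - lo + 1 < span:
                    continue
                start = lo + int(rng.integers(hi - lo + 2 - span))
                window = state[start : start + span]
                ok = bool(np.all(window == -1))
            if not ok:
                continue
            member_slots = [start + o for o in offsets]
            state[start : start + span] = -2
            state[member_slots] = ci
            gap_slots = []
            for a, b in zip(member_slots, member_slots[1:]):
                if b - a > 1:
                    gap_slots.append((a + 1, b - a - 1))
            records.append(
                {
                    "_index": ci,
                    "member_slots": member_slots,
                    "start_slot": start,
                    "span": span,
                    "gap_slots": gap_slots,
                }
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place planted cluster {ci} (span {span}); "
                "layout infeasible for the given chromosome sizes"
            )
    records.sort(key=lambda r: r["_index"])
    return state, records


def generate_genome(config: SimConfig | None = None) -> SimulatedGenome:
    """Generate gene table, annotation tables, paralog pairs and the truth ledger."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    sizes = config.resolved_chromosome_sizes()
    chrom_names = [f"chr{i + 1}" for i in range(len(sizes))]
    chrom_bounds = []
    cursor = 0
    for s in sizes:
        chrom_bounds.append((cursor, cursor + s - 1))
        cursor += s

    state, placements = _place_planted(rng, config, chrom_bounds)
    n_planted = sum(spec.n_members for spec in config.planted_clusters)

    # background family structure
    n_background = n - n_planted
    n_single = min(n_background, int(round(config.singleton_fraction * n)))
    multi_sizes = _sample_family_sizes(rng, config, n_background - n_single)
    leftover = n_background - n_single - sum(multi_sizes)
    n_single += leftover  # at most 1 gene, folded back into singletons

    labels: list[str] = []
    families: dict[str, list[str]] = {}
    for fi, size in enumerate(multi_sizes):
        labels.extend([f"FAM{fi + 1:05d}"] * size)
    for si in range(n_single):
        labels.append(f"SGL{si + 1:05d}")
    labels_arr = np.array(labels, dtype=object)
    rng.shuffle(labels_arr)

    # fill background genes into non-member slots in slot order
    family_of_slot = np.empty(n, dtype=object)
    free_slots = np.flatnonzero(state < 0)
    assert len(free_slots) == n_background
    family_of_slot[free_slots] = labels_arr
    for ci, spec in enumerate(config.planted_clusters):
        fam = f"PFAM{ci + 1:03d}"
        for slot in placements[ci]["member_slots"]:
            family_of_slot[slot] = fam

    # gene records (slot order == rank order)
    gene_ids = [f"G{slot + 1:06d}" for slot in range(n)]
    chromosome_col = np.empty(n, dtype=object)
    start_col = np.empty(n, dtype=np.int64)
    end_col = np.empty(n, dtype=np.int64)
    for (lo, hi), name in zip(chrom_bounds, chrom_names):
        count = hi - lo + 1
        starts = (
            np.arange(count, dtype=np.int64) * 2000
            + 1
            + rng.integers(0, 1000, size=count)
        )
        chromosome_col[lo : hi + 1] = name
        start_col[lo : hi + 1] = starts
        end_col[lo : hi + 1] = starts + 300 + rng.integers(0, 1500, size=count)
    strand_col = np.where(rng.random(n) < 0.5, "+", "-")
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chromosome_col,
            "start": start_col,
            "end": end_col,
            "strand": strand_col,
        }
    )

    for slot in range(n):
        families.setdefault(str(family_of_slot[slot]), []).append(gene_ids[slot])

    # prolific domains on dispersed background genes
    hf_carriers: dict[str, list[str]] = {}
    background_slots = free_slots
    for domain, count in config.high_frequency_domains:
        count = min(count, len(background_slots))
        if count == 0:
            continue
        chosen = rng.choice(background_slots, size=count, replace=False)
        hf_carriers[domain] = sorted(gene_ids[s] for s in chosen)

    # per-dataset annotation tables with per-gene dropout
    planted_records = []
    for ci, spec in enumerate(config.planted_clusters):
        slots = placements[ci]["member_slots"]
        planted_records.append(
            {
                "family": f"PFAM{ci + 1:03d}",
                "chromosome": str(chromosome_col[slots[0]]),
                "member_ranks": [s + 1 for s in slots],
                "member_gene_ids": [gene_ids[s] for s in slots],
                "start_rank": placements[ci]["start_slot"] + 1,
                "end_rank": placements[ci]["start_slot"] + placements[ci]["span"],
                "n_members": spec.n_members,
                "gaps": list(spec.gaps),
                "nested_in": spec.nested_in,
            }
        )

    ann_rows: list[tuple[str, str, str]] = []
    pair_rows: list[tuple[str, str, str]] = []
    dropped: dict[str, list[str]] = {}
    for ds in config.dataset_names:
        keep = rng.random(n) >= config.dropout
        dropped[ds] = [gene_ids[i] for i in range(n) if not keep[i]]
        if ds == "ensembl_paralogs":
            for fam, members in families.items():
                kept = [g for g in members if keep[int(g[1:]) - 1]]
                for i, a in enumerate(kept):
                    for b in kept[i + 1 :]:
                        pair_rows.append((ds, a, b))
        else:
            for slot in range(n):
                if not keep[slot]:
                    continue
                ann_rows.append((ds, gene_ids[slot], str(family_of_slot[slot])))
            if ds in HF_DATASET_NAMES:
                for domain, carriers in hf_carriers.items():
                    for g in carriers:
                        if keep[int(g[1:]) - 1]:
                            ann_rows.append((ds, g, domain))

    annotations = pd.DataFrame(
        ann_rows, columns=["dataset", "gene_id", "term_id"]
    ).sort_values(["dataset", "gene_id", "term_id"], kind="stable", ignore_index=True)
    pairs = pd.DataFrame(
        pair_rows, columns=["dataset", "gene_id_1", "gene_id_2"]
    ).sort_values(
        ["dataset", "gene_id_1", "gene_id_2"], kind="stable", ignore_index=True
    )

    ledger = TruthLedger(
        seed=config.seed,
        n_genes=n,
        chromosome_sizes=sizes,
        dataset_names=config.dataset_names,
        dropout=config.dropout,
        families={k: sorted(v) for k, v in sorted(families.items())},
        planted=planted_records,
        hf_carriers=hf_carriers,
        dropped={k: sorted(v) for k, v in dropped.items()},
    )
    return SimulatedGenome(genes=genes, annotations=annotations, pairs=pairs, ledger=ledger)


def generate_ortholog_map(
    ledger_a: TruthLedger,
    ledger_b: TruthLedger,
    conserved_fraction: float,
    seed: int = 0,
) -> OrthologMap:
    """Link a fraction of planted clusters across two genomes as in-paralogs.

    Cluster i of genome A is paired with cluster i of genome B; for each linked
    pair the members are joined 1:1 (up to the shorter member list) with the
    relation "inparalog". Linked cluster indices are recorded in both ledgers'
    ``conserved_clusters``.
    """
    if not 0.0 <= conserved_fraction <= 1.0:
        raise ValueError("conserved_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = min(len(ledger_a.planted), len(ledger_b.planted))
    pairs: set[tuple[str, str, str]] = set()
    conserved: list[int] = []
    for i in range(n):
        if rng.random() < conserved_fraction:
            conserved.append(i)
            mem_a = ledger_a.planted[i]["member_gene_ids"]
            mem_b = ledger_b.planted[i]["member_gene_ids"]
            for a, b in zip(mem_a, mem_b):
                pairs.add((a, b, "inparalog"))
    ledger_a.conserved_clusters = list(conserved)
    ledger_b.conserved_clusters = list(conserved)
    return OrthologMap(pairs=pairs)
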