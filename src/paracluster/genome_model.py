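"""Rank-ordered genome representation and term-based annotation evidence.

Every analysis in this package works on a *master gene list*: all protein-coding
genes of a genome placed in rank order along chromosomes, chromosome after
chromosome. Distances between genes are measured as rank differences, never in
base pairs, which removes gene-density artifacts and keeps only relative
positioning. The index assigns each gene a genome-wide ``rank`` (1..N) and a
per-chromosome ``chrom_rank``.

Annotation evidence of ancestral relatedness comes in two forms and is
normalized to one:

* term-based datasets (protein domains, superfamilies, protein families): a
  table mapping each gene to a set of term ids; two genes are related when they
  share at least one term;
* pair-based paralogy assertions (explicit gene-gene paralog pairs): converted
  to term form by taking connected components of the paralogy graph as
  synthetic family terms (:func:`pairs_to_families`).

For every term the genome-wide carrier count ``m`` (the number of genes in the
genome carrying the term) is tabulated exactly; ``m`` is the success count of
the hypergeometric model used downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Gene",
    "GenomeIndex",
    "AnnotationDataset",
    "ParalogPairSet",
    "build_gene_index",
    "pairs_to_families",
    "term_frequencies",
    "natural_chromosome_order",
    "read_gene_table",
    "write_gene_table",
    "read_annotation_table",
    "write_annotation_table",
    "annotation_datasets_from_frame",
    "read_paralog_pairs",
    "write_paralog_pairs",
    "paralog_pair_sets_from_frame",
]

GENE_TABLE_COLUMNS = ("gene_id", "chromosome", "start", "end", "strand")


@dataclass(frozen=True)
class Gene:
    """A positioned, ranked locus.

    Coordinates are 1-based closed; ``rank`` is the genome-wide position in the
    master list (1..N) and ``chrom_rank`` the position within the chromosome.
    Strand is carried for reporting only; no computation conditions on it.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    rank: int = 0
    chrom_rank: int = 0


class GenomeIndex:
    """Immutable rank-ordered master list of genes.

    ``genes[i].rank == i + 1``; chromosome spans partition 1..N in the stated
    chromosome order.
    """

    def __init__(self, genes: Sequence[Gene], chromosome_order: Sequence[str]):
        self.genes: list[Gene] = list(genes)
        self.chromosome_order: list[str] = list(chromosome_order)
        self.by_id: dict[str, Gene] = {}
        for g in self.genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self.by_id[g.gene_id] = g
        spans: dict[str, list[int]] = {}
        for g in self.genes:
            if g.chromosome in spans:
                spans[g.chromosome][1] = g.rank
            else:
                spans[g.chromosome] = [g.rank, g.rank]
        self.chromosome_spans: dict[str, tuple[int, int]] = {
            c: (lo, hi) for c, (lo, hi) in spans.items()
        }

    @property
    def N(self) -> int:
        return len(self.genes)

    def gene_at(self, rank: int) -> Gene:
        return self.genes[rank - 1]

    def chromosome_of_rank(self, rank: int) -> str:
        return self.genes[rank - 1].chromosome

    def ranks_of(self, gene_ids: Iterable[str]) -> list[int]:
        return [self.by_id[g].rank for g in gene_ids]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chromosome": [g.chromosome for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "rank": [g.rank for g in self.genes],
                "chrom_rank": [g.chrom_rank for g in self.genes],
            }
        )

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.genes)


def natural_chromosome_order(names: Iterable[str]) -> list[str]:
    """Natural sort of chromosome names (chr2 before chr10, X/Y/scaffolds after).

    Numeric fragments compare numerically, everything else lexicographically.
    """

    def key(name: str):
        parts = re.split(r"(\d+)", name)
        # numeric fragments sort before alphabetic ones (chr2 < chr10 < chrX)
        return tuple((0, int(p), "") if p.isdigit() else (1, 0, p) for p in parts if p != "")

    return sorted(set(names), key=key)


def build_gene_index(
    genes: pd.DataFrame | Iterable[Mapping | Gene],
    chromosome_order: Sequence[str] | None = None,
) -> GenomeIndex:
    """Assemble the rank-ordered master gene list.

    Ranks are assigned 1..N following ``chromosome_order`` then ascending start
    coordinate; ties broken by end coordinate, then by gene_id. When
    ``chromosome_order`` is None, chromosomes are natural-sorted by name
    (unplaced scaffolds simply sort as additional chromosomes).

    Raises ``ValueError`` on duplicate gene ids, invalid coordinates, or a
    chromosome absent from an explicit ``chromosome_order``.
    """
    if isinstance(genes, pd.DataFrame):
        records = genes.to_dict("records")
    else:
        records = [
            r if isinstance(r, Mapping) else {
                "gene_id": r.gene_id,
                "chromosome": r.chromosome,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
            }
            for r in genes
        ]
    if not records:
        raise ValueError("no gene records supplied")

    seen: set[str] = set()
    for r in records:
        gid = str(r["gene_id"])
        if gid in seen:
            raise ValueError(f"duplicate gene_id {gid!r}")
        seen.add(gid)
        start, end = int(r["start"]), int(r["end"])
        if start < 1 or end < start:
            raise ValueError(f"invalid coordinates for {gid!r}: start={start} end={end}")

    chroms_present = {str(r["chromosome"]) for r in records}
    if chromosome_order is None:
        order = natural_chromosome_order(chroms_present)
    else:
        order = list(chromosome_order)
        missing = chroms_present - set(order)
        if missing:
            raise ValueError(
                "chromosome(s) absent from chromosome_order: "
                + ", ".join(sorted(missing))
            )
    order_idx = {c: i for i, c in enumerate(order)}

    records.sort(
        key=lambda r: (
            order_idx[str(r["chromosome"])],
            int(r["start"]),
            int(r["end"]),
            str(r["gene_id"]),
        )
    )

    out: list[Gene] = []
    chrom_counter: dict[str, int] = {}
    for i, r in enumerate(records):
        chrom = str(r["chromosome"])
        chrom_counter[chrom] = chrom_counter.get(chrom, 0) + 1
        out.append(
            Gene(
                gene_id=str(r["gene_id"]),
                chromosome=chrom,
                start=int(r["start"]),
                end=int(r["end"]),
                strand=str(r.get("strand", ".") or "."),
                rank=i + 1,
                chrom_rank=chrom_counter[chrom],
            )
        )
    present_order = [c for c in order if c in chroms_present]
    return GenomeIndex(out, present_order)


@dataclass
class AnnotationDataset:
    """A named gene -> term-set map with exact genome-wide term frequencies.

    ``kind`` is "term-based" for native term tables and "pair-derived" for
    family terms obtained from paralog pairs. A gene may carry zero, one or
    many terms.
    """

    name: str
    terms: dict[str, frozenset[str]]
    freq: dict[str, int] = field(default_factory=dict)
    kind: str = "term-based"
    _rank_cache: tuple[int, list[frozenset[str]]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.freq:
            self.freq = term_frequencies(self)

    @classmethod
    def from_assignments(
        cls,
        name: str,
        assignments: Iterable[tuple[str, str]],
        index: GenomeIndex | None = None,
        kind: str = "term-based",
    ) -> "AnnotationDataset":
        by_gene: dict[str, set[str]] = {}
        for gene_id, term in assignments:
            by_gene.setdefault(str(gene_id), set()).add(str(term))
        if index is not None:
            unknown = sorted(g for g in by_gene if g not in index.by_id)
            if unknown:
                raise ValueError(
                    f"dataset {name!r} annotates gene(s) absent from the gene index: "
                    + ", ".join(unknown[:10])
                    + ("..." if len(unknown) > 10 else "")
                )
        terms = {g: frozenset(ts) for g, ts in by_gene.items()}
        return cls(name=name, terms=terms, kind=kind)

    def n_annotated(self) -> int:
        return sum(1 for ts in self.terms.values() if ts)

    def rank_term_sets(self, index: GenomeIndex) -> list[frozenset[str]]:
        """Term sets aligned to ranks (entry i is the terms of rank i+1).

        Cached per index identity; the index is immutable in practice.
        """
        if self._rank_cache is not None and self._rank_cache[0] == id(index):
            return self._rank_cache[1]
        empty: frozenset[str] = frozenset()
        sets = [self.terms.get(g.gene_id, empty) for g in index.genes]
        self._rank_cache = (id(index), sets)
        return sets

    def carriers_by_term(self, index: GenomeIndex) -> dict[str, list[int]]:
        """Sorted carrier ranks per term (ranks are ascending by construction)."""
        out: dict[str, list[int]] = {}
        for g in index.genes:
            for t in self.terms.get(g.gene_id, ()):  # index order => sorted ranks
                out.setdefault(t, []).append(g.rank)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.name, g, t)
            for g in sorted(self.terms)
            for t in sorted(self.terms[g])
        ]
        return pd.DataFrame(rows, columns=["dataset", "gene_id", "term_id"])


def term_frequencies(dataset: AnnotationDataset | Mapping[str, frozenset[str]]) -> dict[str, int]:
    """Exact count, per term, of genes carrying the term (m).

    A gene carrying a term is counted once regardless of multiplicity; terms
    carried by no gene do not appear.
    """
    terms = dataset.terms if isinstance(dataset, AnnotationDataset) else dataset
    freq: dict[str, int] = {}
    for ts in terms.values():
        for t in ts:
            freq[t] = freq.get(t, 0) + 1
    return freq


@dataclass
class ParalogPairSet:
    """Unordered gene-gene paralogy assertions for one dataset."""

    name: str
    pairs: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, str]]) -> "ParalogPairSet":
        canon: set[tuple[str, str]] = set()
        for a, b in pairs:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-pair {a!r} in paralog set {name!r}")
            canon.add((a, b) if a < b else (b, a))
        return cls(name=name, pairs=canon)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(
            {
                "dataset": self.name,
                "gene_id_1": [a for a, _ in rows],
                "gene_id_2": [b for _, b in rows],
            }
        )


def pairs_to_families(pairs: ParalogPairSet, index: GenomeIndex) -> AnnotationDataset:
    """Convert pairwise paralogy to family terms via connected components.

    Each connected component of the paralogy graph becomes one synthetic term
    named after the component's lexicographically smallest gene id, so the
    result is independent of pair input order. ``freq`` of a component term is
    the component size.
    """
    unknown = sorted(
        {g for pair in pairs.pairs for g in pair if g not in index.by_id}
    )
    if unknown:
        raise ValueError(
            f"paralog pair set {pairs.name!r} references gene(s) absent from the "
            "gene index: " + ", ".join(unknown[:10])
        )
    graph = nx.Graph()
    graph.add_edges_from(pairs.pairs)
    assignments: list[tuple[str, str]] = []
    for component in nx.connected_components(graph):
        term = f"{pairs.name}:fam:{min(component)}"
        assignments.extend((g, term) for g in component)
    return AnnotationDataset.from_assignments(
        pairs.name, assignments, index=index, kind="pair-derived"
    )


# ---------------------------------------------------------------------------
# Table I/O
#
# Gene tables: TSV (gene_id, chromosome, start, end[, strand]), BED6 (0-based
# half-open, converted to 1-based closed) or GFF3 (feature type "gene", ID
# attribute). Annotation tables: TSV (dataset, gene_id, term_id). Paralog
# pairs: TSV (dataset, gene_id_1, gene_id_2).
# ---------------------------------------------------------------------------


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return "bed"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    return "tsv"


def read_gene_table(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a gene position table (TSV / BED6 / GFF3) into standard columns.

    Output columns: gene_id, chromosome, start, end, strand with 1-based
    closed coordinates.
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
        missing = {"gene_id", "chromosome", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"gene table {path} lacks column(s): {sorted(missing)}")
        if "strand" not in df.columns:
            df["strand"] = "."
        return df[list(GENE_TABLE_COLUMNS)]
    if fmt == "bed":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chromosome", "start", "end", "gene_id", "score", "strand"],
            usecols=range(6),
            dtype={"chromosome": str, "gene_id": str, "strand": str},
        )
        df["start"] = df["start"].astype(int) + 1  # BED is 0-based half-open
        df["end"] = df["end"].astype(int)
        return df[list(GENE_TABLE_COLUMNS)]
    if fmt == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        rows = []
        for feat in db.features_of_type("gene"):
            gid = feat.attributes.get("ID", [feat.id])[0]
            rows.append(
                (gid, feat.seqid, int(feat.start), int(feat.end), feat.strand or ".")
            )
        return pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS))
    raise ValueError(f"unknown gene table format {fmt!r}")


def write_gene_table(
    genes: GenomeIndex | pd.DataFrame, path: str | Path, fmt: str | None = None
) -> Path:
    """Write a gene table as TSV, BED6 or GFF3 (inverse of :func:`read_gene_table`)."""
    path = Path(path)
    fmt = fmt or _detect_format(path)
    df = genes.to_frame() if isinstance(genes, GenomeIndex) else genes
    if fmt == "tsv":
        df[list(GENE_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        out = pd.DataFrame(
            {
                "chromosome": df["chromosome"],
                "start": df["start"].astype(int) - 1,
                "end": df["end"].astype(int),
                "gene_id": df["gene_id"],
                "score": 0,
                "strand": df["strand"].replace(".", "."),
            }
        )
        out.to_csv(path, sep="\t", index=False, header=False)
    elif fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in df.itertuples(index=False):
                strand = r.strand if r.strand in ("+", "-") else "."
                fh.write(
                    f"{r.chromosome}\tparacluster\tgene\t{int(r.start)}\t{int(r.end)}"
                    f"\t.\t{strand}\t.\tID={r.gene_id}\n"
                )
    else:
        raise ValueError(f"unknown gene table format {fmt!r}")
    return path


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"dataset", "gene_id", "term_id"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks column(s): {sorted(missing)}")
    return df[["dataset", "gene_id", "term_id"]]


def write_annotation_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[["dataset", "gene_id", "term_id"]].to_csv(path, sep="\t", index=False)
    return path


def annotation_datasets_from_frame(
    df: pd.DataFrame, index: GenomeIndex
) -> dict[str, AnnotationDataset]:
    """Split a long annotation table into one dataset per ``dataset`` value."""
    out: dict[str, AnnotationDataset] = {}
    for name, grp in df.groupby("dataset", sort=True):
        out[str(name)] = AnnotationDataset.from_assignments(
            str(name), zip(grp["gene_id"], grp["term_id"]), index=index
        )
    return out


def read_paralog_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"dataset", "gene_id_1", "gene_id_2"} - set(df.columns)
    if missing:
        raise ValueError(f"paralog pair table {path} lacks column(s): {sorted(missing)}")
    return df[["dataset", "gene_id_1", "gene_id_2"]]


def write_paralog_pairs(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[["dataset", "gene_id_1", "gene_id_2"]].to_csv(path, sep="\t", index=False)
    return path


def paralog_pair_sets_from_frame(df: pd.DataFrame) -> dict[str, ParalogPairSet]:
    out: dict[str, ParalogPairSet] = {}
    for name, grp in df.groupby("dataset", sort=True):
        out[str(name)] = ParalogPairSet.from_pairs(
            str(name), zip(grp["gene_id_1"], grp["gene_id_2"])
        )
    return out
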