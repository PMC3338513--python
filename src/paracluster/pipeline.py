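"""End-to-end pipeline: index -> walk -> chaining -> scoring -> merging -> reports.

The pipeline is a thin orchestration over the library modules. Every run
writes a provenance record (parameters, seed, input checksums) and logs gene,
chain and cluster counts at each stage so regressions are observable. All
report files are plain TSV/JSON and byte-identical across runs with the same
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .chaining import ChainingConfig, chains_to_frame, detect_chains_all
from .genome_model import (
    AnnotationDataset,
    GenomeIndex,
    annotation_datasets_from_frame,
    build_gene_index,
    pairs_to_families,
    paralog_pair_sets_from_frame,
    read_annotation_table,
    read_gene_table,
    read_paralog_pairs,
)
from .merging import (
    dataset_overlap_matrix,
    genome_metrics,
    merge_across_datasets,
    paraclusters_to_frame,
)
from .proximity_walk import (
    nearest_histogram_frame,
    permutation_baseline,
    relatedness_profile,
    walk_profile_frame,
)
from .significance import filter_significant, score_chains

__all__ = ["RunConfig", "run_pipeline", "coverage_audit", "load_inputs", "PipelineResult"]

logger = logging.getLogger("paracluster")


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the method's standard operating point
    (span 100, gap 15, e < 0.01, 10 permutations)."""

    genes: str
    out_dir: str
    annotations: str | None = None
    pairs: str | None = None
    datasets: tuple[str, ...] | None = None  # roster; None = all present
    chromosome_order: tuple[str, ...] | None = None
    max_span: int = 100
    max_gap: int = 15
    max_gaps: int | None = None
    collapse_nested: bool = True
    e_threshold: float = 0.01
    n_permutations: int = 10
    seed: int = 0
    run_walk: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("datasets", "chromosome_order"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("datasets", "chromosome_order"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def chaining_config(self) -> ChainingConfig:
        return ChainingConfig(
            max_gap=self.max_gap,
            max_gaps=self.max_gaps,
            collapse_nested=self.collapse_nested,
        )


@dataclass
class PipelineResult:
    index: GenomeIndex
    datasets: dict[str, AnnotationDataset]
    chains_by_dataset: dict
    significant_by_dataset: dict
    paraclusters: list
    summary: dict
    paths: dict[str, Path]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def load_inputs(config: RunConfig) -> tuple[GenomeIndex, dict[str, AnnotationDataset]]:
    """Read and validate gene, annotation and paralog-pair tables."""
    genes_path = Path(config.genes)
    if not genes_path.exists():
        raise FileNotFoundError(f"gene table not found: {genes_path}")
    index = build_gene_index(read_gene_table(genes_path), config.chromosome_order)

    datasets: dict[str, AnnotationDataset] = {}
    if config.annotations:
        ann_path = Path(config.annotations)
        if not ann_path.exists():
            raise FileNotFoundError(f"annotation table not found: {ann_path}")
        datasets.update(
            annotation_datasets_from_frame(read_annotation_table(ann_path), index)
        )
    if config.pairs:
        pairs_path = Path(config.pairs)
        if not pairs_path.exists():
            raise FileNotFoundError(f"paralog pair table not found: {pairs_path}")
        for name, pairset in paralog_pair_sets_from_frame(
            read_paralog_pairs(pairs_path)
        ).items():
            datasets[name] = pairs_to_families(pairset, index)
    if config.datasets is not None:
        missing = [d for d in config.datasets if d not in datasets]
        if missing:
            raise ValueError(f"dataset(s) not found in inputs: {missing}")
        datasets = {d: datasets[d] for d in config.datasets}
    if not datasets:
        raise ValueError("no annotation datasets supplied")
    return index, datasets


def coverage_audit(
    index: GenomeIndex, datasets: Mapping[str, AnnotationDataset]
) -> dict:
    """Annotation coverage: per dataset, per chromosome, and genome dark regions.

    Genes unannotated in every dataset still occupy ranks (they can only be
    interstitial); the audit makes their extent visible.
    """
    per_dataset = {}
    annotated_anywhere: set[str] = set()
    for name, ds in sorted(datasets.items()):
        annotated = {g for g, ts in ds.terms.items() if ts}
        annotated_anywhere |= annotated
        per_dataset[name] = len(annotated) / index.N
    per_chromosome = {}
    for chrom in index.chromosome_order:
        lo, hi = index.chromosome_spans[chrom]
        ids = [index.gene_at(r).gene_id for r in range(lo, hi + 1)]
        covered = sum(1 for g in ids if g in annotated_anywhere)
        per_chromosome[chrom] = covered / len(ids)
    dark = sorted(
        g.gene_id for g in index.genes if g.gene_id not in annotated_anywhere
    )
    return {
        "per_dataset_coverage": per_dataset,
        "per_chromosome_coverage": per_chromosome,
        "unannotated_everywhere": dark,
        "overall_coverage": len(annotated_anywhere) / index.N,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write all report files to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    index, datasets = load_inputs(config)
    logger.info("indexed %d genes on %d chromosomes; %d datasets",
                index.N, len(index.chromosome_order), len(datasets))

    config_record = config.to_dict()
    config_record.pop("out_dir")  # identical runs into different dirs stay byte-identical
    provenance = {
        "config": config_record,
        "inputs": {
            name: _sha256(p)
            for name, p in (
                ("genes", config.genes),
                ("annotations", config.annotations),
                ("pairs", config.pairs),
            )
            if p
        },
        "n_genes": index.N,
    }
    paths["run_info"] = out / "run_info.yaml"
    paths["run_info"].write_text(yaml.safe_dump(provenance, sort_keys=True))

    if config.run_walk:
        for name, ds in sorted(datasets.items()):
            profile = relatedness_profile(index, ds, config.max_span)
            baseline = permutation_baseline(
                index, ds, config.n_permutations, config.max_span, config.seed
            )
            walk_profile_frame(profile, baseline).to_csv(
                out / f"walk_{name}.tsv", sep="\t", index=False
            )
            nearest_histogram_frame(profile, baseline).to_csv(
                out / f"nearest_{name}.tsv", sep="\t", index=False
            )
            paths[f"walk_{name}"] = out / f"walk_{name}.tsv"
            paths[f"nearest_{name}"] = out / f"nearest_{name}.tsv"
            logger.info("walk %s: %d related pairs within span %d",
                        name, profile.total_related_pairs(), config.max_span)

    chains = detect_chains_all(index, datasets, config.chaining_config())
    scored = {
        name: score_chains(cs, datasets[name], index.N) for name, cs in chains.items()
    }
    significant = {
        name: filter_significant(cs, config.e_threshold) for name, cs in scored.items()
    }
    for name in sorted(scored):
        frame = chains_to_frame(scored[name], index)
        frame.to_csv(out / f"chains_{name}.tsv", sep="\t", index=False)
        paths[f"chains_{name}"] = out / f"chains_{name}.tsv"
        logger.info("chains %s: %d candidates, %d significant at e<%g",
                    name, len(scored[name]), len(significant[name]), config.e_threshold)

    paraclusters = merge_across_datasets(significant, index)
    paraclusters_to_frame(paraclusters).to_csv(
        out / "paraclusters.tsv", sep="\t", index=False
    )
    paths["paraclusters"] = out / "paraclusters.tsv"
    logger.info("merged %d paraclusters", len(paraclusters))

    summary_obj = genome_metrics(paraclusters, significant, index)
    summary = summary_obj.to_dict()
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True))
    summary_obj.size_distribution.to_csv(
        out / "size_distribution.tsv", sep="\t", index=False
    )
    paths["size_distribution"] = out / "size_distribution.tsv"
    overlap = dataset_overlap_matrix(significant, index)
    overlap.to_csv(out / "overlap_matrix.tsv", sep="\t")
    paths["overlap_matrix"] = out / "overlap_matrix.tsv"

    audit = coverage_audit(index, datasets)
    paths["coverage"] = out / "coverage.json"
    paths["coverage"].write_text(json.dumps(audit, indent=1, sort_keys=True))

    return PipelineResult(
        index=index,
        datasets=datasets,
        chains_by_dataset=scored,
        significant_by_dataset=significant,
        paraclusters=paraclusters,
        summary=summary,
        paths=paths,
    )
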