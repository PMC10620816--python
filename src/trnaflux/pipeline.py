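"""End-to-end orchestration: ratio ranking -> decoding -> codon scan ->
translational filter -> nomination, from a single config.

The runner only sequences the library stages (no hidden computation),
writes every stage's table, and emits a machine-readable JSON report
carrying the package version, the full config snapshot, and per-stage
row counts. Identical config + inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .codon_usage import criteria_for_anticodon, scan_cds_set
from .compartment_ratio import (
    distribution_ratio,
    normalize_counts,
    read_counts_tsv,
    select_candidates,
    write_ratio_tsv,
)
from .nomination import nominate, read_gene_list
from .omics_filter import (
    TranslationalFilterConfig,
    read_omics_tables,
    translationally_down,
)
from .trna_names import parse_trna_name

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("trnaflux")


@dataclass
class PipelineConfig:
    counts: str
    cds: str
    proteins: str
    mrna: str
    functional: str
    outdir: str = "trnaflux_out"
    anticodon: str | None = None  # derived from the top candidate when None
    pseudocount: float = 0.5
    top_k: int | None = 2
    ratio_threshold: float | None = None
    score_min: float = 0.02
    ratio_min: float = 1.0
    all_synonymous: bool = False
    protein_max: float = -1.0
    mrna_abs_max: float = 0.585
    mrna_min_adj_p: float = 0.05
    seed: int | None = None  # recorded for provenance in simulation mode

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written to report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_echo = {
        "pseudocount": config.pseudocount,
        "normalization": "CPM per compartment-condition column",
    }
    stage_counts: dict[str, int] = {}

    _stage("ratio")
    counts = read_counts_tsv(config.counts)
    stage_counts["counts_rows"] = len(counts)
    normalized = normalize_counts(counts, pseudocount=config.pseudocount)
    ranked = distribution_ratio(normalized)
    stage_counts["ranked_rows"] = len(ranked)
    write_ratio_tsv(ranked, outdir / "ratio.tsv", params=counts_echo)
    candidates = select_candidates(
        ranked, top_k=config.top_k, threshold=config.ratio_threshold
    )
    stage_counts["candidates"] = len(candidates)
    logger.info("candidates: %s", candidates)

    _stage("decode")
    if config.anticodon is not None:
        anticodon = config.anticodon
    else:
        anticodon = None
        for name in candidates:
            try:
                anticodon = parse_trna_name(name).anticodon
                break
            except ValueError:
                continue
        if anticodon is None:
            raise ValueError("no candidate name parses as a tRNA isodecoder")
    criteria = criteria_for_anticodon(
        anticodon,
        score_threshold=config.score_min,
        ratio_threshold=config.ratio_min,
        all_synonymous=config.all_synonymous,
    )
    logger.info(
        "anticodon %s -> target %s vs %s",
        anticodon,
        criteria.target_codon,
        sorted(criteria.comparison_codons),
    )

    _stage("codon-scan")
    enriched, scan_table = scan_cds_set(config.cds, criteria)
    stage_counts["cds_genes"] = len(scan_table)
    stage_counts["codon_enriched"] = len(enriched)
    scan_table.to_csv(outdir / "codon_scan.tsv", sep="\t")

    _stage("omics-filter")
    omics = read_omics_tables(config.proteins, config.mrna)
    stage_counts["omics_rows"] = len(omics)
    filter_config = TranslationalFilterConfig(
        protein_down_log2_max=config.protein_max,
        mrna_unchanged_abs_log2_max=config.mrna_abs_max,
        mrna_unchanged_min_adj_p=config.mrna_min_adj_p,
    )
    translational, omics_table = translationally_down(omics, filter_config)
    stage_counts["translational_down"] = len(translational)
    omics_table.to_csv(outdir / "translational_down.tsv", sep="\t")

    _stage("nominate")
    functional = read_gene_list(config.functional)
    stage_counts["functional"] = len(functional)
    report = nominate(
        enriched,
        translational,
        functional,
        provenance_sources={
            "codon_scan": {
                g: scan_table.loc[g].to_dict() for g in enriched if g in scan_table.index
            },
            "omics_filter": {
                g: omics_table.loc[g].to_dict()
                for g in translational
                if g in omics_table.index
            },
        },
        parameters={
            "version": __version__,
            "config": config.to_dict(),
            "anticodon": anticodon,
            "target_codon": criteria.target_codon,
            "comparison_codons": sorted(criteria.comparison_codons),
            **counts_echo,
        },
    )
    stage_counts["nominated"] = len(report.nominated)

    full_report = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_counts": stage_counts,
        "candidates": candidates,
        "anticodon": anticodon,
        "target_codon": criteria.target_codon,
        "nomination": report.to_dict(),
    }
    (outdir / "report.json").write_text(
        json.dumps(full_report, indent=2, sort_keys=True, default=str) + "\n"
    )
    with open(outdir / "nominated.tsv", "w") as handle:
        handle.write("gene_id\n")
        for gene in sorted(report.nominated):
            handle.write(gene + "\n")
    logger.info("nominated: %s", sorted(report.nominated))
    return full_report
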