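"""Three-way gene-set intersection nominating translational target genes.

The candidate targets are the genes that are simultaneously (i) enriched
for the cognate codon of the retained tRNA, (ii) translationally
downregulated (protein down, mRNA unchanged), and (iii) on the
user-supplied functional list (e.g. cytokinesis genes). Identifier
harmonization is exact symbol match after case-folding and whitespace
stripping; no alias or ortholog mapping is attempted, and identifiers that
match nothing across sets are listed in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = ["NominationReport", "nominate", "read_gene_list"]


def _harmonize(genes: Iterable[str]) -> dict[str, str]:
    """Map case-folded, stripped symbol -> first-seen original spelling."""
    out: dict[str, str] = {}
    for gene in genes:
        key = str(gene).strip().casefold()
        if key and key not in out:
            out[key] = str(gene).strip()
    return out


@dataclass
class NominationReport:
    codon_enriched: set[str]
    translational_down: set[str]
    functional: set[str]
    nominated: set[str]
    provenance: dict[str, dict] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    unmatched: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "codon_enriched": len(self.codon_enriched),
            "translational_down": len(self.translational_down),
            "functional": len(self.functional),
            "nominated": len(self.nominated),
        }

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "nominated": sorted(self.nominated),
            "provenance": self.provenance,
            "parameters": self.parameters,
            "unmatched": self.unmatched,
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list: one symbol per line, '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def nominate(
    codon_enriched: Iterable[str],
    translational_down: Iterable[str],
    functional: Iterable[str],
    *,
    provenance_sources: Mapping[str, Mapping[str, object]] | None = None,
    parameters: dict | None = None,
) -> NominationReport:
    """Intersect the three gene sets and assemble a provenance-carrying report.

    ``provenance_sources`` optionally maps a source label to a per-gene
    record dict (e.g. the codon-scan or omics-filter audit rows); each
    nominated gene's entries are copied into the report. An empty
    functional list is a configuration error.
    """
    codon_map = _harmonize(codon_enriched)
    trans_map = _harmonize(translational_down)
    func_map = _harmonize(functional)
    if not func_map:
        raise ValueError("functional gene list is empty — misconfiguration")

    nominated_keys = set(codon_map) & set(trans_map) & set(func_map)
    nominated = {func_map[k] for k in nominated_keys}

    all_keys = set(codon_map) | set(trans_map) | set(func_map)
    unmatched = {
        "codon_enriched_only": sorted(
            codon_map[k] for k in set(codon_map) - set(trans_map) - set(func_map)
        ),
        "translational_down_only": sorted(
            trans_map[k] for k in set(trans_map) - set(codon_map) - set(func_map)
        ),
        "functional_only": sorted(
            func_map[k] for k in set(func_map) - set(codon_map) - set(trans_map)
        ),
    }

    provenance: dict[str, dict] = {}
    for key in nominated_keys:
        gene = func_map[key]
        record: dict[str, object] = {
            "in_codon_enriched": True,
            "in_translational_down": True,
            "in_functional": True,
        }
        if provenance_sources:
            for label, per_gene in provenance_sources.items():
                harmonized = {str(g).strip().casefold(): v for g, v in per_gene.items()}
                if key in harmonized:
                    record[label] = harmonized[key]
        provenance[gene] = record

    report = NominationReport(
        codon_enriched={codon_map[k] for k in codon_map},
        translational_down={trans_map[k] for k in trans_map},
        functional={func_map[k] for k in func_map},
        nominated=nominated,
        provenance=provenance,
        parameters=dict(parameters or {}),
        unmatched=unmatched,
    )
    assert len(all_keys) >= len(nominated_keys)
    return report
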