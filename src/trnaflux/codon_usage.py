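"""Per-gene codon usage scoring and cognate-codon enrichment screening.

A gene's codon usage profile is the count of each of the 64 codons over the
in-frame triplets of its CDS (trailing stop excluded). Two normalizations
are kept side by side:

* ``score[c]`` — fraction of codons, ``counts[c] / total_codons``; the
  enrichment threshold (default 0.02, i.e. 2% of codons) applies to this.
* ``per_kilobase[c]`` — occurrences per 1000 nucleotides,
  ``counts[c] / (3 * total_codons) * 1000``; reported for audit only.

A gene is *enriched* for a target codon when its score exceeds the
threshold and beats each synonymous comparison codon by the ratio
threshold (strict inequalities). For anticodon-derived criteria the
comparison set defaults to the wobble-read synonymous codons minus the
cognate (for AGC: GCC and GCA; the fourth Ala codon GCG is not read by
this anticodon and is excluded by default).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .trna_names import (
    _CODON_TABLE,
    degenerate_codons,
    synonymous_codons,
    translate_codon,
)

__all__ = [
    "CodingSequenceRecord",
    "CodonUsageProfile",
    "EnrichmentCriteria",
    "criteria_for_anticodon",
    "count_codons",
    "is_enriched",
    "scan_cds_set",
    "read_cds_fasta",
]

ALL_CODONS = tuple(sorted(_CODON_TABLE))
STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")


@dataclass(frozen=True)
class CodingSequenceRecord:
    gene_id: str
    cds: str

    def __post_init__(self):
        canon = self.cds.strip().upper().replace("U", "T")
        object.__setattr__(self, "cds", canon)
        bad = set(canon) - set("ACGT")
        if bad:
            raise ValueError(
                f"CDS of {self.gene_id!r} contains ambiguous/invalid bases: {sorted(bad)}"
            )


@dataclass(frozen=True)
class CodonUsageProfile:
    gene_id: str
    counts: dict[str, int]
    total_codons: int
    score: dict[str, float] = field(repr=False)
    per_kilobase: dict[str, float] = field(repr=False)


@dataclass(frozen=True)
class EnrichmentCriteria:
    """Target-codon selection rule: score > score_threshold and
    score[target]/score[c] > ratio_threshold for every comparison codon c."""

    target_codon: str
    score_threshold: float = 0.02
    comparison_codons: frozenset[str] = frozenset()
    ratio_threshold: float = 1.0

    def __post_init__(self):
        target_aa = translate_codon(self.target_codon)
        if target_aa == "*":
            raise ValueError("target codon must not be a stop codon")
        for codon in self.comparison_codons:
            if translate_codon(codon) != target_aa:
                raise ValueError(
                    f"comparison codon {codon} is not synonymous with "
                    f"{self.target_codon} ({target_aa})"
                )


def criteria_for_anticodon(
    anticodon: str,
    score_threshold: float = 0.02,
    ratio_threshold: float = 1.0,
    *,
    all_synonymous: bool = False,
) -> EnrichmentCriteria:
    """Build criteria from an anticodon: target = cognate codon, comparisons
    = the other wobble-read codons (or, with ``all_synonymous``, every other
    synonymous codon of the amino acid)."""
    codon_set = degenerate_codons(anticodon)
    if all_synonymous:
        comparisons = synonymous_codons(codon_set.amino_acid) - {codon_set.cognate_codon}
    else:
        comparisons = codon_set.degenerate_codons - {codon_set.cognate_codon}
    return EnrichmentCriteria(
        target_codon=codon_set.cognate_codon,
        score_threshold=score_threshold,
        comparison_codons=frozenset(comparisons),
        ratio_threshold=ratio_threshold,
    )


def count_codons(record: CodingSequenceRecord) -> CodonUsageProfile:
    """In-frame codon counts from position 1; trailing stop excluded.

    Internal stop codons are counted but flagged with a warning; a length
    not divisible by 3 is an error naming the gene.
    """
    cds = record.cds
    if len(cds) % 3 != 0:
        raise ValueError(
            f"CDS length of {record.gene_id!r} ({len(cds)}) is not divisible by 3"
        )
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise ValueError(f"CDS of {record.gene_id!r} has no coding codons")
    internal_stops = sum(1 for c in codons if c in STOP_CODONS)
    if internal_stops:
        warnings.warn(
            f"{record.gene_id}: {internal_stops} internal stop codon(s) in frame",
            stacklevel=2,
        )
    counts = {c: 0 for c in ALL_CODONS}
    for codon in codons:
        counts[codon] += 1
    total = len(codons)
    score = {c: n / total for c, n in counts.items()}
    per_kb = {c: n / (3 * total) * 1000 for c, n in counts.items()}
    return CodonUsageProfile(
        gene_id=record.gene_id,
        counts=counts,
        total_codons=total,
        score=score,
        per_kilobase=per_kb,
    )


def is_enriched(
    profile: CodonUsageProfile, criteria: EnrichmentCriteria
) -> tuple[bool, list[str]]:
    """Apply the selection rule; returns (decision, reasons).

    On failure the reasons list names each failing clause. A comparison
    codon with zero count while the target count is positive passes its
    ratio clause (ratio treated as +infinity).
    """
    reasons: list[str] = []
    target = criteria.target_codon
    target_score = profile.score[target]
    if not target_score > criteria.score_threshold:
        reasons.append(
            f"score[{target}]={target_score:.6g} not > {criteria.score_threshold}"
        )
    for codon in sorted(criteria.comparison_codons):
        comp_score = profile.score[codon]
        if comp_score == 0:
            if target_score > 0:
                continue  # ratio is +infinity
            reasons.append(f"score[{target}]=0 with score[{codon}]=0")
            continue
        ratio = target_score / comp_score
        if not ratio > criteria.ratio_threshold:
            reasons.append(
                f"score[{target}]/score[{codon}]={ratio:.6g} not > {criteria.ratio_threshold}"
            )
    return (not reasons), reasons


def read_cds_fasta(
    path: str | Path, *, id_regex: str = r"^(\S+)"
) -> tuple[list[CodingSequenceRecord], dict]:
    """Read a CDS FASTA; gene id is the first regex group applied to the
    header (default: first whitespace-delimited token).

    Duplicate gene ids keep the longest CDS; unparseable records are
    skipped with a warning. Returns (records, stats) where stats counts
    skipped and duplicate-dropped records.
    """
    pattern = re.compile(id_regex)
    kept: dict[str, CodingSequenceRecord] = {}
    stats = {"skipped": 0, "duplicates_dropped": 0}
    n_seen = 0
    for seq_record in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        match = pattern.search(seq_record.description)
        gene_id = match.group(1) if match else seq_record.id
        try:
            record = CodingSequenceRecord(gene_id=gene_id, cds=str(seq_record.seq))
        except ValueError as exc:
            warnings.warn(f"skipping record {gene_id!r}: {exc}", stacklevel=2)
            stats["skipped"] += 1
            continue
        if gene_id in kept:
            stats["duplicates_dropped"] += 1
            if len(record.cds) <= len(kept[gene_id].cds):
                continue
        kept[gene_id] = record
    if n_seen == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return list(kept.values()), stats


def scan_cds_set(
    records: list[CodingSequenceRecord] | str | Path,
    criteria: EnrichmentCriteria,
) -> tuple[set[str], pd.DataFrame]:
    """Score every CDS and apply the enrichment criteria.

    ``records`` may be a FASTA path or a pre-read record list. Returns the
    enriched gene set and a full per-gene audit table (counts, score,
    per-kilobase frequency, comparison ratios, decision, reasons).
    """
    if isinstance(records, (str, Path)):
        records, _ = read_cds_fasta(records)
    if not records:
        raise ValueError("empty CDS set")
    target = criteria.target_codon
    rows = []
    enriched_genes: set[str] = set()
    for record in records:
        profile = count_codons(record)
        ok, reasons = is_enriched(profile, criteria)
        row = {
            "gene_id": record.gene_id,
            "total_codons": profile.total_codons,
            f"count_{target}": profile.counts[target],
            f"score_{target}": profile.score[target],
            f"per_kb_{target}": profile.per_kilobase[target],
        }
        for codon in sorted(criteria.comparison_codons):
            comp = profile.score[codon]
            row[f"ratio_vs_{codon}"] = (
                float("inf") if comp == 0 else profile.score[target] / comp
            )
        row["enriched"] = ok
        row["reason"] = "" if ok else "; ".join(reasons)
        rows.append(row)
        if ok:
            enriched_genes.add(record.gene_id)
    table = pd.DataFrame(rows).set_index("gene_id")
    return enriched_genes, table
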