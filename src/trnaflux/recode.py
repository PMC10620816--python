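"""Synonymous-codon mutant CDS design.

Every in-frame occurrence of a target codon is replaced by a chosen
synonymous codon (the "all-to-one" mode, mirroring an all-GCT-to-GCC or
all-GCT-to-GCA mutant plasmid); an "alternating" mode cycles through a
list of synonymous replacements for GC-content balance. The translated
protein is verified identical on every call, and the frame is taken from
position 1 of the provided CDS (no ORF search).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .codon_usage import CodingSequenceRecord
from .trna_names import translate_codon

__all__ = ["RecodeResult", "recode_cds"]


@dataclass(frozen=True)
class RecodeResult:
    gene_id: str
    original_cds: str
    mutant_cds: str
    replacements: int
    replacement_positions: tuple[int, ...]  # 1-based codon indices
    mode: str


def recode_cds(
    record: CodingSequenceRecord,
    target_codon: str,
    replacement: str | Sequence[str],
    *,
    mode: str = "all-to-one",
) -> RecodeResult:
    """Replace every in-frame target codon with a synonymous codon.

    ``replacement`` is a single codon for ``mode="all-to-one"`` or a
    sequence of codons cycled in order for ``mode="alternating"``.
    Raises on a non-synonymous or identity replacement, and verifies that
    the mutant translates to the same protein as the original.
    """
    cds = record.cds
    if len(cds) % 3 != 0:
        raise ValueError(
            f"CDS length of {record.gene_id!r} ({len(cds)}) is not divisible by 3"
        )
    target = target_codon.strip().upper().replace("U", "T")
    target_aa = translate_codon(target)
    if target_aa == "*":
        raise ValueError("target codon must not be a stop codon")

    if mode == "all-to-one":
        if not isinstance(replacement, str):
            raise ValueError("all-to-one mode takes a single replacement codon")
        cycle = [replacement]
    elif mode == "alternating":
        if isinstance(replacement, str) or not replacement:
            raise ValueError("alternating mode takes a non-empty codon sequence")
        cycle = list(replacement)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cycle = [c.strip().upper().replace("U", "T") for c in cycle]
    for codon in cycle:
        if translate_codon(codon) != target_aa:
            raise ValueError(
                f"replacement {codon} not synonymous with {target} ({target_aa})"
            )
        if codon == target:
            raise ValueError("replacement codon equals the target codon")

    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    positions = []
    for idx, codon in enumerate(codons):
        if codon == target:
            codons[idx] = cycle[len(positions) % len(cycle)]
            positions.append(idx + 1)
    mutant = "".join(codons)

    if str(Seq(mutant).translate()) != str(Seq(cds).translate()):
        raise AssertionError(
            f"internal error: recoded {record.gene_id!r} changes the protein"
        )
    return RecodeResult(
        gene_id=record.gene_id,
        original_cds=cds,
        mutant_cds=mutant,
        replacements=len(positions),
        replacement_positions=tuple(positions),
        mode=mode,
    )
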