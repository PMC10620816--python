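"""Translational-regulation filter over paired proteomics/transcriptomics.

A gene is called *translationally down* when its protein level drops in
the knockdown (median-centered log2 H/L ratio at or below a cutoff,
default -1, i.e. a two-fold drop) while its transcript is unchanged
(|log2 fold-change| at or below a cutoff, default 0.585 ~ 1.5-fold, and,
when an adjusted p-value is available, adj_p >= 0.05 — i.e. *not*
significantly changed). Genes with protein evidence but no transcript
entry are excluded, not assumed unchanged.

Quantitative proteomics H/L ratios are median-centered on the log2 scale
(equivalent to shifting the median H/L ratio to 1) before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TranslationalFilterConfig",
    "median_center",
    "translationally_down",
    "read_omics_tables",
]


@dataclass(frozen=True)
class TranslationalFilterConfig:
    protein_down_log2_max: float = -1.0
    mrna_unchanged_abs_log2_max: float = 0.585
    mrna_unchanged_min_adj_p: float = 0.05

    def __post_init__(self):
        for name in (
            "protein_down_log2_max",
            "mrna_unchanged_abs_log2_max",
            "mrna_unchanged_min_adj_p",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.protein_down_log2_max >= 0:
            raise ValueError("protein_down_log2_max must be negative")


def median_center(ratios: pd.Series) -> pd.Series:
    """log2-transform positive H/L ratios and shift so the median is 0."""
    ratios = pd.Series(ratios, dtype=float)
    bad = ratios.index[~(ratios > 0) | ~np.isfinite(ratios)]
    if len(bad):
        raise ValueError(f"non-positive H/L ratio for gene {bad[0]!r}")
    logged = np.log2(ratios)
    return logged - logged.median()


def read_omics_tables(
    proteins_path: str | Path, mrna_path: str | Path
) -> pd.DataFrame:
    """Merge a proteomics TSV (`gene_id` + `hl_ratio` or
    `protein_log2_ratio`) with a transcript DE TSV
    (`gene_id, log2_fc[, adj_p]`) into one record table.

    Raw H/L ratios are median-centered; pre-logged ratios are taken as-is.
    Genes missing from the transcript table keep NaN mRNA fields and are
    excluded downstream with an explicit reason.
    """
    prot = pd.read_csv(proteins_path, sep="\t", comment="#")
    if "gene_id" not in prot.columns:
        raise ValueError("proteomics TSV needs a 'gene_id' column")
    if prot["gene_id"].duplicated().any():
        dup = prot["gene_id"][prot["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id in proteomics table: {dup!r}")
    prot = prot.set_index("gene_id")
    if "protein_log2_ratio" in prot.columns:
        protein_log2 = prot["protein_log2_ratio"].astype(float)
    elif "hl_ratio" in prot.columns:
        protein_log2 = median_center(prot["hl_ratio"])
    else:
        raise ValueError("proteomics TSV needs 'hl_ratio' or 'protein_log2_ratio'")

    mrna = pd.read_csv(mrna_path, sep="\t", comment="#")
    if "gene_id" not in mrna.columns or "log2_fc" not in mrna.columns:
        raise ValueError("mRNA TSV needs 'gene_id' and 'log2_fc' columns")
    mrna = mrna.set_index("gene_id")

    table = pd.DataFrame({"protein_log2_ratio": protein_log2})
    table["mrna_log2_fc"] = mrna["log2_fc"].reindex(table.index)
    table["mrna_adj_p"] = (
        mrna["adj_p"].reindex(table.index) if "adj_p" in mrna.columns else np.nan
    )
    return table


def translationally_down(
    table: pd.DataFrame, config: TranslationalFilterConfig | None = None
) -> tuple[set[str], pd.DataFrame]:
    """Apply the translational filter to a merged omics table.

    ``table`` is indexed by gene_id with columns ``protein_log2_ratio,
    mrna_log2_fc`` and optional ``mrna_adj_p``. Returns the included gene
    set and a per-gene audit frame with ``included`` and ``reason``.
    """
    config = config or TranslationalFilterConfig()
    required = {"protein_log2_ratio", "mrna_log2_fc"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"omics table missing columns: {sorted(missing)}")
    out = table.copy()
    if "mrna_adj_p" not in out.columns:
        out["mrna_adj_p"] = np.nan

    included = []
    reasons = []
    for gene, row in out.iterrows():
        why = []
        protein = row["protein_log2_ratio"]
        if not np.isfinite(protein):
            why.append("no protein measurement")
        elif not protein <= config.protein_down_log2_max:
            why.append(
                f"protein log2 {protein:.3g} > {config.protein_down_log2_max}"
            )
        fc = row["mrna_log2_fc"]
        if not np.isfinite(fc):
            why.append("no transcript evidence")
        else:
            if not abs(fc) <= config.mrna_unchanged_abs_log2_max:
                why.append(
                    f"|mRNA log2FC| {abs(fc):.3g} > {config.mrna_unchanged_abs_log2_max}"
                )
            adj_p = row["mrna_adj_p"]
            if np.isfinite(adj_p) and not adj_p >= config.mrna_unchanged_min_adj_p:
                why.append(
                    f"mRNA adj_p {adj_p:.3g} < {config.mrna_unchanged_min_adj_p}"
                )
        included.append(not why)
        reasons.append("" if not why else "; ".join(why))
    out["included"] = included
    out["reason"] = reasons
    genes = set(out.index[out["included"]])
    return genes, out
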