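"""Differential nucleocytoplasmic distribution of tRNA isodecoders.

Given per-isodecoder counts in nucleus and cytoplasm under a control and a
knockdown condition, each compartment-condition column is normalized to
counts per million (with a pseudocount), the nucleus/cytoplasm quotient is
formed within each condition, and the knockdown quotient is contrasted
against the control quotient:

    ratio = (N/C)_knockdown / (N/C)_control

A ratio above 1 means the tRNA is retained in the nucleus after knockdown
of the exporter. Isodecoders are ranked by descending ratio; the top-ranked
ones are the export-dependent candidates.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COUNT_COLUMNS",
    "read_counts_tsv",
    "load_published_ratios",
    "normalize_counts",
    "distribution_ratio",
    "rank_ratios",
    "select_candidates",
]

#: Required columns of a compartment count table, in canonical order.
COUNT_COLUMNS = (
    "nucleus_control",
    "cytoplasm_control",
    "nucleus_knockdown",
    "cytoplasm_knockdown",
)


def _validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    table = table.copy()
    for col in COUNT_COLUMNS:
        values = pd.to_numeric(table[col], errors="raise")
        if values.isna().any():
            bad = table.index[values.isna()][0]
            raise ValueError(f"missing {col} count for row {bad!r}")
        if (values < 0).any():
            bad = table.index[values < 0][0]
            raise ValueError(f"negative {col} count for row {bad!r}")
        table[col] = values.astype(float)
    return table


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a `trna_id` + four-count-column TSV into a validated table.

    Replicate columns such as ``nucleus_control_rep2`` are summed into their
    base column with a warning (no replicate-aware test is computed).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "trna_id" not in df.columns:
        raise ValueError("counts TSV must have a 'trna_id' column")
    df = df.set_index("trna_id")
    for base in COUNT_COLUMNS:
        reps = [c for c in df.columns if c.startswith(base + "_")]
        if reps:
            warnings.warn(
                f"summing replicate columns {reps} into {base!r}", stacklevel=2
            )
            df[base] = df.reindex(columns=[base] + reps).fillna(0).sum(axis=1)
            df = df.drop(columns=reps)
    return _validate_counts(df)


def load_published_ratios() -> pd.DataFrame:
    """The packaged 14-row differential-distribution fixture: published
    nucleocytoplasmic ratio per isodecoder, indexed by tRNA name."""
    with resources.files("trnaflux.data").joinpath("published_ratios.tsv").open() as handle:
        df = pd.read_csv(handle, sep="\t", comment="#")
    return df.set_index("trna_id")


def normalize_counts(
    table: pd.DataFrame,
    pseudocount: float = 0.5,
    library_sizes: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Counts-per-million normalization per compartment-condition column.

    Each count becomes ``(count + pseudocount) / library_size * 1e6``; the
    library size defaults to the raw column sum. The pseudocount guards the
    downstream quotients against zero counts.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    table = _validate_counts(table)
    out = table.copy()
    for col in COUNT_COLUMNS:
        lib = float(library_sizes[col]) if library_sizes else float(table[col].sum())
        if lib <= 0:
            raise ValueError(f"library size for {col!r} must be positive, got {lib}")
        out[col] = (table[col] + pseudocount) / lib * 1e6
    return out


def rank_ratios(ratios: pd.Series) -> pd.DataFrame:
    """Rank a ratio series descending; ties broken lexicographically by id.

    Ranks are the permutation 1..n.
    """
    order = sorted(ratios.index, key=lambda name: (-ratios[name], name))
    ranked = pd.DataFrame({"ratio": ratios.reindex(order)})
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked.index.name = "trna_id"
    return ranked


def distribution_ratio(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-isodecoder N/C quotients and their knockdown-vs-control contrast.

    Input must already be normalized with strictly positive values (use
    :func:`normalize_counts` with a positive pseudocount). Returns a frame
    with ``nc_control, nc_knockdown, ratio, rank`` sorted by rank.
    """
    table = _validate_counts(normalized)
    if (table[list(COUNT_COLUMNS)] <= 0).any().any():
        bad = table.index[(table[list(COUNT_COLUMNS)] <= 0).any(axis=1)][0]
        raise ValueError(
            f"normalized counts must be strictly positive (row {bad!r}); "
            "normalize with a positive pseudocount first"
        )
    nc_control = table["nucleus_control"] / table["cytoplasm_control"]
    nc_knockdown = table["nucleus_knockdown"] / table["cytoplasm_knockdown"]
    ratio = nc_knockdown / nc_control
    ranked = rank_ratios(ratio)
    ranked.insert(0, "nc_control", nc_control.reindex(ranked.index))
    ranked.insert(1, "nc_knockdown", nc_knockdown.reindex(ranked.index))
    return ranked


def select_candidates(
    results: pd.DataFrame,
    top_k: int | None = None,
    threshold: float | None = None,
) -> list[str]:
    """Top-k isodecoder names by rank, or all names with ratio >= threshold.

    Exactly one of ``top_k`` / ``threshold`` must be given.
    """
    if results.empty:
        raise ValueError("empty results table")
    if (top_k is None) == (threshold is None):
        raise ValueError("specify exactly one of top_k or threshold")
    if "ratio" not in results.columns:
        raise ValueError("results table lacks a 'ratio' column")
    if "rank" in results.columns:
        ordered = results.sort_values("rank")
    else:
        ordered = rank_ratios(results["ratio"])
    if top_k is not None:
        if not 0 < top_k <= len(ordered):
            raise ValueError(f"top_k={top_k} out of range for {len(ordered)} rows")
        return list(ordered.index[:top_k])
    return list(ordered.index[ordered["ratio"] >= threshold])


def write_ratio_tsv(results: pd.DataFrame, path: str | Path, *, params: dict | None = None) -> None:
    """Write the ranked table with a leading parameter comment line."""
    with open(path, "w") as handle:
        if params:
            handle.write("# " + " ".join(f"{k}={v}" for k, v in sorted(params.items())) + "\n")
        results.to_csv(handle, sep="\t")
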