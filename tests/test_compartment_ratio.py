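"""Nucleocytoplasmic ratio statistic, normalization and candidate selection."""

import numpy as np
import pandas as pd
import pytest

from trnaflux import (
    distribution_ratio,
    normalize_counts,
    rank_ratios,
    read_counts_tsv,
    select_candidates,
)
from trnaflux.compartment_ratio import COUNT_COLUMNS


def _table(rows: dict[str, tuple[float, float, float, float]]) -> pd.DataFrame:
    # values ordered (N_ctrl, C_ctrl, N_kd, C_kd)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(COUNT_COLUMNS)
    ).rename_axis("trna_id")


def test_cpm_normalization_identity_scale():
    table = _table({"tRNA-Ala-AGC-1-1": (100, 100, 100, 100)})
    out = normalize_counts(table, pseudocount=0.0, library_sizes={c: 1e6 for c in COUNT_COLUMNS})
    assert float(out.iloc[0, 0]) == 100.0


def test_cpm_pseudocount_floors_zero_counts():
    table = _table({"tRNA-Ala-AGC-1-1": (0, 0, 0, 0)})
    out = normalize_counts(table, pseudocount=0.5, library_sizes={c: 1e6 for c in COUNT_COLUMNS})
    assert (out == 0.5).all().all()


def test_cpm_column_mass(random_counts):
    """Column sums match the arithmetic oracle sum((c+p)/L*1e6)."""
    out = normalize_counts(random_counts, pseudocount=0.5)
    for col in COUNT_COLUMNS:
        lib = random_counts[col].sum()
        expected = ((random_counts[col] + 0.5) / lib * 1e6).sum()
        assert np.isclose(out[col].sum(), expected)


def test_zero_library_size_is_an_error():
    table = _table({"tRNA-Ala-AGC-1-1": (1, 1, 1, 1)})
    with pytest.raises(ValueError, match="library size"):
        normalize_counts(table, library_sizes={c: 0.0 for c in COUNT_COLUMNS})


def test_ratio_simple_contrast():
    table = _table({"tRNA-Ala-AGC-1-1": (100, 100, 200, 100)})
    result = distribution_ratio(table)
    assert result["ratio"].iloc[0] == pytest.approx(2.0)


def test_ratio_is_one_under_the_null(random_counts):
    null = random_counts.copy()
    null["nucleus_knockdown"] = null["nucleus_control"]
    null["cytoplasm_knockdown"] = null["cytoplasm_control"]
    result = distribution_ratio(null)
    assert np.allclose(result["ratio"], 1.0)


def test_ratio_matches_brute_force_oracle(random_counts):
    result = distribution_ratio(random_counts)
    for name in random_counts.index:
        row = random_counts.loc[name]
        nc_ctrl = row["nucleus_control"] / row["cytoplasm_control"]
        nc_kd = row["nucleus_knockdown"] / row["cytoplasm_knockdown"]
        assert result.loc[name, "ratio"] == pytest.approx(nc_kd / nc_ctrl)
        assert result.loc[name, "nc_control"] == pytest.approx(nc_ctrl)
        assert result.loc[name, "nc_knockdown"] == pytest.approx(nc_kd)


def test_ratio_invariant_to_per_column_scaling(random_counts):
    base = distribution_ratio(normalize_counts(random_counts, pseudocount=0.0))
    scaled_counts = random_counts.copy()
    for col, factor in zip(COUNT_COLUMNS, (3.0, 0.5, 10.0, 7.0)):
        scaled_counts[col] = scaled_counts[col] * factor
    scaled = distribution_ratio(normalize_counts(scaled_counts, pseudocount=0.0))
    assert np.allclose(base["ratio"], scaled["ratio"].reindex(base.index))


def test_condition_swap_inverts_every_ratio(random_counts):
    swapped = random_counts.rename(
        columns={
            "nucleus_control": "nucleus_knockdown",
            "nucleus_knockdown": "nucleus_control",
            "cytoplasm_control": "cytoplasm_knockdown",
            "cytoplasm_knockdown": "cytoplasm_control",
        }
    )
    forward = distribution_ratio(random_counts)["ratio"]
    backward = distribution_ratio(swapped)["ratio"]
    assert np.allclose(forward * backward.reindex(forward.index), 1.0)


def test_ranks_are_a_permutation_with_lexicographic_ties():
    ratios = pd.Series(
        {"tRNA-B": 2.0, "tRNA-A": 2.0, "tRNA-C": 1.0}, name="ratio"
    )
    ranked = rank_ratios(ratios)
    assert list(ranked.index) == ["tRNA-A", "tRNA-B", "tRNA-C"]
    assert list(ranked["rank"]) == [1, 2, 3]


def test_published_ranking_reproduces_printed_order(published_ratios):
    ranked = rank_ratios(published_ratios["ratio"])
    assert list(ranked.index) == list(published_ratios.index)
    assert select_candidates(ranked, top_k=2) == [
        "tRNA-Thr-AGT-3-1",
        "tRNA-Ala-AGC-10-1",
    ]


def test_select_candidates_bounds_and_threshold(published_ratios):
    ranked = rank_ratios(published_ratios["ratio"])
    assert select_candidates(ranked, top_k=len(ranked)) == list(ranked.index)
    with pytest.raises(ValueError):
        select_candidates(ranked, top_k=len(ranked) + 1)
    with pytest.raises(ValueError):
        select_candidates(ranked, top_k=2, threshold=1.0)
    assert select_candidates(ranked, threshold=ranked["ratio"].max() + 1) == []
    assert select_candidates(ranked, threshold=2.0) == ["tRNA-Thr-AGT-3-1"]


def test_missing_count_column_is_an_error(random_counts):
    with pytest.raises(ValueError, match="missing columns"):
        distribution_ratio(random_counts.drop(columns=["nucleus_control"]))


def test_replicate_columns_are_summed_with_warning(tmp_path, random_counts):
    df = random_counts.reset_index()
    df["nucleus_control_rep2"] = 10
    path = tmp_path / "counts.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.warns(UserWarning, match="replicate"):
        table = read_counts_tsv(path)
    assert np.allclose(
        table["nucleus_control"], random_counts["nucleus_control"] + 10
    )
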