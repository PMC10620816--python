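"""Codon counting, scoring and the enrichment screen."""

from collections import Counter
from importlib import resources

import numpy as np
import pytest

from trnaflux import (
    CodingSequenceRecord,
    EnrichmentCriteria,
    count_codons,
    criteria_for_anticodon,
    is_enriched,
    read_cds_fasta,
    scan_cds_set,
    simulate_cds_set,
)
from trnaflux.synthetic import SENSE_CODONS


def naive_codon_counts(cds: str) -> Counter:
    """Independent oracle: step-by-3 slicing with an explicit stop check."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] in {"TAA", "TAG", "TGA"}:
        codons.pop()
    return Counter(codons)


def test_count_codons_trivial_examples():
    profile = count_codons(CodingSequenceRecord("g1", "GCTGCCGCA"))
    assert profile.counts["GCT"] == profile.counts["GCC"] == profile.counts["GCA"] == 1
    assert profile.total_codons == 3
    assert profile.score["GCT"] == pytest.approx(1 / 3)

    stop_trimmed = count_codons(CodingSequenceRecord("g2", "GCTGCTTAA"))
    assert stop_trimmed.counts["GCT"] == 2
    assert stop_trimmed.total_codons == 2


def test_count_codons_errors_name_the_gene():
    with pytest.raises(ValueError, match="badgene"):
        count_codons(CodingSequenceRecord("badgene", "GCTG"))
    with pytest.raises(ValueError, match="ambiguous"):
        CodingSequenceRecord("nngene", "GCNGCT")


def test_internal_stop_warns_but_counts():
    with pytest.warns(UserWarning, match="internal stop"):
        profile = count_codons(CodingSequenceRecord("g", "GCTTAAGCT"))
    assert profile.total_codons == 3


def test_count_codons_matches_naive_oracle_on_random_cds(rng):
    """Oracle equivalence on 1000 random CDSs (random sense codons plus a
    random stop fate)."""
    stops = ["TAA", "TAG", "TGA"]
    for _ in range(1000):
        n = int(rng.integers(10, 200))
        body = "".join(rng.choice(SENSE_CODONS, size=n))
        if rng.random() < 0.5:
            body += stops[int(rng.integers(3))]
        profile = count_codons(CodingSequenceRecord("g", body))
        oracle = naive_codon_counts(body)
        assert profile.total_codons == sum(oracle.values())
        for codon, count in oracle.items():
            assert profile.counts[codon] == count
        assert sum(profile.counts.values()) == profile.total_codons


def test_score_and_per_kilobase_conservation(rng):
    body = "".join(rng.choice(SENSE_CODONS, size=300))
    profile = count_codons(CodingSequenceRecord("g", body))
    assert sum(profile.score.values()) == pytest.approx(1.0)
    assert sum(profile.per_kilobase.values()) == pytest.approx(1000 / 3)
    assert profile.per_kilobase["GCT"] == pytest.approx(
        profile.counts["GCT"] / (3 * profile.total_codons) * 1000
    )


def test_frame_shift_changes_counts():
    cds = "GCTGCTGCTAGC"  # in frame: 3x GCT + AGC
    shifted = cds[1:] + "G"  # one-base shift, same length
    in_frame = count_codons(CodingSequenceRecord("g", cds))
    off_frame = count_codons(CodingSequenceRecord("g", shifted))
    assert in_frame.counts != off_frame.counts
    assert in_frame.counts["GCT"] == 3
    assert off_frame.counts["GCT"] == 0


def test_appending_target_codon_never_decreases_its_score(rng):
    body = "".join(rng.choice(SENSE_CODONS, size=50))
    for _ in range(20):
        before = count_codons(CodingSequenceRecord("g", body)).score["GCT"]
        body += "GCT"
        after = count_codons(CodingSequenceRecord("g", body)).score["GCT"]
        assert after >= before


def test_is_enriched_infinity_and_strictness():
    criteria = criteria_for_anticodon("AGC")
    assert criteria.target_codon == "GCT"
    assert criteria.comparison_codons == {"GCC", "GCA"}

    all_target, reasons = is_enriched(
        count_codons(CodingSequenceRecord("g", "GCTGCT")), criteria
    )
    assert all_target and not reasons  # zero-count comparisons pass (+inf)

    equal, reasons = is_enriched(
        count_codons(CodingSequenceRecord("g", "GCTGCCGCA")), criteria
    )
    assert not equal  # ratio exactly 1 fails the strict > 1
    assert any("GCC" in r or "GCA" in r for r in reasons)


def test_all_synonymous_flag_adds_gcg():
    criteria = criteria_for_anticodon("AGC", all_synonymous=True)
    assert criteria.comparison_codons == {"GCC", "GCA", "GCG"}


def test_non_synonymous_comparison_codon_is_an_error():
    with pytest.raises(ValueError, match="not synonymous"):
        EnrichmentCriteria(target_codon="GCT", comparison_codons=frozenset({"GGT"}))


def test_scan_picks_the_constructed_heavy_gene(tmp_path):
    fasta = tmp_path / "toy.fa"
    fasta.write_text(
        ">heavy\nGCTGCTGCTGGTTAA\n>light\nGCCGCCGCAGGTTAA\n>neutral\nGGTGGCGGAGGGTAA\n"
    )
    enriched, table = scan_cds_set(fasta, criteria_for_anticodon("AGC"))
    assert enriched == {"heavy"}
    assert table.loc["heavy", "count_GCT"] == 3


def test_scan_recovers_exactly_the_spiked_genes():
    records, truth = simulate_cds_set(n_genes=200, spiked=20, seed=3)
    enriched, table = scan_cds_set(records, criteria_for_anticodon("AGC"))
    assert enriched == set(truth.spiked_genes)
    assert len(table) == 200


def test_scan_decisions_match_independent_filter(rng):
    """Enrichment decisions equal an independently coded threshold filter."""
    records, _ = simulate_cds_set(n_genes=100, spiked=10, seed=5)
    criteria = criteria_for_anticodon("AGC")
    enriched, _ = scan_cds_set(records, criteria)
    for record in records:
        counts = naive_codon_counts(record.cds)
        total = sum(counts.values())
        gct = counts["GCT"] / total
        decision = (
            gct > 0.02
            and gct > counts["GCC"] / total
            and gct > counts["GCA"] / total
        )
        assert decision == (record.gene_id in enriched)


def test_packaged_synthetic_cds_has_13_gct_codons():
    """The packaged demonstration CDS (a synthetic stand-in constructed with
    exactly 13 GCT codons) is counted correctly and passes the screen."""
    path = resources.files("trnaflux.data") / "ttc19_like_synthetic.fa"
    enriched, table = scan_cds_set(str(path), criteria_for_anticodon("AGC"))
    assert table.loc["TTC19_LIKE_SYNTHETIC", "count_GCT"] == 13
    assert "TTC19_LIKE_SYNTHETIC" in enriched


def test_read_cds_fasta_duplicates_keep_longest(tmp_path):
    fasta = tmp_path / "dup.fa"
    fasta.write_text(">g1 short\nGCTTAA\n>g1 long\nGCTGCTGCTTAA\n>g2\nGGTTAA\n")
    records, stats = read_cds_fasta(fasta)
    by_id = {r.gene_id: r for r in records}
    assert len(by_id["g1"].cds) == 12
    assert stats["duplicates_dropped"] == 1


def test_read_cds_fasta_skips_bad_records_and_rejects_empty(tmp_path):
    fasta = tmp_path / "mixed.fa"
    fasta.write_text(">ok\nGCTTAA\n>bad\nGCNNNA\n")
    with pytest.warns(UserWarning, match="skipping"):
        records, stats = read_cds_fasta(fasta)
    assert [r.gene_id for r in records] == ["ok"]
    assert stats["skipped"] == 1

    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(ValueError, match="no FASTA records"):
        read_cds_fasta(empty)
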