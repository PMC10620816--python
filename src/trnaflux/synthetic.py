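"""Synthetic pipeline inputs with known ground truth.

Three generators emulate the statistical shape of the real inputs:

* :func:`simulate_compartment_counts` — negative-binomial sequencing
  counts per isodecoder in nucleus/cytoplasm under control/knockdown,
  with a chosen set of tRNAs given a nuclear-retention effect (their
  knockdown N/C odds are multiplied by ``effect``).
* :func:`simulate_cds_set` — coding sequences whose synonymous-codon
  composition is controlled, with spiked genes satisfying the target
  enrichment criteria in expectation and background genes not.
* :func:`simulate_omics` — median-centerable H/L protein ratios and mRNA
  fold-changes with a spiked translational-repression effect, plus
  transcriptionally co-regulated decoy genes the filter must reject.
  mRNA adjusted p-values are Benjamini-Hochberg adjusted z-test p-values,
  so null genes carry high adj_p as in real differential-expression output.

All randomness flows from one integer seed through
``numpy.random.SeedSequence``; per-stage streams are spawned
deterministically, so identical seeds give byte-identical files.
:func:`simulate_all` wires the three together with exactly one gene spiked
in all three dimensions, which a correct end-to-end run must nominate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .codon_usage import CodingSequenceRecord
from .trna_names import _CODON_TABLE, reverse_complement

__all__ = [
    "SyntheticTruth",
    "simulate_compartment_counts",
    "simulate_cds_set",
    "simulate_omics",
    "simulate_functional_list",
    "simulate_all",
]

SENSE_CODONS = tuple(sorted(c for c, aa in _CODON_TABLE.items() if aa != "*"))

#: Background synonymous-codon fractions for the default GCT spike-in
#: design: a deliberately GCC-preferring alanine background so null genes
#: sit clearly below the enrichment criteria.
DEFAULT_BACKGROUND_FRACTIONS = {"GCT": 0.008, "GCC": 0.030, "GCA": 0.020, "GCG": 0.012}
#: Spiked-gene fractions: GCT at 5% of codons with rare GCC/GCA, so the
#: score threshold (0.02) and both ratio clauses hold in expectation.
DEFAULT_SPIKED_FRACTIONS = {"GCT": 0.05, "GCC": 0.01, "GCA": 0.01, "GCG": 0.005}


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: what was spiked and how."""

    seed: int
    spiked_trnas: dict[str, float] = field(default_factory=dict)
    spiked_genes: dict[str, dict] = field(default_factory=dict)
    n_trnas: int = 0
    n_genes: int = 0
    noise_model: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def default_trna_names(n: int, *, include: tuple[str, ...] = ()) -> list[str]:
    """Deterministic GtRNAdb-style names, one per sense anticodon then
    incrementing family indices; any ``include`` names are placed first."""
    anticodons = [reverse_complement(c) for c in SENSE_CODONS]
    names = list(include)
    family = 1
    while len(names) < n:
        for anticodon in anticodons:
            aa = _CODON_TABLE[reverse_complement(anticodon)]
            name = f"tRNA-{aa}-{anticodon}-{family}-1"
            if name not in names:
                names.append(name)
            if len(names) == n:
                break
        family += 1
    return names[:n]


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB counts with var = mu + dispersion * mu^2 (Poisson when 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_compartment_counts(
    n_trnas: int = 50,
    spiked: tuple[str, ...] | int = 2,
    effect: float = 2.0,
    depth: float = 1e5,
    dispersion: float = 0.002,
    nuclear_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Compartment count table with a nuclear-retention spike-in.

    Background tRNAs keep the same expected N/C odds across conditions;
    spiked tRNAs have their knockdown N/C odds multiplied by ``effect``
    (>1 = retention). ``spiked`` is a count (the first k names are spiked,
    led by tRNA-Ala-AGC-10-1) or an explicit tuple of names. Counts are
    negative-binomial around expectations at sequencing depth ``depth``
    per compartment-condition library.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if isinstance(spiked, int):
        n_spiked = spiked
        names = default_trna_names(n_trnas, include=("tRNA-Ala-AGC-10-1",))
        spiked_names = tuple(names[:n_spiked])
    else:
        spiked_names = tuple(spiked)
        names = default_trna_names(n_trnas, include=spiked_names)
    if not set(spiked_names) <= set(names):
        raise ValueError("spiked set is not a subset of the tRNA names")
    if effect < 1 and spiked_names:
        raise ValueError(
            "retention effect must be >= 1 (1 is the null, >1 nuclear retention)"
        )

    rng_w, rng_counts = _rngs(seed, 2)
    weights = rng_w.dirichlet(np.full(n_trnas, 5.0))
    f = np.full(n_trnas, nuclear_fraction)
    odds = f / (1 - f)
    spiked_mask = np.isin(names, spiked_names)
    odds_kd = np.where(spiked_mask, odds * effect, odds)
    f_kd = odds_kd / (1 + odds_kd)

    mu = {
        "nucleus_control": depth * weights * f,
        "cytoplasm_control": depth * weights * (1 - f),
        "nucleus_knockdown": depth * weights * f_kd,
        "cytoplasm_knockdown": depth * weights * (1 - f_kd),
    }
    table = pd.DataFrame(
        {col: _negative_binomial(rng_counts, m, dispersion) for col, m in mu.items()},
        index=pd.Index(names, name="trna_id"),
    )
    truth = SyntheticTruth(
        seed=seed,
        spiked_trnas={name: effect for name in spiked_names},
        n_trnas=n_trnas,
        noise_model={
            "counts": "negative binomial",
            "dispersion": dispersion,
            "depth": depth,
            "nuclear_fraction": nuclear_fraction,
        },
    )
    return table, truth


def _codon_probabilities(fractions: dict[str, float]) -> np.ndarray:
    """Probability vector over the 61 sense codons: fixed fractions for the
    listed codons, remaining mass uniform over the rest."""
    fixed = sum(fractions.values())
    if not 0 <= fixed < 1:
        raise ValueError(f"infeasible codon composition (sum {fixed})")
    others = [c for c in SENSE_CODONS if c not in fractions]
    p = np.array(
        [fractions.get(c, (1 - fixed) / len(others)) for c in SENSE_CODONS]
    )
    return p / p.sum()


def simulate_cds_set(
    n_genes: int = 200,
    spiked: tuple[str, ...] | int = 20,
    spiked_fractions: dict[str, float] | None = None,
    background_fractions: dict[str, float] | None = None,
    length_range: tuple[int, int] = (300, 1500),
    seed: int = 0,
    gene_names: list[str] | None = None,
) -> tuple[list[CodingSequenceRecord], SyntheticTruth]:
    """CDS set with controlled synonymous-codon composition.

    Each CDS starts with ATG, draws its remaining codons i.i.d. from the
    gene's composition (sense codons only, so no internal stops) and ends
    with a TAA stop. Lengths are uniform over ``length_range`` codons.
    """
    spiked_fractions = dict(spiked_fractions or DEFAULT_SPIKED_FRACTIONS)
    background_fractions = dict(background_fractions or DEFAULT_BACKGROUND_FRACTIONS)
    if gene_names is None:
        gene_names = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    if isinstance(spiked, int):
        spiked_names = tuple(gene_names[:spiked])
    else:
        spiked_names = tuple(spiked)
        if not set(spiked_names) <= set(gene_names):
            raise ValueError("spiked set is not a subset of the gene names")

    p_spiked = _codon_probabilities(spiked_fractions)
    p_background = _codon_probabilities(background_fractions)
    (rng,) = _rngs(seed, 1)
    codon_array = np.array(SENSE_CODONS)
    records = []
    for name in gene_names:
        n_codons = int(rng.integers(length_range[0], length_range[1] + 1))
        p = p_spiked if name in spiked_names else p_background
        body = codon_array[rng.choice(len(codon_array), size=n_codons - 1, p=p)]
        cds = "ATG" + "".join(body) + "TAA"
        records.append(CodingSequenceRecord(gene_id=name, cds=cds))
    truth = SyntheticTruth(
        seed=seed,
        spiked_genes={
            name: {"codon_fractions": spiked_fractions} for name in spiked_names
        },
        n_genes=n_genes,
        noise_model={
            "codon_sampling": "iid sense codons",
            "background_fractions": background_fractions,
            "length_range_codons": list(length_range),
        },
    )
    return records, truth


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def simulate_omics(
    n_genes: int = 200,
    spiked: tuple[str, ...] | int = 30,
    effect: float = -2.0,
    sd: float = 0.2,
    mrna_sd: float = 0.1,
    transcriptional: tuple[str, ...] | int = 10,
    seed: int = 0,
    gene_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Paired proteomics/transcriptomics tables with spiked repression.

    Spiked genes: protein log2 ratio ~ Normal(effect, sd) with unchanged
    mRNA (fc ~ Normal(0, mrna_sd)). ``transcriptional`` genes are decoys
    whose protein *and* mRNA both carry the effect — the filter must
    exclude them. Returns (proteomics table with `hl_ratio`, mRNA table
    with `log2_fc, adj_p`, truth).
    """
    if sd < 0 or mrna_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if gene_names is None:
        gene_names = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    if isinstance(spiked, int):
        spiked_names = tuple(gene_names[:spiked])
    else:
        spiked_names = tuple(spiked)
    if isinstance(transcriptional, int):
        pool = [g for g in gene_names if g not in spiked_names]
        decoy_names = tuple(pool[:transcriptional])
    else:
        decoy_names = tuple(transcriptional)
    if set(spiked_names) & set(decoy_names):
        raise ValueError("spiked and transcriptional decoy sets must be disjoint")

    (rng,) = _rngs(seed, 1)
    names = np.array(gene_names)
    spiked_mask = np.isin(names, spiked_names)
    decoy_mask = np.isin(names, decoy_names)

    protein_log2 = rng.normal(0.0, sd, n_genes)
    protein_log2[spiked_mask | decoy_mask] += effect
    protein_log2 -= np.median(protein_log2)  # emit median-centered, as real H/L tables are
    mrna_fc = rng.normal(0.0, mrna_sd, n_genes)
    mrna_fc[decoy_mask] += effect
    if mrna_sd > 0:
        raw_p = 2 * norm.sf(np.abs(mrna_fc) / mrna_sd)
    else:
        raw_p = np.where(mrna_fc == 0, 1.0, 0.0)
    adj_p = _benjamini_hochberg(raw_p)

    proteins = pd.DataFrame(
        {"gene_id": names, "hl_ratio": np.exp2(protein_log2)}
    ).set_index("gene_id")
    mrna = pd.DataFrame(
        {"gene_id": names, "log2_fc": mrna_fc, "adj_p": adj_p}
    ).set_index("gene_id")
    truth = SyntheticTruth(
        seed=seed,
        spiked_genes={
            **{g: {"protein_log2_effect": effect} for g in spiked_names},
            **{
                g: {"protein_log2_effect": effect, "mrna_log2_effect": effect}
                for g in decoy_names
            },
        },
        n_genes=n_genes,
        noise_model={
            "protein_log2_sd": sd,
            "mrna_log2_sd": mrna_sd,
            "adj_p": "Benjamini-Hochberg over z-test p-values",
        },
    )
    return proteins, mrna, truth


def simulate_functional_list(
    gene_names: list[str],
    must_include: tuple[str, ...],
    n: int = 80,
    seed: int = 0,
) -> list[str]:
    """A functional gene list of size ``n`` containing ``must_include``,
    padded with deterministically sampled other genes."""
    if n > len(gene_names):
        raise ValueError("functional list larger than gene universe")
    (rng,) = _rngs(seed, 1)
    chosen = list(must_include)
    pool = [g for g in gene_names if g not in chosen]
    extra = rng.choice(len(pool), size=n - len(chosen), replace=False)
    chosen += [pool[i] for i in sorted(extra)]
    return chosen


def simulate_all(
    outdir: str | Path | None = None,
    seed: int = 0,
    n_trnas: int = 50,
    n_genes: int = 200,
    retention_effect: float = 2.0,
    depth: float = 1e5,
    dispersion: float = 0.002,
    repression_effect: float = -2.0,
    protein_sd: float = 0.2,
) -> dict:
    """The "paper-like" preset: all pipeline inputs from one seed.

    Exactly one gene (the first, GENE0001) is spiked in all three
    dimensions — codon-enriched, translationally repressed, and on the
    functional list — while the other spiked sets are kept disjoint from
    each other, so a correct end-to-end run nominates exactly that gene.
    The retained tRNA is tRNA-Ala-AGC-10-1, whose cognate codon GCT is
    the enrichment target. When ``outdir`` is given, writes counts.tsv,
    cds.fa, proteins.tsv, mrna.tsv, functional.txt and truth.json.
    """
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(4)]
    gene_names = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    star = gene_names[0]
    codon_spiked = tuple([star] + gene_names[1:20])
    translational_spiked = tuple([star] + gene_names[20:49])
    functional_pool = [star] + gene_names[49:128]

    counts, trna_truth = simulate_compartment_counts(
        n_trnas=n_trnas,
        spiked=("tRNA-Ala-AGC-10-1",),
        effect=retention_effect,
        depth=depth,
        dispersion=dispersion,
        seed=seeds[0],
    )
    cds_records, cds_truth = simulate_cds_set(
        n_genes=n_genes, spiked=codon_spiked, seed=seeds[1], gene_names=gene_names
    )
    proteins, mrna, omics_truth = simulate_omics(
        n_genes=n_genes,
        spiked=translational_spiked,
        effect=repression_effect,
        sd=protein_sd,
        seed=seeds[2],
        gene_names=gene_names,
    )
    functional = simulate_functional_list(
        gene_names, must_include=tuple(functional_pool), n=80, seed=seeds[3]
    )

    truth = SyntheticTruth(
        seed=seed,
        spiked_trnas=trna_truth.spiked_trnas,
        spiked_genes={
            star: {
                "fully_spiked": True,
                "codon": cds_truth.spiked_genes[star],
                "omics": omics_truth.spiked_genes[star],
            },
            **{
                g: {"codon": v}
                for g, v in cds_truth.spiked_genes.items()
                if g != star
            },
            **{
                g: {"omics": v}
                for g, v in omics_truth.spiked_genes.items()
                if g != star
            },
        },
        n_trnas=n_trnas,
        n_genes=n_genes,
        noise_model={
            "counts": trna_truth.noise_model,
            "cds": cds_truth.noise_model,
            "omics": omics_truth.noise_model,
        },
    )
    artifacts = {
        "counts": counts,
        "cds_records": cds_records,
        "proteins": proteins,
        "mrna": mrna,
        "functional": functional,
        "truth": truth,
        "fully_spiked_gene": star,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts.to_csv(outdir / "counts.tsv", sep="\t")
        with open(outdir / "cds.fa", "w") as handle:
            for record in cds_records:
                handle.write(f">{record.gene_id}\n")
                for i in range(0, len(record.cds), 60):
                    handle.write(record.cds[i : i + 60] + "\n")
        proteins.to_csv(outdir / "proteins.tsv", sep="\t")
        mrna.to_csv(outdir / "mrna.tsv", sep="\t")
        (outdir / "functional.txt").write_text("\n".join(functional) + "\n")
        truth.to_json(outdir / "truth.json")
        artifacts["outdir"] = outdir
    return artifacts
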