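# Methods

## The inference chain

The pipeline connects three independent lines of evidence to nominate a
gene whose translation depends on the nuclear export of one specific tRNA:

1. a tRNA whose nucleocytoplasmic distribution shifts toward the nucleus
   when the exporter is depleted,
2. genes whose coding sequences are enriched for that tRNA's cognate
   codon, and
3. genes whose protein level drops while their mRNA is unchanged.

Each stage is a pure function over explicit tables, and the runner only
sequences them, so every intermediate can be audited.

## Distribution ratio statistic

For isodecoder *i* with counts N (nucleus) and C (cytoplasm) under
control and knockdown,

    R_i = (N_i/C_i)_kd / (N_i/C_i)_ctrl

computed on counts-per-million-normalized values. The contrast form is
used (rather than a single-condition N/C) because values near 1 describe
tRNAs whose distribution is *unchanged* between conditions, which is how
the low end of the published ranking is characterized. The statistic is
invariant to any per-column (compartment × condition) scaling, so the
unknown upstream library normalization cannot affect the ranking; this
invariance is asserted by tests.

* **Pseudocount** (default 0.5, configurable): added to every count
  before normalization so quotients are defined for zero counts. At
  realistic depths it perturbs ratios negligibly.
* **Ranking**: descending by ratio; ties broken lexicographically by
  isodecoder name for deterministic output.
* **Replicates**: no inferential test is computed (none is defined for
  this statistic upstream); replicate columns in the input are summed
  with a warning.

## Anticodon decoding

The cognate codon is the reverse complement of the anticodon (both read
5'→3'). Wobble expansion applies position-34 rules — A34 reads codon
third positions {T,C,A}, G34 {C,T}, T34 {A,G}, C34 {G} — and the result
is intersected with the cognate amino acid's synonymous codon set so
degeneracy never crosses amino-acid identity (AGC → {GCT, GCC, GCA};
CAT → {ATG}). These rules reproduce the AGC→GCR behaviour the analysis
requires; beyond that anticodon they are a documented convention, not a
claim about modified-base pairing chemistry (inosine etc. is out of
scope). Anticodons whose cognate codon is a stop are rejected. RNA input
(U) is canonicalized to DNA (T) everywhere on ingestion.

## Codon-usage screen

`score[c] = counts[c] / total_codons` over in-frame triplets from
position 1, trailing stop excluded (internal stops warn but count —
they usually indicate a frame or annotation problem the audit table
should surface, not silently drop). The enrichment rule is
`score[target] > 0.02` and `score[target]/score[c] > 1` for each
comparison codon, with strict inequalities and a zero-count comparison
treated as ratio +∞ when the target count is positive.

The 0.02 threshold is interpreted on the codon-fraction scale (2% of
codons): a per-kilobase reading of the same cutoff would be implausibly
low (0.02 occurrences per 1000 nt ≈ one codon per 50 genes), so the
per-1000-nucleotides frequency is computed and reported in the audit
table but not thresholded. The default comparison set for an
anticodon-derived screen is the wobble-read set minus the cognate (for
AGC: GCC and GCA); the fourth alanine codon GCG is not read by this
anticodon and is excluded by default, with `all_synonymous=True` to
include it. Duplicate gene ids keep the longest CDS (canonical-transcript
convention); unparseable records are skipped and counted.

## Translational filter

Raw H/L proteomics ratios are log2-transformed and median-centered
(equivalently, the median H/L ratio is shifted to 1). A gene is
translationally down when protein log2 ≤ −1 (two-fold drop) and its
transcript is unchanged: |log2FC| ≤ 0.585 (≈1.5-fold) and, when an
adjusted p-value is present, adj_p ≥ 0.05 (not significantly changed).
These cutoffs are package conventions — the upstream study states the
concept but not numeric thresholds — and are mandatory, echoed verbatim
into every report. Genes with protein evidence but no transcript entry
are excluded with reason "no transcript evidence" (conservative: absence
of evidence is not evidence of an unchanged transcript).

## Nomination

Exact-symbol intersection after case-folding and whitespace stripping; no
alias or ortholog mapping. The report records the three input set sizes,
the intersection, per-nominated-gene provenance rows from the upstream
audit tables, the full parameter snapshot, and the identifiers unique to
each set (where harmonization failures surface). The packaged 80-gene
cytokinesis list is hand-assembled from well-known central-spindle,
contractile-ring and abscission machinery purely as a demonstration
fixture and is labelled non-authoritative; real analyses should supply a
curated list.

## Synonymous recoding

All-to-one replacement of every in-frame target codon (default,
mirroring one-replacement-per-plasmid designs), with an alternating mode
for GC balance. Synonymy is validated against the standard genetic code
and the mutant is re-translated on every call; recoding is idempotent.

## Synthetic data generator

The generator defines the conditions under which the pipeline is tested;
its defaults are fixed study conditions, not tuning knobs.

* **Compartment counts**: 50 isodecoders; per-isodecoder abundance
  weights ~ Dirichlet(5); nuclear fraction 0.3 for all tRNAs in control;
  spiked tRNAs have their knockdown N/C *odds* multiplied by the
  retention effect (default 2.0), so the expected ratio statistic equals
  the effect. Counts are negative-binomial (var = μ + αμ²) at depth 1e5
  per compartment-condition library. The default dispersion α = 0.002 is
  technical-replicate-scale overdispersion: the four libraries are
  fractions of one cell pool, not biological replicates, so only
  fractionation/library noise applies. Biological replicate variability
  (α ≈ 0.01–0.1) would swamp a 2-fold effect in a single contrast —
  which is precisely why the statistic is defined on a paired
  fractionation design.
* **CDS sets**: 200 genes, lengths uniform on 300–1500 codons, codons
  i.i.d. from a per-gene composition (sense codons only → no internal
  stops; ATG prepended, TAA appended). Spiked genes use GCT 5%,
  GCC/GCA 1%, GCG 0.5%; background genes use a GCC-preferring alanine
  profile (GCT 0.8%, GCC 3%, GCA 2%, GCG 1.2%) so null genes sit clearly
  below both the score and ratio clauses. The background is deliberately
  more GCC-biased than the human genomic average (where GCT sits near
  the 2% threshold) so that the spike-recovery tests measure the filter,
  not threshold-edge noise.
* **Omics tables**: protein log2 ratios Normal(0, 0.2) background,
  shifted by −2 for 30 spiked genes; emitted median-centered as real H/L
  tables are. mRNA log2FC Normal(0, 0.1); 10 decoy genes carry the
  effect in *both* protein and mRNA and must be rejected by the filter.
  Adjusted p-values are Benjamini–Hochberg-adjusted z-test p-values
  (null scale = the background mRNA sd): in a mostly-null table BH pushes
  null adj_p toward 1, which matches real differential-expression output
  and is what the filter's adj_p ≥ 0.05 clause assumes. Raw uniform
  p-values would mislabel ~5% of genuinely unchanged transcripts as
  changed by construction.
* **Preset**: one gene (GENE0001) is spiked in all three dimensions; the
  other spiked sets are pairwise disjoint by construction, so exactly
  that gene must be nominated end to end. The retained tRNA is
  tRNA-Ala-AGC-10-1, making GCT the derived target codon.
* **Determinism**: all randomness flows from one integer seed through
  `numpy.random.SeedSequence.spawn`; identical seeds give byte-identical
  output files.

What the generator does **not** emulate: multi-mapping of tRNA-seq reads
across isodecoders, tRNA modification chemistry, codon autocorrelation
along real CDSs, peptide-level proteomics noise, or correlated
mRNA–protein measurement error. Passing tests therefore demonstrate the
correctness and statistical behaviour of the pipeline's computations
under a clean generative model, not performance on raw sequencing or
spectrometry data.

## Worked-example fixture

The packaged `ttc19_like_synthetic.fa` is a synthetic 380-codon CDS
constructed (fixed generator seed) to contain exactly 13 GCT codons with
GCC/GCA/GCG at 5/4/3 — the codon arithmetic of the canonical worked
example, without shipping any third-party sequence. Applying
`count_codons`/`recode_cds` to the real canonical human TTC19 CDS
(obtainable from NCBI/Ensembl) performs the same analysis on the real
gene; the repository deliberately ships no downloaded data.

## Problem sizes and numerical choices

The test suite and the acceptance script use 14-row fixture ranking,
200-gene CDS/omics sets, 1000-CDS counting oracles and 1000-replicate
Monte-Carlo recovery runs — sizes chosen so the whole suite completes in
well under a minute on one CPU while keeping Monte-Carlo standard errors
below one percentage point. Floating-point comparisons use exact
equality only where the arithmetic is exact (fixture passthrough, median
of an odd-length sample); elsewhere tolerances are stated per test.
Degenerate inputs (empty tables, zero library sizes, non-positive
ratios, stop-codon targets) raise structured errors naming the offending
record rather than propagating NaNs.

## Known limitations

* The ratio statistic carries no uncertainty: with unreplicated
  compartment libraries a rank list is all the design supports.
* The wobble table is a convention beyond the AGC case (see above).
* The enrichment screen ignores expression weighting and codon context
  (no tAI/CAI); it is a faithful implementation of a threshold rule, not
  a model of translational efficiency.
* Identifier harmonization is exact-match; cross-annotation symbol drift
  must be resolved upstream.
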