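# Methods

## Library model

The expression cassette is a 174-nt ORF: codon 1 is the start codon
(embedded in a Kozak context), codon 2 a second constant codon, codons
3–52 the 150-nt random region, and codons 53–58 a 6×His tag, flanked by
HindIII and NotI cloning sites with a stop codon between the His tag and
the NotI site. The identity of the second constant codon is not part of
the design arithmetic, only its presence; it is configurable and defaults
to GCC (a high-usage human alanine codon). His codons default to CAC, the
more frequent human histidine codon. ORF extraction anchors on the
constant Kozak/start context and the His-tag/stop context and demands
exactly 174 nt between them; reads failing either anchor are
"unparseable", anchored reads with a wrong-length window are "malformed"
(e.g. synthesis deletions).

Peptide lengths follow a truncated geometric law. Under uniform base
composition a random codon is a stop with probability P = 3/64, so the
first stop lands at random codon k with probability (1−P)^(k−1)·P,
producing a peptide of 2 + (k−1) residues (the two constant codons
translate, the stop truncates). With no stop among the 50 random codons —
probability (61/64)^50 ≈ 0.0907 — translation runs through the His tag to
the full 58 residues. P is exposed as a parameter so biased libraries can
use an empirical per-codon stop probability. The count of possible
peptides of length k is 20^k, computed as an exact integer.

Ambiguous bases (N) exclude a clone rather than being imputed; exclusions
are logged. All frequency outputs (positional nucleotide tables,
amino-acid composition, length masses) are normalized to sum to 1.

## Growth simulation

Fitness is a per-clone selection coefficient s acting multiplicatively
per doubling: over a passage with d doublings the expected frequency
update is f_i → f_i (1+s_i)^d, renormalized. Each passage reseeds a fixed
number of cells drawn multinomially from the updated frequencies — this
is the drift model for the one-fourth carryover bottleneck. Timepoint 1
is the initial seeding; each later timepoint follows one passage, so a
10-timepoint course spans 9 passages. A deterministic mode propagates
expectations exactly and is used for closed-form tests.

Defaults mirror the study design: 5 replicate flasks, 10 timepoints,
carryover 1/4, 3×10^6 cells per flask, d = 2 doublings per two-day
passage (the passaging interval is documented, the doubling count is a
modeling choice and exposed in the configuration), and ~7×10^5 reads per
amplicon sample. The small common-growth pool uses 14 clones, 3
replicates, 5 cycles and 7×10^5 cells.

Amplicon reads are full-length cassettes (constant flanks + ORF) drawn
multinomially from clone frequencies at the configured depth, with
independent per-base substitutions at the configured error rate
(default 0.001). Error positions are drawn with replacement across the
read matrix; coincident draws collapse, a ~10^-4 relative effect at these
rates. Indels, PCR bias and chimeras are not modeled — amplicons are
fixed-length and the mapper is substitution-only by design. Reads are
emitted as Phred+33 FASTQ with a constant quality score, or kept
in-memory as base-index matrices for high-depth runs.

## Barcode counting

The 150-nt insert is the mapping key. Reference building counts distinct
inserts across the first-timepoint samples, ranks them by abundance
(ties broken lexicographically), and walks down the ranking greedily:
a candidate within Hamming distance ≤ `collapse_radius` (default 2) of an
already retained, more abundant center is absorbed into the nearest such
center; otherwise it is retained if its own count reaches `min_count`
(default 2). Mapping assigns each read to the unique nearest reference
insert within `max_mismatch` (default 2); a distance tie leaves the read
unmapped, as does a failed anchor. Candidate centers are found with a
pigeonhole chunk index — a read within m mismatches of a center matches
at least one of m+1 disjoint chunks exactly — so only inexact reads (a
~14% minority at error rate 0.001 over a ~200-nt amplicon) incur any
search at all. Since inserts are positionally fixed in the fixed-length
amplicon, the mapper slices the insert window by position and tolerates
errors in the constant flanks.

## Differential abundance

The test is a deliberately compact re-implementation of the
negative-binomial Wald workflow popularized by DESeq2, reduced to what
the two-condition contrast needs:

- **Size factors** — median-of-ratios: per-clone geometric means over
  samples are computed on clones with all-positive counts; a sample's
  factor is the median ratio to those geometric means. This matches
  pyDESeq2's estimates exactly (cross-checked in the test suite).
- **Dispersion** — method of moments on normalized counts with variance
  pooled within condition, α̂ = max(0, (s²−μ̄)/μ̄²), shrunk halfway
  (configurable weight) toward a fitted trend α(μ) = a₀ + a₁/μ. This
  replaces DESeq2's Cox–Reid/MAP machinery; at the clone counts and
  replicate numbers of this design it yields approximately uniform null
  p-values and realized false-call rates at or under the FDR target
  (both properties are under test).
- **Wald test** — per-clone NB GLM with log link and a condition
  indicator, fitted by IRLS **on the normalized-count scale** rather
  than on raw counts with per-sample offsets. With a two-group design
  and the log link the working weights are equal within each group, so
  the fitted group means are the exact MLE regardless of dispersion, and
  the fit depends on the data only through the normalized matrix: a
  depth change absorbed by the size factors leaves fold changes
  bit-identical, which is the normalization property the pipeline
  guarantees. The cost is that the variance weighting treats samples as
  equally deep, a negligible approximation at the near-uniform depths of
  amplicon time courses. log2FC = b₁/ln 2, two-sided normal p on b₁/SE.
- **FDR and classes** — Benjamini–Hochberg step-up with missing values
  passed through; UP if padj < 0.05 and log2FC > 0, DOWN if padj < 0.05
  and log2FC < 0, else NS (untestable clones default to NS so the three
  groups always partition the clone set). No fold-change shrinkage and
  no outlier filtering are applied.

Pool ranking computes, per replicate, frequency(final cycle)/
frequency(start), averages over replicates, and ranks descending with
lexicographic tie-breaks. Clones with zero final-cycle counts in every
replicate are flagged "failed to grow" and left unranked; zero start
frequencies exclude a clone with a warning.

## Group analysis

Feature distributions per class are compared with the two-sample
Kolmogorov–Smirnov test (asymptotic p with effective sample size, via
scipy). The default background for a group test is the whole library
including the tested group, mirroring the published comparisons of each
class against the full database; exclusive-background and pairwise modes
are provided because the published wording supports either reading.
Quantiles use linear interpolation between order statistics (no
convention is documented for the original analysis); whiskers extend to
the furthest points within 1.5×IQR of the hinges. The aggregation flag is
true at PASTA energy ≤ −5 PEU — inclusive, per the "−5 or less" rule.
PEU and IDS are ingested external predictor scores, never computed.

## Meta-analysis

Spearman correlations use average ranks for ties and the two-tailed
t-approximation p = 2·P(T_{n−2} > |ρ|√((n−2)/(1−ρ²))); this convention
reproduces both published values on the packaged tables (ρ = −0.21,
p ≈ 0.4 over 16 expression/DE-count pairs; ρ = −0.07, p ≈ 0.8 over the
14 ranked clones after dropping the two "n.a." entries pairwise). A
permutation option exists for small n. Foldability boundaries are strict
inequalities (IDS > 0.4 low, < 0.1 high; boundary values are
intermediate). Top-N sets are ordered by log2 fold change (the published
phrase is "highest fold changes"), ties broken by gene identifier and
logged; shortfalls below N take all available genes with a note. The
recurrence matrix keeps genes present in ≥ 2 per-experiment sets, orders
by occurrence count, and flags direction conflicts.

## What the simulator does and does not emulate

The generator reproduces the stated study conditions: ~150-nt random
inserts (optionally with the thymine-up/adenine-down positional bias),
5 replicates × 10 timepoints with 1/4 carryover, substitution-error
amplicon sequencing at configurable depth. It does **not** emulate PCR
amplification bias, chimeras, indels, read-quality structure, culture
heterogeneity (attachment, confluence effects), or expression-level
variation among clones. Passing recovery tests therefore demonstrate
that the statistical pipeline is correct and well calibrated under the
idealized error model — not that real libraries are free of the
unmodeled artifacts. Real-data headline counts (e.g. the published
1,470/1,934/304 class split of 3,708 clones) require the deposited
sequencing data and are out of scope for the synthetic validation.

## Problem sizes and numerical choices

The packaged validation uses a 10^5-clone library for the length-null
and composition checks (binomial 3-sd bounds; the positional table allows
the binomially expected rate of 3-sd excursions across its 600 dependent
cells) and a 2,000-clone, depth-10^6, 5+5-sample experiment for
end-to-end recovery — sizes at which every check completes in about a
minute while sampling error is far below the tested tolerances. IRLS
iterates to 1e-10 on coefficients with a 50-iteration cap;
non-convergent clones are flagged and classified NS. Dispersion trend
fitting is ordinary least squares on 1/μ̄ with coefficients clipped at
zero. The BH implementation enforces monotonicity by running minimum
from the largest p-value. Seeds thread through `numpy.random.Generator`
end to end; a fixed seed reproduces libraries, trajectories and FASTQ
bytes exactly.

## Known limitations

- The dispersion estimator is intentionally simpler than DESeq2's; at
  very low counts (< ~10 per clone per sample) its p-values drift
  conservative. The filter on total clone counts (default 50 across
  samples) keeps the tested regime comfortable.
- Mapping is Hamming-only; an indel in the random region shifts the
  insert window and the read is lost (counted unmapped) rather than
  rescued by alignment.
- The Wald SE ignores depth differences between samples (normalized-scale
  fit); with strongly unbalanced depths a raw-count GLM with offsets
  would weight samples more faithfully.
- The geometric length null assumes independent uniform codons; it takes
  an empirical stop probability for biased libraries but not
  position-dependent stop probabilities.
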