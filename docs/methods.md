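# Methods

## Scope and model

smrnade implements the single-library-per-condition miRNA workflow used in
insect infection studies: five deep small-RNA libraries (one control, four
treatment time points), compared pairwise against the control. There are no
biological replicates, so between-library differences are assessed purely
under sampling (Poisson/negative-binomial) assumptions; biological
variability is not modelled, and calls should be read accordingly.

## Read filtering

Published accounting tables name six removal categories without defining
them. The package fixes the contract (shared with the generator):

| category | rule | default |
|---|---|---|
| low quality | mean Phred < 20 or any `N` | threshold 20 |
| 3′ adapter-null | no exact match of an adapter prefix (≥ 6 nt) | min overlap 6 |
| insert-null | adapter starts at position 0 | — |
| 5′ contaminant | insert starts with a ≥ 8 nt suffix of the 5′ adapter | min overlap 8 |
| shorter than 18 nt | trimmed insert < 18 nt | 18 |
| polyA | ≥ 80 % A in the trimmed insert | 0.80 |

Each read is counted once, in the first matching category, in the order
above (the order the published table prints them). The high-quality total
(after the quality rule) is the 100 % denominator; percentages are rounded
half-up to two decimals, which reproduces every printed percentage of the
packaged five-library table exactly. Adapter matching is exact (longest
adapter prefix, leftmost occurrence, truncation at the read end allowed);
mismatch-tolerant trimming is deliberately out of scope since the synthetic
reads carry exact adapters.

## Exact test

The Audic–Claverie conditional p(y|x) is evaluated in log space with
`scipy.special.gammaln`; the identity with NB(x+1, N₁/(N₁+N₂)) gives the
tails through `scipy.stats.nbinom` cdf/sf, avoiding catastrophic
cancellation for extreme counts. The two-tailed convention is
2·min(lower, upper) capped at 1; with equal totals the pmf is symmetric in
(x, y) but the discrete tail sums are not, so P-values are only
asymptotically symmetric under swapping the libraries — a property of the
definition, not an implementation artifact. The test is discrete and hence
mildly conservative; at Poisson mean 100 the measured null rejection rate
at p < 0.05 is ≈ 0.046.

Normalisation is TPM = 10⁶·count/clean-total. Zero TPMs become 0.01 (so
ratios stay finite); miRNAs under 1 TPM in all libraries are removed before
testing. Bonferroni correction uses m = the number of miRNAs retained in
that pairwise comparison; the output column is labelled `fdr` because
published DE tables conventionally print the adjusted value under that
header even when the method is Bonferroni. Default call thresholds
(adjusted P < 0.05, |log₂FC| ≥ 1) are configurable; the source study does
not state its cutoffs.

## Synthetic data

The generator emulates the structure the analysis assumes, not real
chemistry:

* **Counts.** Each source sequence gets a fixed relative abundance
  (log-normal, σ = 1, so a few sources dominate as in real libraries),
  shared by all libraries; per-library counts are Poisson with mean
  abundance × depth, matching the exact test's sampling model. Planted
  effects multiply one miRNA's mean in one library by 2^log₂FC; means are
  not renormalised afterwards (planted effects are few and small relative
  to total mass).
* **Lengths.** miRNA inserts are the mature sequences (18–24 nt, modal
  weight at the 22-nt peak); other classes draw insert lengths from a
  bimodal law over 18–30 nt peaked at the two configured lengths (22 and
  28 by default, the miRNA and piRNA peaks). The 28-nt bump carries more
  mass, as in insect libraries.
* **Reads.** insert + 3′ adapter + random fill at constant Phred 40;
  each contaminant category is constructed to violate exactly its own
  filter rule (e.g. low-quality reads at constant Phred 15, polyA inserts
  ≥ 80 % A). Reference sequences are rejection-sampled so they cannot
  accidentally trip the 5′-contaminant or polyA rules; this keeps truth
  labels exact and classification accuracy testable at 100 %.
* **Defaults.** Contaminant fractions follow the control library of the
  packaged accounting table (0.23 % adapter-null, 0.08 % insert-null,
  1.73 % 5′ contaminants, 5.02 % short, 0.01 % polyA) plus 1 % low
  quality; the class mixture (30 % miRNA, 35 % unannotated, the rest
  spread over structural RNA/repeat/exon/intron) reflects typical insect
  library composition. Depth is config-driven; tests use 2,500–40,000
  reads per library for speed, and count-level simulation
  (`simulate_mirna_counts`) at 10⁶-read depth for power studies, where a
  50-TPM miRNA yields ~46 expected counts.

What passing synthetic tests does **not** show: robustness to sequencing
error, adapter mismatches, isomiR-rich loci, multi-mapping tags, or
biological replicate variance — none of which the generator produces.

## Novel-candidate filter

The acceptance rule is score > 1, randfold P < 0.05, MFE < −19 kcal/mol,
with the first failed criterion reported. Discovery scores are external
inputs (miRDeep-style hairpin discovery is out of scope). The shuffle is
the Altschul–Erickson Euler-walk dinucleotide shuffle (exact dinucleotide
multiset and terminal bases preserved). The empirical P uses the
(1 + k)/(1 + n) permutation estimator; note that at exactly 19 shuffles the
smallest attainable P is 0.05, which fails the strict < 0.05 rule, so
practical runs should use ≥ 24 shuffles (pipeline default 24–49, CLI
default 99).

The default energy model is intentionally simple and fully specified: pair
energies GC −3, AU −2, GU −1 kcal/mol, a −1 kcal/mol bonus per directly
stacked pair, minimum hairpin loop 3 nt, optimum over nested structures by
an O(n³) DP (verified against exhaustive structure enumeration for short
sequences). The −19 kcal/mol threshold is therefore meaningful only
relative to the configured model; an RNAfold backend can be swapped in
(`fold_energy(seq, backend="rnafold")`) when thermodynamic energies are
wanted.

## Annotation and commonality

Tag classification is exact substring matching against per-class reference
sets, highest priority wins; mature-miRNA matching accepts tags that are
substrings of the mature sequence, with an optional ±2 nt isomiR overhang
window (off by default). Genome mapping is exact substring on either
strand — a reproducible contract standing in for heuristic aligners. The
between-library commonality percentage is defined symmetrically as
100·(shared mass in A + shared mass in B)/(mass A + mass B); per-side
fractions are also reported, since published single-number "common sRNA"
percentages leave the denominator unspecified.

## qPCR

Replicates are averaged on the Ct scale; ΔCt = Ct(target) − Ct(reference),
ΔΔCt = ΔCt(treatment) − ΔCt(control), relative expression 2^−ΔΔCt, with the
SD of ΔΔCt propagated from replicate SDs. Concordance with sequencing is
sign agreement of log₂ fold-changes. Amplification-efficiency correction is
out of scope.

## Numerical and design notes

* Percentages destined for two-decimal tables are computed with `Decimal`
  half-up rounding, matching table presentation exactly.
* `top_n` ranks by control-library count among miRNAs expressed in all
  libraries; ties break lexicographically.
* Venn identity for target pairs is (miRNA, transcript); site positions
  are ignored, as predictor "spot" counts are pair-level.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; regenerating any artifact with the same
  configuration is byte-identical.
* Degenerate inputs: empty read streams yield zero-total accounting (not
  an error); empty tag sets, empty genomes and missing qPCR conditions
  raise with the offending item named.

## Known limitations

Single-library designs cannot separate biological from sampling variance;
Bonferroni across one comparison ignores the four-time-point family; the
stacking energy model underestimates loop penalties relative to full
nearest-neighbour thermodynamics; exact-substring mapping misses variant
tags a mismatch-tolerant aligner would place. The published study-level
outcomes that depend on its unreleased raw libraries and external tool
versions (counts of DE and novel miRNAs, predictor-specific Venn totals,
GO/KEGG enrichment) are out of reach by construction and are covered
instead by the property-based synthetic checks above.
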