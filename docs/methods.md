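# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices made where the design was genuinely open,
and what the synthetic-data generators do and do not emulate.

## k-mer genome-size estimation

**Model.** Under uniform shotgun coverage, every genomic position spawns
one k-mer window per covering read (a read of length *L* contributes
*L − k + 1* windows), so the multiplicity of a single-copy genomic k-mer
is approximately Poisson with mean equal to the k-mer sequencing depth.
The main peak of the multiplicity spectrum therefore estimates that
depth, and genome size follows as `G = k_num / k_depth`. The base
formulation `G = b_num / b_depth` with
`b_depth = k_depth · L/(L − k + 1)` is reported alongside and agrees
within 1% by construction.

**Choices.**

* *k = 17* by default (overridable); k-mers are strand-canonicalized
  (lexicographic minimum of a window and its reverse complement) because
  shotgun reads come from both strands. Windows containing N are
  excluded.
* *Error-peak exclusion.* Sequencing errors create a large spike of
  multiplicity-1–2 k-mers. The boundary between the error and coverage
  components is taken as the first local minimum of the dense spectrum;
  a spectrum that only decreases has no coverage peak and raises an
  error. The same boundary is used twice: the mode is searched only
  beyond it, and k-mers at or below it are excluded from the totals
  entering the size formula (`exclude_error_kmers=False` restores the
  raw totals). Without the second exclusion, error k-mers inflate the
  numerator but not the peak, and the size is overestimated by roughly
  `1/(1−e)^k − 1` (≈9% at a 0.5% per-base error rate).
* *Peak refinement.* The integer mode alone is biased by up to half a
  bin. For a Poisson-shaped component the log-spectrum is very nearly a
  parabola, so the peak is located by a least-squares parabola on
  log-counts over the half-height window around the mode. The vertex of
  that parabola sits half a bin below the component mean (the mode/mean
  offset of a Poisson), so 0.5 is added back (`mode_to_mean=False`
  disables this). The spectrum *mean* is deliberately not used as the
  depth: repeat content inflates the high-multiplicity tail (and hence
  the mean) while leaving the peak in place, which is exactly why the
  peak-based formula is robust to duplications.

**Validated conditions.** 100 kb genomes at 30× with 100-bp reads and
0–0.5% substitution error recover the true size within 5% (observed
worst case ≈1.4% over 10 seeds); a genome with 10% exact duplication is
recovered within 5% because only the tail shifts. Sizes were chosen so
the whole suite runs in seconds; the estimator itself is linear-time
and memory-bound only by the distinct k-mer count.

## Ka/Ks and the GO-category screen

**Estimator.** ω is defined as Ka/Ks. As the concrete pairwise
estimator we use Nei–Gojobori (1986) fractional counting: each codon
position contributes the fraction of its three single-nucleotide
mutations that are synonymous (mutations to stop codons excluded from
the denominator), so synonymous + nonsynonymous sites equal 3 per codon
exactly; codon pairs differing at *d* positions are averaged over all
*d*! single-step pathways, skipping pathways through stop codons (if
every pathway is blocked the *d* changes are split equally and the pair
flagged). Observed proportions are corrected with Jukes–Cantor,
`d = −(3/4)·ln(1 − 4p/3)`, undefined (saturated) at p ≥ 3/4. ω is
undefined when Ks = 0 and exactly 0 when Ka = 0 with valid Ks; genes
with undefined ω are excluded from category aggregation with a logged
count. Site and pathway counting are verified against exhaustive
enumeration over all 61 sense codons and all 61×61 codon pairs.

**Category screen.** Categories with at least 10 member genes are
scored by the mean ω of their members (median available via
`aggregate="median"`), normalized by the median gene ω of the species
pair. Significance comes from a permutation null — `n_perm` random
same-size gene sets drawn with replacement from the analyzed genes —
with two one-sided tails (rapid: elevated; slow: depressed), an add-one
correction so p ∈ (0, 1], and Benjamini–Hochberg adjustment within each
tail. The permutation criterion is this package's concretization; no
fixed effect-size threshold is imposed. n_perm defaults to 10,000
(≥100 enforced); 2,000 suffices for the planted-recovery checks.

**Positive-selection post-processing.** Branch-site likelihood pairs
(lnL₀, lnL₁) are reduced to 2ΔlnL and referred to the boundary-respecting
50:50 mixture of a point mass at 0 and χ²(1): p = 1 at 2ΔlnL = 0, else
half the χ²(1) upper tail. Genes with q (BH) below the threshold
(default 0.05) are reported. A statistic below −10⁻⁶ is treated as an
input error. Fitting the codon models themselves is out of scope; only
their likelihoods are consumed.

## Poisson differential expression

RPKM is `10⁹·count/(lib_size·gene_length)`; library sizes default to
the column totals of the count table and can be supplied explicitly.
The "Poisson model" test is the conditional exact (Audic–Claverie)
test: given x + y, x is Binomial(x + y, N_x/(N_x + N_y)) under the null
of equal rates, and the two-sided p doubles the smaller tail, capped
at 1. This test is exact and conservative for small counts (observed
null type-I error ≈0.04 at α = 0.05 over 10,000 genes at mean 30).
A gene is called Up/Down only if |log₂ ratio| ≥ 1 (inclusive, "at least
2-fold") *and* BH-adjusted p < 0.001. For genes where exactly one count
is zero, the reported log₂ ratio uses a half-count pseudo-value; the
test itself never does, keeping it exact. Genes with both counts zero
are reported with an undefined ratio and p = 1.

## miRNA target rules and duplex energies

Duplexes are gapless and antiparallel: miRNA position *i* (1-based from
the 5′ end) pairs with site position *L + 1 − i*. Pair states are
Watson–Crick (A:U, G:C), G:U wobble, or mismatch, scored 0 / 0.5 / 1.
The six acceptance rules are listed in the README; all must pass.

* *Wobble semantics.* G:U counts 0.5 in the counting rules (1) and (5).
  For the adjacency/position rules (2)–(4) the default treats a wobble
  as a (weak) pair, consistent with its explicit half-mismatch weight
  and with plant-rule practice; `gu_strict=True` treats it as a full
  mismatch there. Both modes are tested against a literal re-check of
  the rules over every length-7 state vector and 10⁴ random length-21
  vectors.
* *Energy model.* Free energies are nearest-neighbor sums over
  consecutive paired dinucleotide stacks using the published Turner
  2004 RNA stack parameters (Watson–Crick and wobble pairs) embedded as
  literal data; internal mismatches break stacking and contribute no
  loop terms. The two destabilizing tandem-wobble entries (+1.3, +0.3
  kcal/mol) are truncated to zero so that stacking is never
  destabilizing, which makes two useful properties exact: any stacked
  duplex has energy ≤ 0, and converting a pair to a mismatch never
  increases |MFE|. The duplex initiation term is a parameter with
  default 0 kcal/mol: rule (6) compares the *ratio* of two equal-length
  duplexes, and a shared positive constant (+4.09 in the published set,
  available via `init=`) only distorts that ratio while breaking the
  sign guarantees above.
* *Rule (6)* compares absolute values (|MFE| ≥ 0.75·|MFE_perfect|),
  since "≥" on signed negative energies would invert the intended
  meaning. Because the energy model is a stacking-only stand-in, rule-6
  decisions near the 75% boundary may differ from tools with full loop
  thermodynamics.
* *Scanning* evaluates every window of miRNA length on the transcript
  sense strand, computing energies only for windows that already pass
  rules (1)–(5); all accepted windows are reported with 0-based
  half-open coordinates.

Expression normalization is transcripts per million clean reads
(`count/total·10⁶`) and fold change is log₂(treatment/control).

## Segmental duplications

Blocks are kept only if strictly longer than 1 kb *and* strictly above
90% identity; a block aligning an interval to itself on the same strand
(the self-alignment diagonal) is dropped. Both copies of each surviving
block contribute intervals (`sides="query"|"target"` restricts this),
which are unioned — overlapping or abutting — into disjoint sorted
intervals per chromosome; `total_sd_bases` is their summed length,
verified exactly against a per-base boolean-mask oracle. Merging is
idempotent. Producing the self-alignment is out of scope; the block
table (TSV, 0-based half-open) is the input.

## Synthetic-data generators

One global integer seed is split into independent per-generator streams
(genome/reads/codon/counts/blocks), so outputs are byte-reproducible
and uncoupled across generators.

* *Genomes* are i.i.d. bases at a target GC fraction (default 0.41;
  0.38 used in the size-recovery runs, matching an avian-like
  composition). No repeats or heterozygosity unless planted explicitly.
* *Reads* are drawn uniformly with replacement from both strands with
  i.i.d. substitution errors; total bases equal depth × genome length
  within one read. No indels, no quality model, no insert-size
  structure — so passing recovery tests says nothing about
  heterozygosity peaks or coverage biases of real libraries.
* *Codon pairs* start from a random stop-free sequence; one lineage
  accumulates single-nucleotide codon changes until
  `round(branch_length · n_codons)` acceptances. Stop-creating
  proposals are rejected; nonsynonymous proposals are accepted with
  probability min(1, ω) and synonymous ones with min(1, 1/ω), so the
  nonsynonymous/synonymous *rate ratio* equals ω over the whole range
  (a pure min(1, ω) acceptance cannot represent ω > 1). Mutation is
  uniform across positions and bases — no transition/transversion or
  codon-frequency bias — which is exactly the regime where NG86
  counting is unbiased; recovery on real, biased data would be less
  clean.
* *Count matrices* are Poisson draws with mean
  `baseline_rpkm · length · lib_size / 10⁹`, treatment scaled by
  2^planted_log2fc. No overdispersion (single biological condition per
  library, as in the two-library design).
* *Block tables* emit planted duplication pairs verbatim plus noise
  blocks that are always below both SD thresholds; a planted pair on
  its own diagonal is rejected as a self-hit.

## Problem sizes and determinism

Default verification sizes — 100 kb genomes at 30×, 2,000-codon
alignments over 20 seeds, 600-gene GO universes with 2,000
permutations over 10 seeds, 10,000-gene null count matrices — keep the
full suite and the acceptance script fast on a single core while
leaving estimator standard errors well inside the asserted tolerances.
All randomness flows through explicit integer seeds; the same seed
reproduces every file byte-identically.

## Known limitations

* The k-mer estimator assumes a unimodal coverage component;
  heterozygous (bimodal) spectra and ploidy are not modeled.
* NG86 with Jukes–Cantor is the simplest consistent ω estimator; it
  ignores transition/transversion and codon-usage bias and saturates
  at p ≥ 3/4.
* The permutation GO screen tests exchangeability of gene labels; gene
  length or expression confounders in real annotations are not
  adjusted for.
* The DE test has no replicate-aware dispersion; it tests Poisson
  equality between two libraries only. Printed P/FDR columns from the
  original experiment are not recomputable without the library totals,
  so only the RPKM → log₂-ratio arithmetic is checked against them.
* The duplex energy model has no bulges, internal-loop or dangling-end
  terms; it is a ranking/ratio model, not a ΔG predictor.
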