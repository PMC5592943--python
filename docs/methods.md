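# Methods

This note documents the models, defaults and numerical choices behind
`mirileqtl`, and what the synthetic-data generator does and does not
emulate.

## Population model

A miRIL panel is simulated as: F1 hybrids of two fully homozygous parents
(P1 = N2-like, coded 1; P2 = CB4856-like, coded 0); one F2 per line,
resampled until homozygous P1 at the selected (introgressed) locus; then
`n_selfing = 10` generations of self-fertilisation. Any residual
heterozygosity after selfing is forced to a random parental allele, so
output lines are strictly homozygous. Meiosis draws the number of
crossovers per chromosome from Poisson(`recomb_rate = 1`) with breakpoint
positions uniform in bp. This is the simplest model that reproduces the
two features downstream stages depend on: linkage decay along a
chromosome and a P1 allele-frequency skew around the selected locus that
decays with distance (unlinked markers segregate 1:1 in expectation).

Defaults mirror the study design: 33 lines, six chromosomes totalling
~98 Mb, markers every 400 kb (~242 true markers), selected locus at
IV:11.7 Mb. The effective recombination density of the real crossing
scheme is unknown; the default rate is calibrated only to yield a map in
the 200–300-informative-marker range, not to match the real genetic map.

## Expression model

`value(spot, strain) = baseline + Σ effect·1[genotype at target = P1] + N(0, sd)`
with `sd = 1` and effects in noise-SD units, so an allelic effect `a` at
a marker with P1 frequency `p` explains `R² = a²p(1−p) / (a²p(1−p)+1)`
— at a balanced marker, `a = 1` explains 20% of the variance. The planted
architecture contains, by default: one spot per reference-panel gene
carrying its panel cis effect; 8% of features with a cis effect at the
marker nearest their own position, positive (N2-higher) with probability
0.71 to reproduce the observed N2 bias of cis-eQTL; 4% scattered trans
effects with balanced signs; two trans-bands of 60 spots each targeting a
single random marker; the remainder pure noise. Effect magnitudes are
Uniform(0.5, 3). Parental profiles are generated as pure-P1 and pure-P2
genotype rows, four replicates each.

The generator does **not** emulate microarray artifacts (dye bias, probe
cross-hybridisation, intensity-dependent variance), heterozygous or
multi-allelic genetics, polygenic backgrounds, or expression correlation
beyond that induced by shared eQTL. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not robustness to
real-array noise structure.

## Reference cis-eQTL panel and expression markers

The genotyping reference emulates a panel of *pre-selected strong* cis
effects from a prior experiment: 8480 genes (424 windows of 20) placed
uniformly, magnitudes Uniform(2.5, 5) in log₂ units with random signs
(positive = higher in P1). Window density matters: with 20-gene windows
spanning ~230 kb, a within-window crossover is rare and calls localise
breakpoints well below the window span.

Markers are called per strain from the Pearson correlation between the
window's signed reference effects and the strain's parental-centred
intensities. Windows are *non-overlapping consecutive blocks* in genomic
order (chromosome, then position), giving `floor(n_matched/20)` markers;
a block spanning a chromosome boundary takes the chromosome and position
of its median gene (in practice a negligible minority). The
representative position of a window is its median gene, as no principled
alternative exists without per-gene weights. Pearson (not rank)
correlation is used because both vectors are continuous effect estimates;
the choice is configurable.

Call thresholds follow the two-tier scheme: |r| > 0.5 for window-level QC
(every parental replicate must be called as its own genotype, and more
than half the strains must exceed 0.5), |r| > 0.6 for assigning a
genotype. Missing calls flanked by concordant calls are imputed;
discordant flanks leave the interval missing and flagged as a crossover —
fabricating a genotype inside a breakpoint interval would bias peak
positions, so residual missing calls are instead excluded per-strain from
the regression. Chromosome ends copy the distal-most assigned call.
Pruning keeps markers with minor-genotype frequency > 0.15 (this removes
the selected-locus region, which is nearly fixed for P1) and collapses
runs of adjacent markers with identical strain patterns to their first
member, the crossover-border representative.

## eQTL scan

With a single binary regressor, the OLS F test equals the pooled-variance
two-sample t test; the scan computes that statistic in closed form,
vectorised over all spot × marker pairs, with missing genotypes excluded
per marker and markers with fewer than 2 strains per class skipped
(flagged, −log₁₀(p) = 0). p-values come from the t distribution with
n−2 df via `logsf`, so extreme statistics stay finite; an exact fit is
capped at −log₁₀(p) = 350. Peak calling takes the chromosome-wide maximum
(leftmost on ties, for determinism); one peak per spot per chromosome —
multi-peak splitting within a chromosome is deliberately not attempted.
The confidence interval is the contiguous run around the peak with
−log₁₀(p) strictly greater than peak − 1.5 (">" rather than "≥";
configurable). cis/trans uses the gene start coordinate, 1-based.

## Permutation FDR

Each permutation shuffles every spot's values independently across
strains, preserving marginals while breaking genotype association. The
discovery unit is a spot whose maximum −log₁₀(p) reaches the cutoff
(matching "genes with an eQTL" counting); candidate cutoffs are the
sorted unique observed spot maxima, since values between observed maxima
change nothing. The estimator is `FDS(t)/RDS(t) ≤ q` with `m0/m = 1` —
the standard permutation estimator, conservative because m0 ≤ m. Optional
`m0_ratio` and `log_m_correction` (multiply/divide) flags reproduce
alternative published readings of the criterion. On the default synthetic
data with q = 0.1 the selected cutoff lands at −log₁₀(p) ≈ 3.3, and the
realized false-discovery proportion averages ≈ 0.07 over 50 replicates
(computed by the test suite and the acceptance script).

## Power simulation

For every marker of the informative map and each explained-variance level
r² ∈ {0.20 … 0.80, step 0.05}, 10 phenotypes are simulated as
`a·genotype + N(0,1)` with `a = 2√(r²/(1−r²))` and scanned genome-wide.
"Detected correctly" is not uniquely defined for a genome-wide scan; the
default — the genome-wide peak exceeds the threshold, lies on the correct
chromosome, and the true marker falls inside the peak's 1.5-drop CI — is
the main lever on the headline detection rate and is configurable. With
the derived ~266-marker map at threshold 3.2 the simulated detection of a
40%-variance QTL is ≈ 74–77%, bracketed by the single-marker noncentral-F
analytic power (79.6% for group sizes 16/17): the genome-wide criterion
can only lose power relative to the oracle single test. Estimated
explained variance at detected peaks is reported untouched; it is
upward-biased at low power (winner's curse) and the bias shrinks toward
r² = 0.8.

## Hotspots, replication, uniqueness

Trans spot peaks are binned into half-open [k, k+1) Mb bins anchored at
coordinate 0, so whole-Mb band boundaries arise naturally and no spot is
double-counted. λ = total trans spots / occupied bins; a bin is a hotspot
when the exact upper-tail Poisson probability P(X ≥ count) falls below
the significance level (so "> 30 spots" ⇔ P(X ≥ 31) < 0.05 at λ = 22.10,
and "> 38" ⇔ P < 0.001); adjacent significant bins merge into a band
whose p-value is the minimum member p. Poisson tails are computed as
exact pmf sums in log space (`logsumexp` over `−λ + k·lnλ − ln k!`) and
cross-checked in the tests against term-by-term summation and
`scipy.stats.poisson`.

Replication is gene-level: a cis gene replicates if any reference table
carries a cis-eQTL for it; a trans gene additionally requires the same
peak chromosome. Band uniqueness is the lower-tail probability
P(X ≤ replicated) with λ = expected rate × band genes, where the expected
rate defaults to the genome-wide trans replication rate computed from the
supplied references and is overridable.

## Enrichment and concordance

Hypergeometric over-representation on unique genes (spots deduplicated),
upper tail only. A category passes at Bonferroni-corrected p < 0.05 with
category size > 3 and overlap > 2. The Bonferroni denominator counts only
categories surviving the size filter — the hypotheses actually tested;
counting the raw catalogue would be more conservative and can be obtained
by pre-filtering the annotation table. The universe defaults to the genes
present on the platform and in the annotation table. Concordance pairs
per-gene eQTL allelic effects (averaged over spots) with transgenic
allelic differences on the same sign convention; zero differences count
as discordant and are reported.

## Numerical and interface conventions

Coordinates are 1-based inclusive bp in all TSVs; bins are half-open in
Mb. Numeric TSV output uses 6 significant digits so reruns diff cleanly.
Every stochastic operation takes an explicit seed and no global RNG state
is used; the pipeline runner derives per-stage seeds from one master
seed, making reruns byte-identical. Zero-variance correlation windows
yield missing calls with a warning; constant expression rows score
−log₁₀(p) = 0 everywhere.

## Problem sizes used in tests and the acceptance script

The study-scale data set used for parameter recovery is 33 lines,
5000 planted features plus the 8480-gene panel, scanned against the
derived ~266-marker map; the realized-FDR check uses 50 independent
replicates of 600 features (120 signal, 480 null) at 10 permutations
each; the power check uses 10 replicates per marker (≈2700 scans per r²
level) plus 4000 replicates at a single balanced marker for the
analytic comparison. These sizes give Monte-Carlo standard errors well
inside the asserted tolerances.

## Known limitations

- One peak per spot per chromosome; closely linked QTL in coupling on the
  same chromosome merge into a single record.
- The miRIL crossing scheme's true recombination density is not matched,
  only the resulting informative-marker count range.
- The permutation estimator assumes exchangeability of strains per spot;
  population structure beyond the selected locus is not modelled.
- Counts that depend on the real arrays (absolute numbers of cis/trans
  genes) are emergent properties of the planted architecture, not
  calibrated targets.
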