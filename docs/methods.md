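# Methods

## Survival model and cutpoint discovery

Survival is modeled as right-censored time-to-event data (times in
months, event = 1 for death). Kaplan–Meier estimation, the two-group
log-rank test and univariate Cox proportional-hazards fitting are
delegated to lifelines behind this package's interfaces; Cox ties use
the Efron approximation, and non-convergence (e.g. monotone likelihood
under perfect separation) is reported via a `converged` flag rather
than raised.

Maximally selected rank statistics are implemented in
`ezscore.survival`. For a covariate x, every admissible split "x > c"
is evaluated with the standardized log-rank statistic
(O − E)/√V using the hypergeometric variance, so the squared statistic
at any split equals the ordinary log-rank chi-square there — the suite
checks this identity against lifelines directly. Candidate cutpoints
are midpoints between consecutive distinct sorted values; a split is
admissible when both groups contain at least `min_prop` (default 0.10)
of the samples. The implementation computes all splits in one
vectorized pass over the risk-set matrix and is verified to agree
exactly with exhaustive brute-force search on cohorts up to n = 100.

Because the cutpoint maximizes over many candidate splits, the naive
chi-square p of the maximal statistic is anti-conservative. The
reported corrected p uses the improved-Bonferroni approximation for the
supremum of a standardized Brownian bridge over the admissible quantile
range [ε, 1−ε]:

P(max |Z| ≥ b) ≈ 4φ(b)/b + φ(b)(b − 1/b) · log[ε′(1−ε)/(ε(1−ε′))],

clamped to [2Φ(−b), 1]. A permutation mode (shuffling the covariate,
recomputing the maximal statistic) is available with an explicit seed;
the approximation is checked to be conservative against 10,000-sample
permutation estimates on null cohorts.

## Signature construction

Candidates are (1) genes upregulated by the drug at fold change ≥ 2 and
FDR < 0.05 from a supplied differential-expression table (the pipeline
never computes DE itself; the fold-change threshold is configurable
because 1.5 is also a defensible choice for this filter), then (2)
intersected with the H3K27me3-associated gene set on case-insensitive
symbols. Each surviving probeset is screened on the training cohort:
maxstat cutpoint on its linear signal, univariate Cox on the
dichotomized (strictly-above) indicator, direction labeled Bad (HR > 1)
or Good (HR < 1).

Three p-values are reported per gene — the corrected maxstat p, the
uncorrected chi-square tail of the statistic at the chosen cutpoint
(the column printed in the published parameter table; we verified the
printed p equals the chi-square tail of the printed chi-square in all
15 rows), and the Cox Wald p. Selection filters the corrected maxstat p
at alpha = 0.05 by default: on pure-null cohorts this keeps per-gene
retention at or below alpha, whereas filtering the uncorrected p
retains ~40–45% of null genes because of the cutpoint search. Filtering
on the other p-values, or adding a Benjamini–Hochberg step across
genes, is exposed via flags. A consequence worth knowing: when several
prognostic genes act in the same cohort, each univariate screen omits
the others, attenuating every marginal log-HR toward zero
(non-collapsibility of the Cox model); per-gene screening power is
therefore below what a single-gene power calculation suggests, and the
recovered betas in the worked example are visibly shrunken relative to
the planted conditional values.

## Scoring and stratification

The score is the ±1-weighted sum of per-gene betas (strictly above the
cutpoint → +1; at or below → −1, matching the maxstat split
convention). Betas are taken as ln(HR) when a table stores only hazard
ratios; for the shipped table the 2-significant-figure rounding of the
published HRs propagates roughly 1% relative uncertainty into the
score. Missing signature genes raise an error — the ±1 weighting cannot
be renormalized without changing the score's scale, so no imputation is
attempted. Stratification labels a sample high-risk iff score >
threshold, with the threshold either fixed (0.686 is the published
value for this signature) or discovered by running maxstat on the score
itself. Score–survival association is reported both continuously (Cox
on the raw score) and dichotomized (KM curves + log-rank).
Score–drug-response association uses Pearson correlation by default
(Spearman optional).

## Methylation and overlap analyses

Promoter methylation uses BED-convention 0-based half-open intervals: a
CpG at position p belongs to promoter [s, e) iff s ≤ p < e. A
gene–sample pair is "methylated" when at least one promoter CpG has
beta strictly above 0.8 (the threshold is configurable in (0,1);
classification is monotone in it). Genes without any assayed promoter
CpG are "no-data" and excluded from group comparisons. When a promoter
map must be derived from annotation, the default window is TSS −1500/+500
bp (a common 450k convention); a ready-made map is accepted directly.
Sensitive-vs-resistant comparison summarizes each sample by its
methylated fraction over the informative target genes and applies a
two-sided Wilcoxon rank-sum test (exact for ≤8 per group); a per-gene
2×2 count table is emitted alongside for per-line summaries. Venn
accounting for drug-deregulated × H3K27me3 × H3K4me3 gene sets
("bivalent" = both marks) is exact set algebra on normalized symbols.

## Synthetic data

The generator produces what the analysis assumes, with truth recorded:

- **Expression**: per-gene log-normal on the linear scale (default
  meanlog 5.5, sdlog 1 — median signal ≈ 245, right-skewed and
  nonnegative like MAS5 summaries). No probe-level artifacts, batch
  effects or gene–gene correlation are emulated; passing tests
  demonstrate statistical correctness of the pipeline, not robustness
  to array artifacts.
- **Survival**: exponential baseline (default 0.02/month → median ≈ 35
  months) with each planted gene multiplying the hazard by exp(beta)
  through its above-cutpoint indicator; cutpoints sit at population
  quantiles (default median) of the gene's marginal. Censoring is
  independent uniform on (0, m) with m solved by root-finding so the
  expected event fraction hits the target (default 0.7); this is
  administrative, non-informative censoring.
- **Drug response**: viability = intercept + slope·score + Gaussian
  noise; `calibrate_sensitivity_noise` inverts the attenuation formula
  |r| = |slope|·sd(score)/√(slope²·var(score)+σ²) so replicate studies
  can target a chosen correlation (the validation study targets
  r = −0.68 at n = 14).
- **Methylation**: betas from a Beta(1,9)/Beta(9,1) low/high mixture
  (means ≈ 0.1 / 0.9, matching the bimodality of array beta values);
  resistant lines draw the high component with elevated probability on
  target-gene promoters.

All generators are deterministic given a seed.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale problems chosen to
make the statistical checks sharp: exhaustive-oracle equivalence on 50
cohorts of n ≤ 100; permutation conservativeness with 10,000 permutations
on 5 null cohorts; Cox recovery on 20 cohorts of n = 1000; signature
recovery on replicated n = 300 cohorts with 5 planted genes among 50
nulls; correlation calibration over 500 replicates of n = 14. Cox
convergence follows lifelines defaults; maxstat ties in x produce no
candidate between equal values; equal scores at the threshold go to the
low-risk group (strict ">"), consistent with the cutpoint convention.

## Known limitations

- Signals must already be normalized, linear and nonnegative; the
  package never log-transforms, since cutpoints live on the input scale.
- The corrected maxstat p is an approximation, slightly conservative in
  the tails; use the permutation mode when calibration matters.
- Univariate screening inherits marginal-vs-conditional attenuation
  (above); multivariate Cox models are out of scope.
- Exact small-sample maxstat null distributions are not implemented
  beyond the permutation mode.
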