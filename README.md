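# ezscore

A tested implementation of the **EZ score** — a gene-expression survival
score for multiple myeloma that identifies poor-prognosis patients
predicted to benefit from EZH2-inhibitor (EPZ-6438 / tazemetostat)
treatment — together with the full pipeline that builds such scores:
maximally selected rank statistics (maxstat) for expression cutpoints,
univariate Cox proportional-hazards screening, Kaplan–Meier / log-rank
survival comparison, epigenetic gene-set overlap accounting, and
promoter CpG methylation classification.

## Who it is for

Biostatisticians and computational biologists building or evaluating
prognostic expression signatures on survival cohorts, and anyone who
needs a clean, oracle-tested maxstat + Cox screening pipeline with a
synthetic-cohort generator for end-to-end validation.

## The score

For a sample with linear-scale (MAS5-style) signal $s_g$ on each of the
15 signature genes, with per-gene maxstat cutpoint $c_g$ and Cox
log-hazard-ratio $\beta_g$:

$$\mathrm{EZ} = \sum_{g=1}^{15} \beta_g \cdot \mathrm{sign}_g,\qquad
\mathrm{sign}_g = \begin{cases}+1 & s_g > c_g\\ -1 & s_g \le c_g\end{cases}$$

The shipped parameter table (`ezscore.load_signature_params()`) carries
the published 15 genes: 3 adverse ("Bad", HR > 1: NRP2, REEP1, SV2B) and
12 favorable ("Good", HR < 1). $\beta_g = \ln \mathrm{HR}_g$, so the
attainable score range is exactly
$[-\sum_g|\beta_g|, +\sum_g|\beta_g|] = [-8.077, +8.077]$, and a sample
with every gene above its cutpoint scores $\sum_g \beta_g = -4.940$.
Higher scores mean worse prognosis and higher predicted inhibitor
sensitivity; cohorts are split into high/low risk at a fixed threshold
(the published 0.686) or at a maxstat-discovered one.

Each cutpoint $c_g$ is found by evaluating the standardized log-rank
statistic at every admissible split $s_g > c$ (both groups ≥ 10% of
samples) and taking the maximizer; the p-value is corrected for the
cutpoint search (improved-Bonferroni approximation, with an optional
permutation mode).

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
synthetic cohort with recorded ground truth:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_build_signature.py
python analysis/03_score_and_stratify.py
```

which prints (abridged):

```
cohort: 300 samples x 55 genes, 207 events (69%)
planted genes: ['G0000', 'G0001', 'G0002', 'G0003', 'G0004']
retained 7 of 55 candidates at alpha=0.05
planted recovered: ['G0000', 'G0001', 'G0002', 'G0003', 'G0004']
false positives: ['G0007', 'G0025']
  G0000: beta +0.684 (true +0.693), cutpoint 222 (true 245), direction Bad
maxstat threshold on score: 0.802
continuous Cox: beta 0.520/unit (HR 1.68), p = 1.41e-24
high vs low risk log-rank: chi2 = 102.4, p = 4.47e-24
```

All five genes planted with conditional hazard ratios 2 / 0.5 are
recovered with betas near truth (recovered marginal betas are slightly
attenuated toward zero because each univariate screen omits the other
four planted effects), the discovered score threshold separates the risk
groups, and the score is strongly prognostic both continuously and
dichotomized. `analysis/04_epigenetic_overlap.py` and
`analysis/05_drug_sensitivity.py` run the methylation comparison
(sensitive vs resistant lines, rank-sum p = 0.0079 on the synthetic
panel) and the score-vs-viability correlation study (median replicate
r = −0.70 when calibrated to −0.68 at n = 14).

A CLI mirrors the library for shell use:

```bash
ezscore simulate --n-samples 200 --seed 7 --out cohort/
ezscore score --expr cohort/expression.tsv --out scores.csv   # published 15-gene table
ezscore stratify --scores scores.csv --threshold 0.686 --out strata.csv
ezscore qpcr --ct-gene 21 --ct-ref 18 --dct-positive-control 3   # -> 100
```

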