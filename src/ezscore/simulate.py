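"""Synthetic cohorts with the statistical structure the score analysis assumes.

Expression is log-normal on the linear scale (nonnegative, right-skewed,
MAS5-like).  Planted prognostic genes act through their above-cutpoint
indicator: the hazard of sample i is

    lambda_i = lambda0 * exp( sum_g beta_g * 1[signal_gi > cutpoint_g] )

with an exponential baseline and independent uniform administrative
censoring calibrated to a target event fraction.  Drug response is
linear in the true score plus Gaussian noise, and methylation betas come
from a low/high two-component mixture with resistant lines receiving an
elevated high-component probability on target-gene promoters.  All
ground truth (cutpoints, betas, true scores, censoring) is recorded so
recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .survival import SurvivalData

__all__ = [
    "PlantedGene",
    "SyntheticTruth",
    "generate_cohort",
    "generate_sensitivity",
    "calibrate_sensitivity_noise",
    "generate_methylation",
]


@dataclass(frozen=True)
class PlantedGene:
    gene: str
    beta: float  # log hazard ratio of the above-cutpoint indicator
    cut_quantile: float = 0.5  # cutpoint placed at this quantile of the signal


@dataclass(frozen=True)
class SyntheticTruth:
    planted: list  # [(gene, cutpoint, beta)]
    baseline_hazard: float
    censor_max: float
    target_event_fraction: float
    true_score: pd.Series  # ±1-weighted beta sum per sample
    seed: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted": [
                {"gene": g, "cutpoint": float(c), "beta": float(b)}
                for g, c, b in self.planted
            ],
            "baseline_hazard": self.baseline_hazard,
            "censor_max": self.censor_max,
            "target_event_fraction": self.target_event_fraction,
            "true_score": {str(k): float(v) for k, v in self.true_score.items()},
            "seed": self.seed,
        }


def _solve_censor_max(lam: np.ndarray, target: float) -> float:
    """Uniform(0, m) censoring horizon giving the target expected event fraction.

    P(T < C) for T ~ Exp(lam), C ~ U(0, m) is 1 - (1 - exp(-lam m))/(lam m),
    increasing in m from 0 to 1, so any target in (0, 1) is attainable.
    """
    if not 0 < target < 1:
        raise ValueError("target event fraction must be in (0, 1)")

    def frac(m):
        x = lam * m
        return float(np.mean(1.0 - (1.0 - np.exp(-x)) / x)) - target

    lo, hi = 1e-9, 1.0
    while frac(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("censoring target infeasible")
    return brentq(frac, lo, hi)


def generate_cohort(
    n_samples: int,
    n_genes: int,
    planted: list[PlantedGene] | None = None,
    seed: int = 0,
    baseline_hazard: float = 0.02,
    event_fraction: float = 0.7,
    meanlog: float = 5.5,
    sdlog: float = 1.0,
) -> tuple[pd.DataFrame, SurvivalData, SyntheticTruth]:
    """Simulate an expression cohort with planted dichotomous survival effects.

    Returns (expression matrix genes x samples, survival data, truth).
    Baseline hazard is per month, so the default gives median untreated
    survival around 35 months — a plausible myeloma-cohort scale.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    planted = planted or []
    names = {p.gene for p in planted}
    rng = np.random.default_rng(seed)

    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    for p in planted:
        if p.gene not in gene_ids:
            raise ValueError(f"planted gene {p.gene} outside the gene universe")
    sample_ids = np.array([f"S{i:04d}" for i in range(n_samples)])

    expr = pd.DataFrame(
        rng.lognormal(mean=meanlog, sigma=sdlog, size=(n_genes, n_samples)),
        index=gene_ids,
        columns=sample_ids,
    )

    log_hr = np.zeros(n_samples)
    true_score = np.zeros(n_samples)
    planted_rows = []
    for p in planted:
        signal = expr.loc[p.gene].to_numpy()
        # population quantile of the log-normal, not the sample's, so the
        # cutpoint is a property of the design rather than of one draw
        cut = float(np.exp(meanlog + sdlog * _norm_ppf(p.cut_quantile)))
        z = signal > cut
        log_hr += p.beta * z
        true_score += p.beta * np.where(z, 1.0, -1.0)
        planted_rows.append((p.gene, cut, p.beta))

    lam = baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / lam)
    censor_max = _solve_censor_max(lam, event_fraction)
    t_censor = rng.uniform(0.0, censor_max, size=n_samples)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    surv = SurvivalData(time=time, event=event, sample_id=sample_ids)
    truth = SyntheticTruth(
        planted=planted_rows,
        baseline_hazard=baseline_hazard,
        censor_max=censor_max,
        target_event_fraction=event_fraction,
        true_score=pd.Series(true_score, index=sample_ids),
        seed=seed,
    )
    return expr, surv, truth


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def calibrate_sensitivity_noise(
    true_scores, slope: float, target_r: float
) -> float:
    """Noise sd making the expected score-viability correlation equal target_r.

    For viability = a + slope*score + eps, |r| = |slope| sd(score) /
    sqrt(slope^2 var(score) + sd_eps^2); invert for sd_eps.  The sign of
    ``target_r`` must match the sign of ``slope``.
    """
    if target_r == 0 or abs(target_r) >= 1:
        raise ValueError("target_r must be in (-1, 0) or (0, 1)")
    if np.sign(target_r) != np.sign(slope):
        raise ValueError("target correlation sign must match the slope sign")
    sd = float(np.std(np.asarray(true_scores, dtype=float), ddof=1))
    return abs(slope) * sd * float(np.sqrt(1.0 / target_r**2 - 1.0))


def generate_sensitivity(
    true_scores,
    slope: float,
    noise_sd: float,
    seed: int = 0,
    intercept: float = 50.0,
) -> pd.DataFrame:
    """Viability (% of control) linear in the true score plus Gaussian noise.

    A negative slope plants the observed direction: high-score samples
    lose more cells under the inhibitor.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    s = pd.Series(true_scores, dtype=float)
    rng = np.random.default_rng(seed)
    viability = intercept + slope * s.to_numpy() + rng.normal(0.0, noise_sd, s.size)
    return pd.DataFrame({"sample_id": s.index, "viability": viability})


def generate_methylation(
    n_sensitive: int,
    n_resistant: int,
    target_genes: list[str],
    n_other_genes: int = 50,
    cpgs_per_promoter: int = 5,
    high_prob: float = 0.15,
    resistant_shift: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Bimodal methylation betas for sensitive vs resistant cell lines.

    Betas come from a two-component Beta mixture (low centered ~0.1,
    high ~0.9).  On target-gene promoters, resistant lines draw the high
    component with probability ``high_prob + resistant_shift``;
    elsewhere (and for sensitive lines) with ``high_prob``.

    Returns (betas CpG x sample, cpg_coords, promoters, group labels).
    """
    if not 0 <= high_prob <= 1 or not 0 <= high_prob + resistant_shift <= 1:
        raise ValueError("high-component probabilities must stay in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(target_genes) + [f"OFF{i:03d}" for i in range(n_other_genes)]
    target_set = set(target_genes)

    samples = [f"SEN{i}" for i in range(n_sensitive)] + [
        f"RES{i}" for i in range(n_resistant)
    ]
    group = pd.Series(
        ["sensitive"] * n_sensitive + ["resistant"] * n_resistant, index=samples
    )

    prom_rows, cpg_rows = [], []
    cpg_index = []
    for gi, gene in enumerate(genes):
        start = 10_000 * (gi + 1)
        prom_rows.append({"gene": gene, "chrom": "chr1", "start": start, "end": start + 2000})
        for ci in range(cpgs_per_promoter):
            cid = f"cg_{gene}_{ci}"
            cpg_index.append(cid)
            cpg_rows.append({"cpg": cid, "chrom": "chr1", "pos": start + 100 + 300 * ci})
    promoters = pd.DataFrame(prom_rows).set_index("gene")
    cpg_coords = pd.DataFrame(cpg_rows).set_index("cpg")

    betas = np.empty((len(cpg_index), len(samples)))
    for j, sample in enumerate(samples):
        shift = resistant_shift if group[sample] == "resistant" else 0.0
        row = 0
        for gene in genes:
            p_high = high_prob + (shift if gene in target_set else 0.0)
            for _ in range(cpgs_per_promoter):
                if rng.random() < p_high:
                    betas[row, j] = rng.beta(9, 1)  # high component, mean 0.9
                else:
                    betas[row, j] = rng.beta(1, 9)  # low component, mean 0.1
                row += 1
    betas_df = pd.DataFrame(betas, index=cpg_index, columns=samples)
    return betas_df, cpg_coords, promoters, group
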