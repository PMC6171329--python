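"""The EZ score: a ±1-weighted sum of per-gene Cox beta coefficients.

For a sample with linear-scale signal s_g on each signature gene g with
parameters (cutpoint c_g, beta_g = log hazard ratio):

    score = sum_g beta_g * sign_g,   sign_g = +1 if s_g > c_g else -1

Higher scores mean more genes flipped toward their risk-increasing
configuration: above the cutpoint for adverse (HR > 1, "Bad") genes,
below it for favorable (HR < 1, "Good") genes.  The attainable range is
exactly [-sum|beta|, +sum|beta|].  A cohort is stratified at a fixed
threshold or at a maxstat-discovered one, and the score's association
with survival (continuous Cox + two-group log-rank) and with drug
response (correlation with viability under EZH2 inhibition) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import (
    KMCurve,
    SurvivalData,
    fit_cox_univariate,
    kaplan_meier,
    logrank_test,
    maxstat_cutpoint,
)

__all__ = [
    "EZScoreResult",
    "compute_ez_score",
    "score_samples",
    "stratify",
    "score_survival_association",
    "score_sensitivity_correlation",
]


@dataclass(frozen=True)
class EZScoreResult:
    sample_id: str
    score: float
    per_gene_sign: pd.Series  # +1 / -1 per signature probeset
    risk_group: str | None = None  # "high" / "low" once stratified


def _check_params(params: pd.DataFrame) -> pd.DataFrame:
    for col in ("probeset", "cutpoint", "beta"):
        if col not in params.columns:
            raise ValueError(f"parameter table missing column {col!r}")
    return params


def compute_ez_score(signals: pd.Series, params: pd.DataFrame) -> EZScoreResult:
    """Score one sample from its per-probeset linear signals.

    Every signature probeset must be present with a nonnegative signal;
    a missing probeset raises (the ±1 weighting cannot be renormalized
    without changing the score's scale, so no silent imputation).
    """
    params = _check_params(params)
    missing = [p for p in params["probeset"] if p not in signals.index]
    if missing:
        raise KeyError(f"signature probesets missing from sample: {missing}")
    s = signals.loc[params["probeset"]].to_numpy(dtype=float)
    if np.any(s < 0) or np.any(~np.isfinite(s)):
        raise ValueError("signals must be finite and nonnegative (linear scale)")
    sign = np.where(s > params["cutpoint"].to_numpy(dtype=float), 1.0, -1.0)
    score = float(np.dot(params["beta"].to_numpy(dtype=float), sign))
    return EZScoreResult(
        sample_id=str(signals.name) if signals.name is not None else "",
        score=score,
        per_gene_sign=pd.Series(sign, index=params["probeset"].to_numpy()),
    )


def score_samples(expr: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Score every column of a probeset-by-sample matrix.

    Returns a DataFrame indexed by sample_id with a ``score`` column.
    """
    params = _check_params(params)
    missing = [p for p in params["probeset"] if p not in expr.index]
    if missing:
        raise KeyError(f"signature probesets missing from matrix: {missing}")
    sub = expr.loc[params["probeset"]].to_numpy(dtype=float)
    if np.any(sub < 0) or np.any(~np.isfinite(sub)):
        raise ValueError("signals must be finite and nonnegative (linear scale)")
    sign = np.where(sub > params["cutpoint"].to_numpy(dtype=float)[:, None], 1.0, -1.0)
    scores = params["beta"].to_numpy(dtype=float) @ sign
    return pd.DataFrame({"score": scores}, index=pd.Index(expr.columns, name="sample_id"))


def stratify(
    scores: pd.DataFrame,
    threshold: float | str = "maxstat",
    surv: SurvivalData | None = None,
    min_prop: float = 0.10,
) -> tuple[pd.DataFrame, float]:
    """Label samples high/low risk at a fixed or maxstat-discovered threshold.

    ``threshold="maxstat"`` discovers the score cutpoint maximizing the
    standardized log-rank statistic (survival required); high risk iff
    score > threshold.  Returns (labeled frame, threshold used).
    """
    out = scores.copy()
    if threshold == "maxstat":
        if surv is None:
            raise ValueError("maxstat threshold discovery requires survival data")
        aligned = out.loc[list(surv.sample_id), "score"].to_numpy(dtype=float)
        ms = maxstat_cutpoint(aligned, surv, min_prop=min_prop)
        thr = ms.cutpoint
    else:
        thr = float(threshold)
    out["risk_group"] = np.where(out["score"] > thr, "high", "low")
    return out, thr


def score_survival_association(
    scores: pd.DataFrame, surv: SurvivalData, threshold: float | str = "maxstat"
) -> dict:
    """Associate the score with survival, continuously and dichotomized.

    Returns a dict with the continuous Cox fit on the score, the
    stratification threshold, per-stratum Kaplan–Meier curves and the
    two-group log-rank test.
    """
    s = scores.loc[list(surv.sample_id), "score"].to_numpy(dtype=float)
    cox = fit_cox_univariate(s, surv)
    labeled, thr = stratify(scores, threshold=threshold, surv=surv)
    groups = labeled.loc[list(surv.sample_id), "risk_group"].to_numpy()
    report: dict = {"cox_continuous": cox, "threshold": thr}
    if np.unique(groups).size == 2:
        stat, p = logrank_test(surv, groups)
        km: dict[str, KMCurve] = {}
        for gname in ("high", "low"):
            mask = groups == gname
            km[gname] = kaplan_meier(
                SurvivalData(
                    time=surv.time[mask],
                    event=surv.event[mask],
                    sample_id=surv.sample_id[mask],
                )
            )
        report.update(logrank_stat=stat, logrank_p=p, km_curves=km)
    return report


def score_sensitivity_correlation(
    scores, viability, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between score and drug-response viability.

    Emulates the validation on primary myeloma cells: percent viable
    malignant cells after EZH2-inhibitor exposure against the sample's
    score.  A negative r means high-score samples lose more cells, i.e.
    the score predicts inhibitor sensitivity.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(viability, dtype=float)
    if x.size != y.size:
        raise ValueError("scores and viability must be paired")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 paired records")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    return float(r), float(p)
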