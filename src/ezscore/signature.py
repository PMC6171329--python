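"""Build the gene-score parameter table for the EZ signature.

The pipeline: filter drug-deregulated genes from a differential-expression
table, intersect them with an epigenetic-mark gene set (H3K27me3), then —
per candidate probeset on a training cohort — discover the optimal
expression cutpoint by maxstat, dichotomize the signal at that cutpoint,
fit a univariate Cox model on the indicator, and retain genes whose
cutpoint log-rank p is below alpha.  The retained rows (probeset,
cutpoint, chi-square, p, hazard ratio, Good/Bad direction) form the
parameter table the score consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import SurvivalData, fit_cox_univariate, maxstat_cutpoint

log = logging.getLogger(__name__)

__all__ = [
    "GeneScoreParams",
    "filter_de_genes",
    "intersect_epigenetic",
    "select_prognostic_genes",
    "normalize_symbols",
    "validate_params",
]

PARAM_COLUMNS = [
    "probeset",
    "gene",
    "cutpoint",
    "beta",
    "hazard_ratio",
    "chisq",
    "p_value",
    "p_maxstat",
    "p_cox",
    "prognostic",
]


@dataclass(frozen=True)
class GeneScoreParams:
    """Per-gene scoring parameters: maxstat cutpoint and Cox log-HR."""

    probeset: str
    gene: str
    cutpoint: float
    beta: float
    hazard_ratio: float
    chisq: float
    p_value: float
    prognostic: str  # "Bad" (HR > 1) or "Good" (HR < 1)
    p_maxstat: float = float("nan")


def normalize_symbols(members) -> set[str]:
    """Case-insensitive gene-symbol normalization (upper-cased, stripped)."""
    return {str(m).strip().upper() for m in members if str(m).strip()}


def filter_de_genes(
    de: pd.DataFrame,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    gene_col: str = "gene",
    fc_col: str = "fold_change",
    padj_col: str = "padj",
) -> set[str]:
    """Upregulated genes with fold change >= fc_min and adjusted p < fdr_max.

    Only the upregulated direction is considered (fold change on the
    linear treated/control scale, so > 1 means induced by treatment).
    """
    if fc_min <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be positive")
    fc = de[fc_col].to_numpy(dtype=float)
    padj = de[padj_col].to_numpy(dtype=float)
    if np.any(fc <= 0):
        raise ValueError("fold changes must be positive (linear scale)")
    keep = (fc >= fc_min) & (padj < fdr_max)
    return normalize_symbols(de.loc[keep, gene_col])


def intersect_epigenetic(de_genes, mark_genes) -> set[str]:
    """Exact set intersection on normalized gene symbols."""
    return normalize_symbols(de_genes) & normalize_symbols(mark_genes)


def select_prognostic_genes(
    expr: pd.DataFrame,
    surv: SurvivalData,
    candidates,
    alpha: float = 0.05,
    min_prop: float = 0.10,
    dichotomize: bool = True,
    select_on: str = "maxstat",
    bh_correct: bool = False,
    probe_to_gene: dict | None = None,
) -> pd.DataFrame:
    """Screen candidate probesets for prognostic value; build the parameter table.

    For each candidate present in ``expr`` (probesets x samples, columns
    aligned with ``surv``): run maxstat on its signal, dichotomize at the
    discovered cutpoint (strictly above = 1) and fit a univariate Cox
    model on the indicator (or on the continuous signal when
    ``dichotomize=False``).

    Three p-values are reported per gene: ``p_maxstat`` (corrected for
    cutpoint multiplicity), ``p_value`` (uncorrected chi-square tail of
    the log-rank statistic at the chosen cutpoint — the published
    table's column) and ``p_cox`` (Wald p of the dichotomized Cox fit).
    ``select_on`` chooses which is filtered at ``alpha``; the default
    "maxstat" uses the corrected p, which keeps the null retention rate
    at or below alpha despite the data-driven cutpoint search.  With
    ``bh_correct=True`` a Benjamini–Hochberg step across genes is
    applied to the selected p before filtering.

    Candidates absent from the matrix are skipped with a warning.
    Returns a DataFrame with one row per retained gene, columns
    ``PARAM_COLUMNS``.
    """
    p_col = {"maxstat": "p_maxstat", "cutpoint": "p_value", "cox": "p_cox"}.get(select_on)
    if p_col is None:
        raise ValueError(f"unknown select_on: {select_on!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if list(expr.columns) != list(surv.sample_id):
        expr = expr.loc[:, list(surv.sample_id)]

    rows = []
    for probeset in candidates:
        if probeset not in expr.index:
            log.warning("candidate %s absent from expression matrix; skipped", probeset)
            continue
        signal = expr.loc[probeset].to_numpy(dtype=float)
        if np.unique(signal).size < 2:
            log.warning("candidate %s has constant signal; skipped", probeset)
            continue
        try:
            ms = maxstat_cutpoint(signal, surv, min_prop=min_prop)
        except ValueError as err:
            log.warning("maxstat failed for %s (%s); skipped", probeset, err)
            continue
        covariate = (
            (signal > ms.cutpoint).astype(float) if dichotomize else signal
        )
        try:
            cox = fit_cox_univariate(covariate, surv)
        except ValueError as err:
            log.warning("Cox fit failed for %s (%s); skipped", probeset, err)
            continue
        p_cut = float(stats.chi2.sf(ms.chisq, 1))
        rows.append(
            {
                "probeset": probeset,
                "gene": probe_to_gene.get(probeset, probeset)
                if probe_to_gene
                else probeset,
                "cutpoint": ms.cutpoint,
                "beta": cox.beta,
                "hazard_ratio": cox.hazard_ratio,
                "chisq": ms.chisq,
                "p_value": p_cut,
                "p_maxstat": ms.p_value,
                "p_cox": cox.p_value,
                "prognostic": "Bad" if cox.hazard_ratio > 1 else "Good",
            }
        )

    table = pd.DataFrame(rows, columns=PARAM_COLUMNS)
    if table.empty:
        return table
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(table[p_col], alpha=alpha, method="fdr_bh")
        table = table[reject]
    else:
        table = table[table[p_col] < alpha]
    return table.reset_index(drop=True)


def validate_params(table: pd.DataFrame, tol: float = 1e-6) -> None:
    """Check the parameter-table invariants; raise ValueError on violation.

    Every row must satisfy hazard_ratio = exp(beta) (to tolerance) and
    prognostic = "Bad" iff hazard_ratio > 1.
    """
    missing = {"probeset", "cutpoint", "beta", "hazard_ratio", "prognostic"} - set(
        table.columns
    )
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    if table["probeset"].duplicated().any():
        raise ValueError("duplicate probesets in parameter table")
    hr = table["hazard_ratio"].to_numpy(dtype=float)
    beta = table["beta"].to_numpy(dtype=float)
    if np.any(np.abs(hr - np.exp(beta)) > tol * np.maximum(1.0, np.abs(hr))):
        raise ValueError("hazard_ratio inconsistent with exp(beta)")
    bad = table["prognostic"].to_numpy() == "Bad"
    if np.any(bad != (hr > 1)):
        raise ValueError("prognostic label inconsistent with hazard ratio")
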