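"""Epigenetic set logic and promoter-methylation analyses.

Covers the overlap accounting between drug-deregulated genes and histone
marks (H3K27me3 / H3K4me3; a gene carrying both is "bivalent"), the
classification of promoter CpG methylation from array beta values, the
sensitive-versus-resistant methylation comparison, and the nested
overlap between methylated promoters and demethylating-agent response.

Coordinates are 0-based half-open (BED convention): a CpG at position p
overlaps a promoter [s, e) iff s <= p < e.  A gene-sample pair is called
methylated when at least one CpG in the promoter has beta strictly above
the threshold (default 0.8).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .signature import normalize_symbols

__all__ = [
    "mark_overlap_counts",
    "assign_cpgs_to_promoters",
    "classify_promoter_methylation",
    "compare_methylation_by_sensitivity",
    "methylation_de_overlap",
]


def mark_overlap_counts(de_genes, k27, k4) -> dict[str, int]:
    """Sizes of all Venn regions for (deregulated, H3K27me3, H3K4me3).

    Also reports the headline quantities: deregulated genes carrying
    H3K27me3, and the bivalent subset (both marks) among them.
    """
    a, b, c = normalize_symbols(de_genes), normalize_symbols(k27), normalize_symbols(k4)
    return {
        "de_only": len(a - b - c),
        "k27_only": len(b - a - c),
        "k4_only": len(c - a - b),
        "de_k27_only": len((a & b) - c),
        "de_k4_only": len((a & c) - b),
        "k27_k4_only": len((b & c) - a),
        "de_k27_k4": len(a & b & c),
        "de_and_k27": len(a & b),
        "bivalent_in_de": len(a & b & c),
        "union": len(a | b | c),
    }


def assign_cpgs_to_promoters(
    cpg_coords: pd.DataFrame, promoters: pd.DataFrame
) -> dict[str, list[str]]:
    """Map each gene to the CpG ids falling in its promoter interval.

    ``cpg_coords``: index = CpG id, columns chrom, pos (0-based).
    ``promoters``: index = gene, columns chrom, start, end (half-open).
    """
    if (promoters["start"] >= promoters["end"]).any():
        raise ValueError("promoter intervals must satisfy start < end")
    out: dict[str, list[str]] = {}
    by_chrom = {
        ch: grp.sort_values("pos") for ch, grp in cpg_coords.groupby("chrom")
    }
    for gene, row in promoters.iterrows():
        grp = by_chrom.get(row["chrom"])
        if grp is None:
            out[gene] = []
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, row["start"], side="left")
        hi = np.searchsorted(pos, row["end"], side="left")
        out[gene] = list(grp.index[lo:hi])
    return out


def classify_promoter_methylation(
    betas: pd.DataFrame,
    cpg_coords: pd.DataFrame,
    promoters: pd.DataFrame,
    beta_threshold: float = 0.8,
) -> pd.DataFrame:
    """Per-gene, per-sample promoter methylation status.

    ``betas``: CpG x sample matrix of beta values in [0, 1].  Status is
    "methylated" iff >= 1 promoter CpG has beta strictly > threshold,
    "unmethylated" otherwise, and "no-data" for genes whose promoter
    contains no assayed CpG (excluded from downstream tests).
    """
    if not 0 < beta_threshold < 1:
        raise ValueError("beta_threshold must be in (0, 1)")
    vals = betas.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("beta values must lie in [0, 1]")
    assignment = assign_cpgs_to_promoters(cpg_coords, promoters)
    status = pd.DataFrame(
        "no-data", index=promoters.index, columns=betas.columns, dtype=object
    )
    for gene, cpgs in assignment.items():
        cpgs = [c for c in cpgs if c in betas.index]
        if not cpgs:
            continue
        meth = (betas.loc[cpgs] > beta_threshold).any(axis=0)
        status.loc[gene] = np.where(meth, "methylated", "unmethylated")
    return status


def compare_methylation_by_sensitivity(
    status: pd.DataFrame, group: pd.Series, target_genes
) -> dict:
    """Compare promoter methylation of target genes between response groups.

    ``group``: per-sample labels "sensitive" / "resistant".  Each
    sample's methylated fraction over the informative target genes is
    compared between groups with a two-sided Wilcoxon rank-sum
    (Mann-Whitney) test; a per-gene 2x2 count table (methylated samples
    per group) is also returned for cross-panel summaries.
    """
    labels = set(group.unique())
    if labels != {"sensitive", "resistant"}:
        raise ValueError("group must contain both 'sensitive' and 'resistant'")
    targets = [
        g for g in status.index if str(g).strip().upper() in normalize_symbols(target_genes)
    ]
    sub = status.loc[targets]
    informative = sub.ne("no-data")
    meth = sub.eq("methylated")
    with np.errstate(invalid="ignore"):
        frac = meth.sum(axis=0) / informative.sum(axis=0).replace(0, np.nan)
    frac = frac.dropna()
    g = group.loc[frac.index]
    fs = frac[g == "sensitive"].to_numpy(dtype=float)
    fr = frac[g == "resistant"].to_numpy(dtype=float)
    if fs.size == 0 or fr.size == 0:
        raise ValueError("both groups must have informative samples")
    if np.all(fs == fs[0]) and np.all(fr == fr[0]) and fs[0] == fr[0]:
        stat, p = np.nan, 1.0  # identical distributions: no evidence of difference
    else:
        method = "exact" if (fs.size <= 8 and fr.size <= 8) else "asymptotic"
        res = stats.mannwhitneyu(fr, fs, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    per_gene = pd.DataFrame(
        {
            "methylated_sensitive": meth.loc[:, g.index[g == "sensitive"]].sum(axis=1),
            "n_sensitive": informative.loc[:, g.index[g == "sensitive"]].sum(axis=1),
            "methylated_resistant": meth.loc[:, g.index[g == "resistant"]].sum(axis=1),
            "n_resistant": informative.loc[:, g.index[g == "resistant"]].sum(axis=1),
        }
    )
    return {
        "statistic": stat,
        "p_value": p,
        "fraction_sensitive": fs,
        "fraction_resistant": fr,
        "per_gene": per_gene,
    }


def methylation_de_overlap(methylated_genes, de_upregulated) -> dict[str, int]:
    """Nested intersection: methylated promoters among drug targets that
    also respond to a demethylating agent."""
    m = normalize_symbols(methylated_genes)
    d = normalize_symbols(de_upregulated)
    return {
        "n_methylated": len(m),
        "n_de": len(d),
        "n_overlap": len(m & d),
    }
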