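"""Readers and writers for the pipeline's text formats, plus small utilities.

Expression matrices are tab-delimited (probesets x samples, linear
MAS5-style nonnegative signals — never log-transformed silently, since
cutpoints live on the input scale).  Survival tables and parameter
tables are comma-separated with '.' decimals.  Gene sets are one symbol
per line or GMT.  The published 15-gene signature parameter table ships
with the package and loads via :func:`load_signature_params`.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signature import validate_params
from .survival import SurvivalData

__all__ = [
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "read_gene_set",
    "read_gmt",
    "read_params",
    "write_params",
    "load_signature_params",
    "relative_qpcr_expression",
    "write_manifest",
]


def read_expression(path) -> pd.DataFrame:
    """Read a probeset-by-sample TSV matrix; validate ids and signal range."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate probeset ids in expression matrix")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("expression signals must be nonnegative (linear scale)")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_survival(path) -> SurvivalData:
    """Read a survival CSV with columns sample_id, time, event (months)."""
    df = pd.read_csv(path)
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    return SurvivalData.from_frame(df)


def write_survival(surv: SurvivalData, path) -> None:
    surv.to_frame().to_csv(path, index=False)


def read_gene_set(path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> members..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            continue
        sets[fields[0]] = {m for m in fields[2:] if m}
    return sets


def read_params(path) -> pd.DataFrame:
    """Read a gene-score parameter table CSV and validate its invariants.

    If the file stores only hazard ratios (no beta column), beta is
    derived as ln(hazard_ratio).
    """
    df = pd.read_csv(path)
    if "beta" not in df.columns:
        df["beta"] = np.log(df["hazard_ratio"].to_numpy(dtype=float))
    validate_params(df)
    return df


def write_params(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_signature_params() -> pd.DataFrame:
    """The published 15-gene EZ signature parameter table.

    Per probeset: the maxstat expression cutpoint (linear MAS5 scale),
    the log-rank chi-square at that cutpoint with its p-value, the Cox
    hazard ratio of the dichotomized covariate, and the prognostic
    direction (3 adverse "Bad" genes with HR > 1, 12 favorable "Good"
    with HR < 1).  beta is derived as ln(hazard_ratio) since the betas
    themselves are not published; the ~2-significant-figure rounding of
    the hazard ratios propagates about 1% uncertainty into the score.
    """
    ref = importlib.resources.files("ezscore.data") / "ez_signature.csv"
    with importlib.resources.as_file(ref) as path:
        return read_params(path)


def relative_qpcr_expression(
    ct_gene: float, ct_ref: float, dct_positive_control: float
) -> float:
    """Relative qPCR expression as percent of a positive control.

    dCt = Ct(gene) - Ct(reference); ddCt = dCt - dCt(positive control);
    returns 100 / 2**ddCt, so ddCt = 0 gives 100% and each extra cycle
    halves the value.
    """
    for v in (ct_gene, ct_ref, dct_positive_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_gene - ct_ref) - dct_positive_control
    return float(100.0 / 2.0**ddct)


def write_manifest(out_dir, config: dict, inputs: dict[str, str] | None = None) -> Path:
    """Write a machine-readable run manifest (config, seed, input hashes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for name, p in (inputs or {}).items():
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        hashes[name] = h
    manifest = {"config": config, "input_sha256": hashes}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
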