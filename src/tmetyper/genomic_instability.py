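"""Genomic-instability comparison between immune subtypes.

Somatic CNV burden (number of copy-number segments), nonsynonymous
tumor mutation burden (mutations/Mb) and predicted neoepitope loads are
consumed as per-sample inputs, log10-transformed, and compared between
subtypes with the unpaired Student t-test; cytolytic activity is
correlated with neoepitope load by Pearson's product-moment
correlation (both on the log10(x + 1) scale by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .survival_stats import TTestResult, t_test

__all__ = [
    "CorrelationResult",
    "read_instability_tsv",
    "log10_burden",
    "compare_burden",
    "cyt_neoepitope_correlation",
]

#: Pseudocount added to TMB before log10 (zero-mutation samples occur).
TMB_PSEUDOCOUNT = 1.0

BURDEN_FIELDS = ("n_segments", "tmb")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    p: float
    n: int
    defined: bool = True


def read_instability_tsv(path: str | Path) -> pd.DataFrame:
    """Read per-sample instability records.

    Columns: sample_id, n_segments, tmb, neoepitope_load. Rows with a
    missing field are dropped (their count logged by a warning), per
    the convention that samples without instability data leave this
    analysis only.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "n_segments", "tmb", "neoepitope_load"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"instability TSV missing columns {sorted(missing)}")
    df = df.set_index("sample_id")
    n_before = len(df)
    df = df.dropna(subset=["n_segments", "tmb", "neoepitope_load"])
    if len(df) < n_before:
        warnings.warn(
            f"dropped {n_before - len(df)} sample(s) without instability data",
            stacklevel=2,
        )
    if (df["n_segments"] < 1).any():
        raise ValueError("n_segments must be >= 1")
    if (df["tmb"] < 0).any() or (df["neoepitope_load"] < 0).any():
        raise ValueError("tmb and neoepitope_load must be non-negative")
    return df


def log10_burden(
    records: pd.DataFrame | pd.Series,
    burden_field: str | None = None,
    pseudocount: float | None = None,
) -> pd.Series:
    """log10-transformed burden per sample.

    Segment counts are log10(x) (and must be positive); TMB is
    log10(x + pseudocount) with pseudocount 1 by default so
    zero-mutation samples map to 0. Strictly monotone, so group-mean
    orderings survive the transform.
    """
    if isinstance(records, pd.DataFrame):
        if burden_field not in BURDEN_FIELDS:
            raise ValueError(f"burden_field must be one of {BURDEN_FIELDS}")
        values = records[burden_field].astype(float)
    else:
        values = records.astype(float)
    if values.isna().any():
        raise ValueError("burden values missing for some samples")
    if burden_field == "tmb":
        pc = TMB_PSEUDOCOUNT if pseudocount is None else pseudocount
        return np.log10(values + pc)
    if (values <= 0).any():
        raise ValueError("segment counts must be positive")
    return np.log10(values)


def compare_burden(group_a, group_b) -> TTestResult:
    """Unpaired Student t-test between subtype burden values.

    Callers pass log-transformed values (figure convention); the test
    itself is scale-agnostic. Degenerate variance is flagged on the
    result.
    """
    return t_test(np.asarray(group_a, float), np.asarray(group_b, float))


def cyt_neoepitope_correlation(
    cyt, neoepitope_load, log_scale: bool = True
) -> CorrelationResult:
    """Pearson correlation of CYT score with neoepitope load.

    Both vectors are log10(x + 1)-transformed by default; R^2 = r^2 and
    the two-sided p comes from the t transform of r. Zero variance in
    either vector makes the correlation undefined (flagged).
    """
    x = np.asarray(cyt, dtype=float)
    y = np.asarray(neoepitope_load, dtype=float)
    if x.size != y.size:
        raise ValueError("cyt and neoepitope vectors differ in length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 paired samples")
    if log_scale:
        if (x < 0).any() or (y < 0).any():
            raise ValueError("log-scale correlation needs non-negative inputs")
        x = np.log10(x + 1.0)
        y = np.log10(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return CorrelationResult(np.nan, np.nan, np.nan, int(x.size), defined=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(r * r), float(p), int(x.size))
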