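"""Count normalization and variable-gene selection.

Raw gene-level counts are carried to one of four normalized states:

``fpkm``
    count / (gene length in kb x library size in millions).
``tpm``
    FPKM rescaled per sample so each column sums to 1e6.
``vst``
    median-of-ratios size-factor normalization followed by log2(x + 1),
    an explicit, fully specified variance-stabilizing transform of the
    same normalization family as the count-model VST used for bulk
    RNA-seq; only the rank/variance structure feeds clustering.
``log2_centered``
    log2(FPKM + 1) with each gene row median-centered, the conventional
    input for expression heatmaps.

All matrices are genes x samples DataFrames wrapped in
:class:`NormalizedMatrix`, which tracks the normalization state so
stages can refuse inputs at the wrong scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NORMALIZATION_STATES",
    "NormalizedMatrix",
    "compute_fpkm",
    "fpkm_to_tpm",
    "variance_stabilize",
    "select_top_variable_genes",
    "log2_median_center",
    "read_counts_tsv",
    "read_gene_lengths_tsv",
]

NORMALIZATION_STATES = ("counts", "fpkm", "tpm", "vst", "log2_centered")

TPM_TOTAL = 1e6


@dataclass
class NormalizedMatrix:
    """A genes x samples expression matrix tagged with its scale.

    ``values.index`` holds gene ids, ``values.columns`` sample ids.
    """

    values: pd.DataFrame
    state: str

    def __post_init__(self) -> None:
        if self.state not in NORMALIZATION_STATES:
            raise ValueError(
                f"unknown normalization state {self.state!r}; "
                f"expected one of {NORMALIZATION_STATES}"
            )
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def require_state(self, *states: str) -> None:
        if self.state not in states:
            raise ValueError(
                f"matrix is in state {self.state!r}; expected {states}"
            )

    def to_tsv(self, path: str | Path) -> None:
        """Write values as TSV plus a `.meta.json` sidecar with the state."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps({"state": self.state}) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, state: str | None = None) -> "NormalizedMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col=0)
        if state is None:
            sidecar = path.with_suffix(path.suffix + ".meta.json")
            if sidecar.exists():
                state = json.loads(sidecar.read_text())["state"]
            else:
                state = "counts"
        return cls(values=values, state=state)


def _counts_frame(counts) -> tuple[pd.DataFrame, pd.Series | None]:
    """Accept a CohortDataset, a NormalizedMatrix in counts state, or a raw frame."""
    gene_lengths = None
    if hasattr(counts, "counts") and hasattr(counts, "gene_lengths"):
        gene_lengths = counts.gene_lengths
        counts = counts.counts
    elif isinstance(counts, NormalizedMatrix):
        counts.require_state("counts")
        counts = counts.values
    if not isinstance(counts, pd.DataFrame):
        raise TypeError("counts must be a DataFrame, NormalizedMatrix or CohortDataset")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts contain negative entries")
    return counts, gene_lengths


def compute_fpkm(counts, gene_lengths: pd.Series | None = None) -> NormalizedMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM[g, s] = count[g, s] / (length_g in kb * library-size_s in
    millions), with the library size the column total of raw counts.

    Raises if any sample has a zero column total (naming the sample) or
    any gene lacks a positive length (naming the gene).
    """
    counts, attached = _counts_frame(counts)
    if gene_lengths is None:
        gene_lengths = attached
    if gene_lengths is None:
        raise ValueError("gene lengths required to compute FPKM")
    gene_lengths = pd.Series(gene_lengths)
    missing = counts.index.difference(gene_lengths.index)
    if len(missing) > 0:
        raise ValueError(f"missing gene length for gene {missing[0]!r}")
    lengths = gene_lengths.reindex(counts.index).astype(float)
    bad = lengths[~(lengths > 0) | lengths.isna()]
    if len(bad) > 0:
        raise ValueError(f"nonpositive gene length for gene {bad.index[0]!r}")

    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")

    kb = lengths.to_numpy()[:, None] / 1e3
    millions = totals.to_numpy()[None, :] / 1e6
    fpkm = counts.to_numpy(dtype=float) / (kb * millions)
    return NormalizedMatrix(
        pd.DataFrame(fpkm, index=counts.index, columns=counts.columns), "fpkm"
    )


def fpkm_to_tpm(fpkm: NormalizedMatrix) -> NormalizedMatrix:
    """Rescale FPKM columns to transcripts per million.

    TPM[g, s] = FPKM[g, s] / sum_g FPKM[g, s] * 1e6, so every column
    sums to exactly 1e6.
    """
    fpkm.require_state("fpkm")
    totals = fpkm.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero FPKM column for sample {zero.index[0]!r}")
    tpm = fpkm.values / totals.to_numpy()[None, :] * TPM_TOTAL
    return NormalizedMatrix(tpm, "tpm")


def variance_stabilize(counts) -> NormalizedMatrix:
    """Size-factor-normalized log counts: v = log2(count / s_j + 1).

    Size factors come from the median-of-ratios estimator: the
    reference is the per-gene geometric mean across samples restricted
    to genes with all-positive counts, and s_j is the median over those
    genes of count[g, j] / reference_g. If no gene is positive in every
    sample the estimator falls back to column totals scaled to mean 1,
    with a warning.
    """
    counts, _ = _counts_frame(counts)
    if counts.shape[1] < 2:
        raise ValueError("variance stabilization needs at least 2 samples")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")

    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if all_pos.any():
        log_ref = np.log(arr[all_pos]).mean(axis=1)  # log geometric mean
        ratios = np.log(arr[all_pos]) - log_ref[:, None]
        size_factors = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no gene with all-positive counts; falling back to "
            "column-total size factors",
            stacklevel=2,
        )
        size_factors = totals.to_numpy(dtype=float)
        size_factors = size_factors / size_factors.mean()

    v = np.log2(arr / size_factors[None, :] + 1.0)
    return NormalizedMatrix(
        pd.DataFrame(v, index=counts.index, columns=counts.columns), "vst"
    )


def select_top_variable_genes(matrix: NormalizedMatrix, n: int) -> list[str]:
    """Ids of the ``n`` genes with largest across-sample variance.

    Variance is the unbiased (n-1) sample variance on the
    variance-stabilized scale; ties break by lexicographic gene id.
    Asking for more genes than exist returns all of them with a warning.
    """
    matrix.require_state("vst")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    variances = matrix.values.var(axis=1, ddof=1)
    order = sorted(variances.index, key=lambda g: (-variances[g], str(g)))
    if n > len(order):
        warnings.warn(
            f"requested {n} genes but only {len(order)} available; returning all",
            stacklevel=2,
        )
        n = len(order)
    return list(order[:n])


def log2_median_center(fpkm: NormalizedMatrix) -> NormalizedMatrix:
    """log2(FPKM + 1) with each gene row median-centered.

    The +1 pseudocount avoids -inf on zeros; after centering every gene
    row has median zero.
    """
    fpkm.require_state("fpkm")
    x = np.log2(fpkm.values.to_numpy(dtype=float) + 1.0)
    x = x - np.median(x, axis=1, keepdims=True)
    return NormalizedMatrix(
        pd.DataFrame(x, index=fpkm.gene_ids, columns=fpkm.sample_ids),
        "log2_centered",
    )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-as-rows count TSV (first column gene ids, header sample ids)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts contain negative entries")
    return counts


def read_gene_lengths_tsv(path: str | Path) -> pd.Series:
    """Read a two-column (gene_id, length_bp) TSV into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("gene-length TSV needs two columns: gene_id, length_bp")
    return df.set_index(df.columns[0])[df.columns[1]].astype(float)
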