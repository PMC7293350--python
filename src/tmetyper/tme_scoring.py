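"""Tumor-microenvironment scoring and subtype labeling.

Per-sample scores
-----------------
immune / stromal score
    Single-sample gene-set enrichment (ssGSEA) of an immune or stromal
    signature: genes are ranked by decreasing expression, the in-set
    running sum is weighted by rank^alpha (alpha = 0.25 by default), and
    the score is the sum over all rank positions of the normalized
    weighted in-set CDF minus the unweighted out-set CDF. This is the
    single-sample enrichment recipe of the ESTIMATE family.
estimate score
    immune + stromal (exact identity).
tumor purity
    cos(a + b * ESTIMATE score) with the published ESTIMATE constants
    (Yoshihara et al. 2013, Nat Commun 4:2612), clamped to [0, 1];
    undefined (NaN) when the cosine argument leaves [0, pi].
CYT
    Cytolytic activity, the geometric mean of GZMA and PRF1 expression
    (TPM) with a 0.01 offset (Rooney et al. 2015, Cell 160:48).
signature z-scores
    Per-gene z against the non-cancer-control mean and SD on the FPKM
    scale, averaged over the genes of a marker set per sample. Cohorts
    with fewer than two controls fall back to the cancer samples as the
    reference distribution (with a prominent warning).

Cluster labeling and cohort inclusion
-------------------------------------
Of the two candidate cancer clusters, the one with the lower mean of
(immune + stromal)/2 is the immune-deficient subtype A, the other the
immune-competent subtype B. A cohort is retained only if at least 3 of
the 4 TME indicators differ between subtypes in the expected direction
(immune, stromal, CYT higher in B; purity lower in B) at p < alpha by
the unpaired t-test.

Score tables are plain DataFrames indexed by sample id with columns
``immune_score``, ``stromal_score``, ``estimate_score``, ``purity``,
``cyt``, ``subtype`` (and ``is_control`` when known).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedMatrix
from .survival_stats import t_test

__all__ = [
    "GeneSet",
    "SignatureZScore",
    "TmeCriteriaResult",
    "ssgsea_score",
    "ssgsea_score_matrix",
    "estimate_scores",
    "estimate_purity",
    "cyt_score",
    "signature_zscores",
    "assign_subtypes",
    "tme_criteria_check",
    "geneset_overlap_enrichment",
    "read_gmt",
    "write_gmt",
]

GENE_SET_CATEGORIES = ("immune_signature", "stromal_signature", "marker", "checkpoint")

#: Tumor-purity transform constants from the ESTIMATE publication
#: (Yoshihara et al. 2013, Nat Commun 4:2612): purity = cos(intercept +
#: slope * ESTIMATE score).
PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884

DEFAULT_SSGSEA_ALPHA = 0.25
DEFAULT_CYT_OFFSET = 0.01


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene identifiers with a category tag."""

    name: str
    category: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in GENE_SET_CATEGORIES:
            raise ValueError(
                f"unknown gene-set category {self.category!r}; "
                f"expected one of {GENE_SET_CATEGORIES}"
            )
        if len(self.gene_ids) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"gene set {self.name!r} has duplicate gene ids")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class SignatureZScore:
    """Per-sample average z of a marker signature, with group summary."""

    name: str
    per_sample: pd.Series  # tumor samples only, mean z over signature genes
    n_genes_used: int
    n_genes_dropped: int
    reference: str  # "controls" or "cancer_samples"
    group_means: dict[str, float] = field(default_factory=dict)
    p_value: float | None = None


@dataclass
class TmeCriteriaResult:
    """Outcome of the four-score inclusion check for one cohort."""

    status: str  # "included" | "excluded_tme_criteria"
    n_directional_significant: int
    details: pd.DataFrame  # rows: score name; cols: t, p, direction_ok, significant


def ssgsea_score(
    expression: pd.Series,
    gene_set: GeneSet,
    alpha: float = DEFAULT_SSGSEA_ALPHA,
) -> float:
    """Single-sample gene-set enrichment score of one expression column.

    All G genes are ordered by decreasing expression (ties broken by
    gene id); each gene's weight is its ascending rank (average ranks
    on ties) raised to ``alpha``. The score is

        sum_i [ P_in(i) - P_out(i) ]

    over all positions i, where P_in is the weighted CDF of in-set
    genes (normalized by the total in-set weight) and P_out the
    unweighted CDF of out-of-set genes. With alpha = 0 the score
    depends on ranks only.
    """
    values = expression.to_numpy(dtype=float)
    genes = expression.index.to_numpy()
    n = values.size
    in_set = expression.index.isin(gene_set.gene_ids)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} shares no genes with the expression column"
        )
    if n_in == n:
        raise ValueError(
            f"gene set {gene_set.name!r} covers every expressed gene; "
            "out-of-set CDF undefined"
        )

    ranks = stats.rankdata(values, method="average")
    weights = np.abs(ranks) ** alpha

    # Decreasing expression; gene id as deterministic tie-break.
    order = np.lexsort((genes, -values))
    in_ord = in_set[order]
    w_ord = weights[order]

    w_in = np.where(in_ord, w_ord, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_ord) / float(n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_score_matrix(
    matrix: NormalizedMatrix,
    gene_set: GeneSet,
    alpha: float = DEFAULT_SSGSEA_ALPHA,
) -> pd.Series:
    """ssGSEA score of every sample column of a TPM/VST/FPKM matrix."""
    matrix.require_state("tpm", "vst", "fpkm")
    return pd.Series(
        {s: ssgsea_score(matrix.values[s], gene_set, alpha) for s in matrix.sample_ids},
        name=gene_set.name,
    )


def estimate_scores(
    expr: NormalizedMatrix,
    immune_set: GeneSet,
    stromal_set: GeneSet,
    alpha: float = DEFAULT_SSGSEA_ALPHA,
) -> pd.DataFrame:
    """Immune, stromal and ESTIMATE (= immune + stromal) score per sample."""
    immune = ssgsea_score_matrix(expr, immune_set, alpha)
    stromal = ssgsea_score_matrix(expr, stromal_set, alpha)
    return pd.DataFrame(
        {
            "immune_score": immune,
            "stromal_score": stromal,
            "estimate_score": immune + stromal,
        }
    )


def estimate_purity(estimate_score, *, return_flags: bool = False):
    """Tumor purity from the ESTIMATE score via the published cosine fit.

    purity = cos(PURITY_INTERCEPT + PURITY_SLOPE * score), which is
    monotone non-increasing while the argument stays in [0, pi].
    Values where the argument leaves [0, pi] are undefined (NaN,
    flagged ``"undefined"``); a negative cosine within the valid range
    is clamped to 0 and flagged ``"clamped"``.
    """
    score = np.asarray(estimate_score, dtype=float)
    arg = PURITY_INTERCEPT + PURITY_SLOPE * score
    purity = np.cos(arg)
    flags = np.where(purity < 0.0, "clamped", "")
    purity = np.clip(purity, 0.0, 1.0)
    invalid = (arg < 0.0) | (arg > np.pi)
    purity = np.where(invalid, np.nan, purity)
    flags = np.where(invalid, "undefined", flags)
    if np.ndim(estimate_score) == 0:
        return (float(purity), str(flags)) if return_flags else float(purity)
    if isinstance(estimate_score, pd.Series):
        purity = pd.Series(purity, index=estimate_score.index, name="purity")
        flags = pd.Series(flags, index=estimate_score.index, name="purity_flag")
    return (purity, flags) if return_flags else purity


def cyt_score(tpm_gzma, tpm_prf1, offset: float = DEFAULT_CYT_OFFSET):
    """Cytolytic activity: geometric mean of GZMA and PRF1 TPM plus offset.

    CYT = sqrt((GZMA + offset) * (PRF1 + offset)); symmetric in its two
    arguments and defined for non-negative expression only.
    """
    a = np.asarray(tpm_gzma, dtype=float)
    b = np.asarray(tpm_prf1, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("CYT inputs must be non-negative")
    out = np.sqrt((a + offset) * (b + offset))
    if np.ndim(tpm_gzma) == 0 and np.ndim(tpm_prf1) == 0:
        return float(out)
    if isinstance(tpm_gzma, pd.Series):
        return pd.Series(out, index=tpm_gzma.index, name="cyt")
    return out


def signature_zscores(
    fpkm: NormalizedMatrix,
    control_ids,
    signature: GeneSet,
    groups: pd.Series | None = None,
) -> SignatureZScore:
    """Average signature z-score per tumor sample against controls.

    For gene g and tumor sample s,

        z[g, s] = (FPKM[g, s] - mean_controls FPKM[g]) / SD_controls FPKM[g]

    with the control SD over control samples (n-1 denominator); the
    per-sample signature score is the mean of z over the signature
    genes. Genes whose control SD is zero are dropped with a warning.

    With fewer than two controls the cohort's cancer samples serve as
    the reference distribution instead (single-control fallback),
    announced by a prominent warning. ``groups`` (subtype label per
    tumor sample) adds group means and an A-vs-B t-test p-value.
    """
    fpkm.require_state("fpkm")
    control_ids = [s for s in control_ids if s in fpkm.sample_ids]
    tumor_ids = [s for s in fpkm.sample_ids if s not in set(control_ids)]
    present = [g for g in signature.gene_ids if g in fpkm.gene_ids]
    if not present:
        raise ValueError(
            f"no gene of signature {signature.name!r} present in the matrix"
        )

    if len(control_ids) >= 2:
        ref_ids, reference = control_ids, "controls"
    else:
        warnings.warn(
            f"only {len(control_ids)} non-cancer control(s); using the "
            "cohort's cancer samples as the z-score reference",
            stacklevel=2,
        )
        ref_ids, reference = tumor_ids, "cancer_samples"
        if len(ref_ids) < 2:
            raise ValueError("need >= 2 reference samples for z-scores")

    ref = fpkm.values.loc[present, ref_ids]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} signature gene(s) with zero reference SD dropped",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("every signature gene has zero reference SD")
    used = [g for g in present if keep[g]]

    z = fpkm.values.loc[used, tumor_ids].sub(mu[used], axis=0).div(sd[used], axis=0)
    per_sample = z.mean(axis=0)
    per_sample.name = signature.name

    result = SignatureZScore(
        name=signature.name,
        per_sample=per_sample,
        n_genes_used=len(used),
        n_genes_dropped=n_dropped,
        reference=reference,
    )
    if groups is not None:
        groups = groups.reindex(per_sample.index)
        for level in ("A", "B"):
            sel = per_sample[groups == level]
            if len(sel):
                result.group_means[level] = float(sel.mean())
        a = per_sample[groups == "A"].to_numpy()
        b = per_sample[groups == "B"].to_numpy()
        if a.size >= 2 and b.size >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result.p_value = t_test(a, b).p
    return result


def assign_subtypes(decision, scores: pd.DataFrame, is_control) -> pd.DataFrame:
    """Label samples A/B/control from an included clustering decision.

    Of the two candidate cancer clusters the one with the lower mean of
    (immune_score + stromal_score)/2 becomes the immune-deficient
    subtype A and the other the immune-competent subtype B. Controls
    are labeled ``control`` wherever they cluster; cancer samples
    outside the candidate clusters (possible at k = 3) are labeled
    ``none``. Ties in the cluster means resolve to the lower cluster id
    with a warning.
    """
    if decision.status != "included":
        raise ValueError(
            f"cannot assign subtypes for a cohort with status {decision.status!r}"
        )
    scores = scores.copy()
    is_control = pd.Series(np.asarray(is_control, dtype=bool), index=scores.index)
    labels = pd.Series(decision.cluster_labels, index=scores.index)

    mean_score = (scores["immune_score"] + scores["stromal_score"]) / 2.0
    cluster_means = {}
    for cid in decision.cancer_cluster_ids:
        members = (labels == cid) & ~is_control
        cluster_means[cid] = float(mean_score[members].mean())

    cids = sorted(decision.cancer_cluster_ids)
    if len(cids) != 2:
        raise ValueError("expected exactly two candidate cancer clusters")
    if cluster_means[cids[0]] == cluster_means[cids[1]]:
        warnings.warn(
            "tied cluster mean scores; assigning subtype A to the lower "
            "cluster id",
            stacklevel=2,
        )
        a_cluster = cids[0]
    else:
        a_cluster = min(cids, key=lambda c: cluster_means[c])
    b_cluster = cids[0] if a_cluster == cids[1] else cids[1]

    subtype = pd.Series("none", index=scores.index, dtype=object)
    subtype[(labels == a_cluster) & ~is_control] = "A"
    subtype[(labels == b_cluster) & ~is_control] = "B"
    subtype[is_control] = "control"
    scores["subtype"] = subtype
    scores["is_control"] = is_control
    return scores


#: The four TME indicators and the direction expected in the
#: immune-competent subtype B relative to A.
TME_INDICATORS = (
    ("immune_score", "greater"),
    ("stromal_score", "greater"),
    ("cyt", "greater"),
    ("purity", "less"),
)


def tme_criteria_check(scores: pd.DataFrame, alpha: float = 0.05) -> TmeCriteriaResult:
    """Four-score inclusion check between subtypes A and B.

    The cohort is retained iff at least 3 of the 4 indicators (immune,
    stromal, CYT expected higher in B; purity expected lower in B) give
    a two-sided unpaired t-test p < alpha in the expected direction.
    Indicators with degenerate (zero pooled) variance or missing values
    count as non-significant.
    """
    for level in ("A", "B"):
        if int((scores["subtype"] == level).sum()) < 2:
            raise ValueError(f"subtype {level} has fewer than 2 samples")
    rows = []
    n_ok = 0
    for col, direction in TME_INDICATORS:
        a = scores.loc[scores["subtype"] == "A", col].dropna().to_numpy(dtype=float)
        b = scores.loc[scores["subtype"] == "B", col].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            rows.append((col, np.nan, np.nan, False, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = t_test(a, b)
        if res.degenerate:
            rows.append((col, res.t, np.nan, False, False))
            continue
        diff = res.mean_y - res.mean_x  # B minus A
        direction_ok = diff > 0 if direction == "greater" else diff < 0
        significant = bool(res.p < alpha and direction_ok)
        n_ok += significant
        rows.append((col, res.t, res.p, direction_ok, significant))
    details = pd.DataFrame(
        rows, columns=["score", "t", "p", "direction_ok", "significant"]
    ).set_index("score")
    status = "included" if n_ok >= 3 else "excluded_tme_criteria"
    return TmeCriteriaResult(status, n_ok, details)


def geneset_overlap_enrichment(
    query_genes, gene_set: GeneSet, universe_size: int
) -> float:
    """Hypergeometric upper-tail p of the query/set overlap.

    Probability of observing at least the actual overlap when
    ``len(query_genes)`` genes are drawn without replacement from a
    universe of ``universe_size`` containing ``len(gene_set)`` set
    members.
    """
    query = set(query_genes)
    set_genes = set(gene_set.gene_ids)
    if universe_size < len(query) or universe_size < len(set_genes):
        raise ValueError("universe smaller than the query or the gene set")
    overlap = len(query & set_genes)
    return float(
        stats.hypergeom.sf(overlap - 1, universe_size, len(set_genes), len(query))
    )


def read_gmt(path: str | Path, category: str = "marker") -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        sets.append(GeneSet(name=name, category=category, gene_ids=tuple(genes)))
    return sets


def write_gmt(gene_sets, path: str | Path) -> None:
    """Write gene sets to GMT; the description field carries the category."""
    lines = [
        "\t".join([gs.name, gs.category, *gs.gene_ids]) for gs in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
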