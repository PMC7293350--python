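"""Per-cancer-type orchestration and cohort summary tables.

``run_cohort`` drives one cancer type end to end: variance
stabilization, variable-gene selection, complete-linkage clustering at
k = 2 and 3, the separability decision, TME scoring (immune/stromal/
ESTIMATE/purity/CYT), subtype labeling, the four-score inclusion
check, and — where survival and instability covariates are present —
Kaplan-Meier / log-rank / Cox comparisons and burden t-tests.

``summarize_cohort`` reduces a set of per-type results to the subtype
accounting table (per-type subtype-A/B/control counts with a Total
row), the shape of the study's cohort summary.

Every decision rule that fires (exclusion reason, chosen k, which
scores were significant) is logged at INFO so a run's narrative is
auditable from the log alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genomic_instability as gi
from . import preprocess as pp
from . import subtype_clustering as sc
from . import survival_stats as ss
from . import tme_scoring as tme
from .synthetic_data import CohortDataset

__all__ = [
    "PipelineOptions",
    "RunConfig",
    "CohortResult",
    "load_cohort_tsv",
    "run_cohort",
    "run_cohorts",
    "run_pipeline",
    "summarize_cohort",
    "summarize_counts",
]

logger = logging.getLogger("tmetyper")

SUMMARY_COLUMNS = ("n_subtype_A", "n_subtype_B", "n_controls")


@dataclass(frozen=True)
class PipelineOptions:
    """Tunable thresholds of the pipeline, with the documented defaults."""

    n_top_genes: int = 1000
    metric: str = "euclidean"
    control_purity_threshold: float = sc.DEFAULT_CONTROL_PURITY
    min_cancer_cluster: int = sc.DEFAULT_MIN_CANCER
    ssgsea_alpha: float = tme.DEFAULT_SSGSEA_ALPHA
    expression_scale: str = "tpm"  # scale fed to ssGSEA: tpm | vst | fpkm
    criteria_alpha: float = 0.05
    cyt_genes: tuple[str, str] = ("GZMA", "PRF1")
    cyt_offset: float = tme.DEFAULT_CYT_OFFSET

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunConfig:
    """File-driven pipeline configuration (one YAML document).

    ``cohorts`` maps each cancer-type name to its input paths
    (``counts``, ``gene_lengths``, ``sample_sheet``, optional
    ``instability``); ``gene_sets`` points to a GMT whose description
    field carries each set's category (the immune-signature and
    stromal-signature sets are required).
    """

    cohorts: list[dict]
    gene_sets: str | None = None
    options: PipelineOptions = field(default_factory=PipelineOptions)
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        opts = PipelineOptions(**{
            **raw.get("options", {}),
            **(
                {"cyt_genes": tuple(raw["options"]["cyt_genes"])}
                if "cyt_genes" in raw.get("options", {})
                else {}
            ),
        })
        cfg = cls(
            cohorts=raw["cohorts"],
            gene_sets=raw.get("gene_sets"),
            options=opts,
            seed=int(raw.get("seed", 0)),
            outdir=raw.get("outdir"),
        )
        base = Path(path).parent
        for cohort in cfg.cohorts:
            for key in ("counts", "gene_lengths", "sample_sheet", "instability"):
                if key in cohort and cohort[key]:
                    p = base / cohort[key]
                    if not p.exists():
                        raise FileNotFoundError(
                            f"cohort {cohort.get('name')}: missing input {p}"
                        )
                    cohort[key] = str(p)
        if cfg.gene_sets:
            p = base / cfg.gene_sets
            if not p.exists():
                raise FileNotFoundError(f"gene_sets GMT not found: {p}")
            cfg.gene_sets = str(p)
        return cfg


@dataclass
class CohortResult:
    """Everything the pipeline derives for one cancer type."""

    name: str
    status: str
    decision: sc.SubtypeDecision
    scores: pd.DataFrame | None = None
    criteria: tme.TmeCriteriaResult | None = None
    km_curves: dict | None = None
    logrank: ss.LogrankResult | None = None
    cox: ss.CoxFit | None = None
    instability: pd.DataFrame | None = None
    cyt_neo_correlation: dict[str, gi.CorrelationResult] = field(default_factory=dict)
    error: str | None = None

    @property
    def counts(self) -> dict[str, int]:
        """Subtype accounting for the summary table."""
        if self.scores is None:
            return {"n_subtype_A": 0, "n_subtype_B": 0, "n_controls": 0}
        sub = self.scores["subtype"]
        return {
            "n_subtype_A": int((sub == "A").sum()),
            "n_subtype_B": int((sub == "B").sum()),
            "n_controls": int((sub == "control").sum()),
        }


def load_cohort_tsv(
    name: str,
    counts_path: str | Path,
    gene_lengths_path: str | Path,
    sample_sheet_path: str | Path,
) -> CohortDataset:
    """Assemble a CohortDataset from the three standard TSV inputs."""
    counts = pp.read_counts_tsv(counts_path)
    lengths = pp.read_gene_lengths_tsv(gene_lengths_path)
    samples = pd.read_csv(sample_sheet_path, sep="\t").set_index("sample_id")
    if "group" not in samples.columns:
        raise ValueError("sample sheet needs a 'group' column (cancer/control)")
    for col in ("subtype_truth",):
        if col not in samples.columns:
            samples[col] = "none"
    for col in ("infiltration", "os_time", "os_event", "n_segments", "tmb",
                "neoepitope_load"):
        if col not in samples.columns:
            samples[col] = np.nan
    samples = samples.loc[counts.columns]
    return CohortDataset(
        name=name,
        counts=counts,
        gene_lengths=lengths.reindex(counts.index),
        samples=samples,
    )


def _cyt_column(dataset: CohortDataset, tpm: pp.NormalizedMatrix,
                options: PipelineOptions) -> pd.Series:
    g1, g2 = options.cyt_genes
    if g1 in tpm.gene_ids and g2 in tpm.gene_ids:
        return tme.cyt_score(tpm.values.loc[g1], tpm.values.loc[g2],
                             offset=options.cyt_offset)
    warnings.warn(
        f"CYT genes {options.cyt_genes} not in matrix; CYT score undefined",
        stacklevel=2,
    )
    return pd.Series(np.nan, index=tpm.sample_ids, name="cyt")


def _survival_block(result: CohortResult, dataset: CohortDataset) -> None:
    scores = result.scores
    tum = dataset.samples.reindex(scores.index)
    mask = scores["subtype"].isin(["A", "B"]) & tum["os_time"].notna()
    if int(mask.sum()) < 4:
        logger.info("%s: too few samples with survival data; skipped", result.name)
        return
    records = pd.DataFrame(
        {
            "time": tum.loc[mask, "os_time"].astype(float),
            "event": tum.loc[mask, "os_event"].astype(bool),
            "group": scores.loc[mask, "subtype"],
        }
    )
    result.km_curves = ss.km_estimate(records)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result.logrank = ss.logrank_test(records)
        try:
            result.cox = ss.cox_univariate(records)
        except ValueError as exc:
            logger.info("%s: Cox regression skipped (%s)", result.name, exc)
    if result.logrank is not None and result.logrank.defined:
        logger.info(
            "%s: log-rank chi2=%.3f p=%.3g (%s)",
            result.name, result.logrank.statistic, result.logrank.p,
            ss.significance_stars(result.logrank.p),
        )
    if result.cox is not None and not result.cox.converged:
        logger.info(
            "%s: monotone Cox partial likelihood (all events in one arm?)",
            result.name,
        )


def _instability_block(result: CohortResult, dataset: CohortDataset) -> None:
    scores = result.scores
    tum = dataset.samples.reindex(scores.index)
    have = tum[["n_segments", "tmb", "neoepitope_load"]].notna().all(axis=1)
    mask = scores["subtype"].isin(["A", "B"]) & have
    if int(mask.sum()) < 4:
        return
    sub = scores.loc[mask, "subtype"]
    rows = []
    for burden_field in ("n_segments", "tmb"):
        log_vals = gi.log10_burden(tum.loc[mask], burden_field)
        a = log_vals[sub == "A"].to_numpy()
        b = log_vals[sub == "B"].to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gi.compare_burden(a, b)
        rows.append(
            (burden_field, res.mean_x, res.mean_y, res.t, res.p,
             ss.significance_stars(res.p))
        )
    if rows:
        result.instability = pd.DataFrame(
            rows,
            columns=["field", "mean_log10_A", "mean_log10_B", "t", "p", "stars"],
        ).set_index("field")
    for level in ("A", "B"):
        sel = mask & (scores["subtype"] == level)
        cyt = scores.loc[sel, "cyt"]
        neo = tum.loc[sel, "neoepitope_load"]
        ok = cyt.notna() & neo.notna()
        if int(ok.sum()) >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result.cyt_neo_correlation[level] = gi.cyt_neoepitope_correlation(
                    cyt[ok].to_numpy(), neo[ok].to_numpy()
                )


def run_cohort(
    dataset: CohortDataset,
    immune_set: tme.GeneSet | None = None,
    stromal_set: tme.GeneSet | None = None,
    options: PipelineOptions | None = None,
) -> CohortResult:
    """Run the full subtype pipeline on one cohort.

    Gene sets default to the cohort's own (synthetic cohorts carry
    their marker sets); real cohorts must supply both signatures.
    """
    options = options or PipelineOptions()
    immune_set = immune_set or dataset.immune_set
    stromal_set = stromal_set or dataset.stromal_set
    if immune_set is None or stromal_set is None:
        raise ValueError("immune and stromal gene sets are required")

    vst = pp.variance_stabilize(dataset)
    top = pp.select_top_variable_genes(vst, options.n_top_genes)
    dendro = sc.hierarchical_cluster(vst, top, metric=options.metric)
    labels2 = sc.cut_tree(dendro, 2)
    labels3 = sc.cut_tree(dendro, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        decision = sc.evaluate_separability(
            labels2,
            labels3,
            dataset.is_control,
            control_purity_threshold=options.control_purity_threshold,
            min_cancer_cluster=options.min_cancer_cluster,
            cancer_type=dataset.name,
        )
    logger.info("%s: %s (k=%s) — %s", dataset.name, decision.status,
                decision.chosen_k, "; ".join(decision.notes))
    if decision.status != "included":
        return CohortResult(name=dataset.name, status=decision.status,
                            decision=decision)

    fpkm = pp.compute_fpkm(dataset)
    tpm = pp.fpkm_to_tpm(fpkm)
    expr = {"tpm": tpm, "vst": vst, "fpkm": fpkm}[options.expression_scale]
    scores = tme.estimate_scores(expr, immune_set, stromal_set,
                                 alpha=options.ssgsea_alpha)
    scores["purity"] = tme.estimate_purity(scores["estimate_score"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores["cyt"] = _cyt_column(dataset, tpm, options)
        scores = tme.assign_subtypes(decision, scores, dataset.is_control)
        criteria = tme.tme_criteria_check(scores, alpha=options.criteria_alpha)
    logger.info(
        "%s: TME criteria %s (%d/4 directionally significant)",
        dataset.name, criteria.status, criteria.n_directional_significant,
    )

    result = CohortResult(
        name=dataset.name,
        status=criteria.status,
        decision=decision,
        scores=scores,
        criteria=criteria,
    )
    if result.status == "included":
        _survival_block(result, dataset)
        _instability_block(result, dataset)
    return result


def run_cohorts(
    datasets,
    immune_set: tme.GeneSet | None = None,
    stromal_set: tme.GeneSet | None = None,
    options: PipelineOptions | None = None,
) -> list[CohortResult]:
    """Run every cohort, isolating per-cohort failures in the summary."""
    results = []
    for ds in datasets:
        try:
            results.append(run_cohort(ds, immune_set, stromal_set, options))
        except Exception as exc:  # noqa: BLE001 — one cohort must not kill the run
            logger.error("%s: pipeline error: %s", ds.name, exc)
            dummy = sc.SubtypeDecision(
                cancer_type=ds.name,
                chosen_k=None,
                cluster_labels=pd.Series(dtype=int),
                status="error",
            )
            results.append(
                CohortResult(name=ds.name, status="error", decision=dummy,
                             error=str(exc))
            )
    return results


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Add an ``n_total`` column and a ``Total`` row to a counts table.

    ``counts`` is indexed by cancer type with columns ``n_subtype_A``,
    ``n_subtype_B``, ``n_controls`` (and optionally ``status``);
    ``n_total`` is their row sum and the Total row sums each numeric
    column.
    """
    for col in SUMMARY_COLUMNS:
        if col not in counts.columns:
            raise ValueError(f"summary input missing column {col!r}")
    out = counts.copy()
    out["n_total"] = out[list(SUMMARY_COLUMNS)].sum(axis=1)
    total = out[list(SUMMARY_COLUMNS) + ["n_total"]].sum(axis=0)
    total_row = {col: int(total[col]) for col in total.index}
    if "status" in out.columns:
        total_row["status"] = ""
    out.loc["Total"] = pd.Series(total_row)
    for col in list(SUMMARY_COLUMNS) + ["n_total"]:
        out[col] = out[col].astype(int)
    return out


def summarize_cohort(results: list[CohortResult]) -> pd.DataFrame:
    """Cohort summary table over pipeline results (Total row included)."""
    if len(results) == 0:
        raise ValueError("no cohort results to summarize")
    rows = {}
    for res in results:
        row = res.counts
        row["status"] = res.status
        rows[res.name] = row
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index.name = "cancer_type"
    return summarize_counts(counts)


def run_pipeline(config: RunConfig) -> tuple[pd.DataFrame, list[CohortResult]]:
    """File-driven multi-cohort run; writes tables when outdir is set."""
    immune_set = stromal_set = None
    if config.gene_sets:
        # The GMT description field carries each set's category (the
        # convention write_gmt uses).
        immune_set, stromal_set = _sets_from_gmt(config.gene_sets)
    datasets = [
        load_cohort_tsv(
            c["name"], c["counts"], c["gene_lengths"], c["sample_sheet"]
        )
        for c in config.cohorts
    ]
    results = run_cohorts(datasets, immune_set, stromal_set, config.options)
    summary = summarize_cohort(results)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "cohort_summary.tsv", sep="\t")
        meta = {"seed": config.seed, "options": config.options.to_dict()}
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
        for res in results:
            if res.scores is not None:
                res.scores.to_csv(outdir / f"{res.name}.scores.tsv", sep="\t",
                                  index_label="sample_id")
            decision = {
                "cancer_type": res.name,
                "status": res.status,
                "chosen_k": res.decision.chosen_k,
                "notes": res.decision.notes,
            }
            (outdir / f"{res.name}.decision.json").write_text(
                json.dumps(decision, indent=2) + "\n"
            )
    return summary, results


def _sets_from_gmt(path: str | Path) -> tuple[tme.GeneSet, tme.GeneSet]:
    """Pull the immune- and stromal-signature sets out of a GMT file."""
    immune = stromal = None
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, desc, *genes = line.rstrip("\n").split("\t")
        genes = tuple(g for g in genes if g)
        if desc == "immune_signature" and immune is None:
            immune = tme.GeneSet(name, "immune_signature", genes)
        elif desc == "stromal_signature" and stromal is None:
            stromal = tme.GeneSet(name, "stromal_signature", genes)
    if immune is None or stromal is None:
        raise ValueError(
            "GMT must contain one immune_signature and one stromal_signature set"
        )
    return immune, stromal
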