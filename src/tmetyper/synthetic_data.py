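"""Synthetic multi-cancer cohorts with the structure the analysis assumes.

Each cohort mimics one cancer type: bulk RNA-seq counts are drawn from
a negative binomial whose per-sample mean mixes a tumor-intrinsic
expression profile T with an immune/stromal reference profile M
concentrated on a designated block of marker genes,

    mu[g, s] = lib_s * ((1 - f_s) * T_g + f_s * M_g),

where f_s in [0, 1] is the sample's latent infiltration fraction. Two
latent cancer subtypes differ only in the distribution of f (subtype B
is the immune-competent, high-infiltration arm); non-cancer controls
draw f near the subtype-B mean by default (controls co-cluster with the
immune-competent arm), near subtype A behind a flag, or from the tumor
mixture itself for "confounded" cohorts whose controls cannot be
isolated by clustering.

Overall survival is exponential with a subtype-B hazard ratio applied
to the subtype-A baseline, censored by an independent uniform time
calibrated to the requested censoring fraction. Per-sample genomic
instability covariates (CNV segment count, nonsynonymous TMB) are
log-normal with a subtype-dependent location; the neoepitope load is
Poisson with mean proportional to TMB.

Two immune marker genes are named GZMA and PRF1 so the cytolytic
activity score is computable end-to-end on synthetic cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .tme_scoring import GeneSet, write_gmt

__all__ = [
    "SimulationConfig",
    "CohortDataset",
    "generate_cohort",
    "generate_multi_cancer",
]

#: Subtype-A baseline hazard: median overall survival 1,000 days.
BASELINE_HAZARD = np.log(2.0) / 1000.0

#: Log-scale locations of the instability covariates in subtype A.
SEGMENTS_LOG_LOC = np.log(60.0)
SEGMENTS_LOG_SD = 0.4
TMB_LOG_LOC = np.log(2.0)
TMB_LOG_SD = 0.5
NEOEPITOPES_PER_TMB = 15.0

#: Tumor cells express immune/stromal marker genes at this fraction of
#: a typical gene, so infiltration dominates marker expression.
TUMOR_MARKER_ATTENUATION = 0.2

CONTROL_SIDES = ("B", "A", "confounded")


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid SimulationConfig.{fieldname}: {msg}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cancer-type cohort.

    Defaults define the canonical test conditions: a clearly separated
    cohort of 100 tumors per subtype with mean infiltration 0.05 (A)
    (SD 0.05) vs 0.60 (B), 20 controls on the subtype-B side, 2,000 genes of
    which 10% are immune/stromal markers, moderate overdispersion, a
    subtype-B hazard ratio of 2 with 30% censoring, and a +0.5
    log-scale TMB shift in subtype B.
    """

    n_genes: int = 2000
    n_tumor_per_subtype: tuple[int, int] = (100, 100)
    n_controls: int = 20
    infiltration_means: tuple[float, float] = (0.05, 0.60)
    infiltration_sd: float = 0.05
    marker_fraction: float = 0.10
    dispersion: float = 0.20
    library_size_mean: int = 1_000_000
    hazard_ratio: float = 2.0
    censoring_rate: float = 0.30
    tmb_shift: float = 0.5
    seed: int = 0
    control_side: str = "B"

    def __post_init__(self) -> None:
        _require(self.n_genes >= 10, "n_genes", "need at least 10 genes")
        _require(
            len(self.n_tumor_per_subtype) == 2
            and all(n >= 0 for n in self.n_tumor_per_subtype),
            "n_tumor_per_subtype",
            "need a pair of non-negative counts",
        )
        _require(self.n_controls >= 0, "n_controls", "must be >= 0")
        _require(
            len(self.infiltration_means) == 2
            and all(0.0 <= m <= 1.0 for m in self.infiltration_means),
            "infiltration_means",
            "each mean must lie in [0, 1]",
        )
        _require(self.infiltration_sd >= 0.0, "infiltration_sd", "must be >= 0")
        _require(
            0.0 < self.marker_fraction < 1.0,
            "marker_fraction",
            "must lie in (0, 1)",
        )
        _require(
            self.n_genes >= 2 * self.n_marker_genes,
            "marker_fraction",
            f"{self.n_marker_genes} marker genes exceed half of "
            f"{self.n_genes} genes",
        )
        _require(self.dispersion > 0.0, "dispersion", "must be > 0")
        _require(self.library_size_mean > 0, "library_size_mean", "must be > 0")
        _require(self.hazard_ratio > 0.0, "hazard_ratio", "must be > 0")
        _require(
            0.0 <= self.censoring_rate < 1.0, "censoring_rate", "must lie in [0, 1)"
        )
        _require(
            self.control_side in CONTROL_SIDES,
            "control_side",
            f"must be one of {CONTROL_SIDES}",
        )

    @property
    def n_marker_genes(self) -> int:
        return int(round(self.marker_fraction * self.n_genes))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("n_tumor_per_subtype", "infiltration_means"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CohortDataset:
    """One cancer type's counts, gene lengths and per-sample annotations.

    ``samples`` is indexed by sample id with columns ``group``
    (cancer/control), ``subtype_truth`` (A/B/none), ``infiltration``,
    and — tumor samples only — ``os_time``, ``os_event``,
    ``n_segments``, ``tmb``, ``neoepitope_load``.
    """

    name: str
    counts: pd.DataFrame  # genes x samples, non-negative integers
    gene_lengths: pd.Series  # bp per gene
    samples: pd.DataFrame
    immune_set: GeneSet | None = None
    stromal_set: GeneSet | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts contain negative entries")
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("counts columns and sample sheet index disagree")
        if not self.counts.index.equals(self.gene_lengths.index):
            raise ValueError("counts rows and gene-length index disagree")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate gene or sample ids")
        tum = self.samples[self.samples["group"] == "cancer"]
        if "os_time" in tum.columns and (tum["os_time"].dropna() <= 0).any():
            raise ValueError("tumor os_time must be positive")
        infl = self.samples["infiltration"]
        if ((infl < 0) | (infl > 1)).any():
            raise ValueError("infiltration outside [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def is_control(self) -> pd.Series:
        return self.samples["group"] == "control"

    @property
    def tumor_ids(self) -> pd.Index:
        return self.samples.index[~self.is_control]

    @property
    def control_ids(self) -> pd.Index:
        return self.samples.index[self.is_control]

    @property
    def true_subtype(self) -> pd.Series:
        return self.samples["subtype_truth"]

    def survival_records(self) -> pd.DataFrame:
        """Tumor-sample survival table keyed by the *true* subtype."""
        tum = self.samples.loc[self.tumor_ids]
        return pd.DataFrame(
            {
                "time": tum["os_time"].astype(float),
                "event": tum["os_event"].astype(bool),
                "group": tum["subtype_truth"],
            }
        )

    def to_tsv(self, outdir: str | Path) -> dict[str, Path]:
        """Write counts, sample sheet, gene lengths and marker GMT."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / f"{self.name}.counts.tsv",
            "samples": outdir / f"{self.name}.samples.tsv",
            "gene_lengths": outdir / f"{self.name}.gene_lengths.tsv",
        }
        self.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
        sheet = self.samples.reset_index(names="sample_id")
        sheet.to_csv(paths["samples"], sep="\t", index=False)
        self.gene_lengths.rename("length_bp").to_csv(
            paths["gene_lengths"], sep="\t", index_label="gene_id"
        )
        if self.immune_set is not None and self.stromal_set is not None:
            paths["gene_sets"] = outdir / f"{self.name}.gene_sets.gmt"
            write_gmt([self.immune_set, self.stromal_set], paths["gene_sets"])
        return paths


def _truncated_normal(rng, mean, sd, size):
    return np.clip(rng.normal(mean, sd, size=size), 0.0, 1.0)


def _censoring_horizon(hazards: np.ndarray, rate: float) -> float:
    """Uniform-censoring horizon u with E[fraction censored] = rate.

    For an exponential event time with hazard h censored by C ~ U(0, u)
    the censoring probability is (1 - exp(-h u)) / (h u); the horizon
    is solved on the cohort's mixture of hazards.
    """

    def frac(u: float) -> float:
        x = hazards * u
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1e12
    return float(brentq(lambda u: frac(u) - rate, lo, hi, xtol=1e-6, rtol=1e-12))


def generate_cohort(config: SimulationConfig, name: str = "SYN") -> CohortDataset:
    """Draw one synthetic cohort; bit-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    n_markers = config.n_marker_genes
    n_a, n_b = config.n_tumor_per_subtype
    n_c = config.n_controls
    n_samples = n_a + n_b + n_c
    if n_samples == 0:
        raise ValueError("invalid SimulationConfig: no samples requested")

    width = max(4, len(str(n_genes)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(n_genes)], dtype=object)
    marker_idx = rng.choice(n_genes, size=n_markers, replace=False)
    immune_idx = np.sort(marker_idx[: n_markers // 2])
    stromal_idx = np.sort(marker_idx[n_markers // 2 :])
    # Name two immune markers after the cytolytic-activity genes.
    if immune_idx.size >= 2:
        gene_ids[immune_idx[0]] = "GZMA"
        gene_ids[immune_idx[1]] = "PRF1"

    marker_mask = np.zeros(n_genes, dtype=bool)
    marker_mask[marker_idx] = True

    # Tumor-intrinsic profile: log-normal abundances, markers attenuated.
    t_prof = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    t_prof[marker_mask] *= TUMOR_MARKER_ATTENUATION
    t_prof /= t_prof.sum()
    # Immune/stromal reference profile lives on the marker block.
    m_prof = np.zeros(n_genes)
    m_prof[marker_mask] = rng.lognormal(mean=0.0, sigma=1.0, size=n_markers)
    m_prof /= m_prof.sum()

    mean_a, mean_b = config.infiltration_means
    f = np.concatenate(
        [
            _truncated_normal(rng, mean_a, config.infiltration_sd, n_a),
            _truncated_normal(rng, mean_b, config.infiltration_sd, n_b),
            _control_infiltration(rng, config, n_c),
        ]
    )
    subtype = np.array(["A"] * n_a + ["B"] * n_b + ["none"] * n_c, dtype=object)
    group = np.array(["cancer"] * (n_a + n_b) + ["control"] * n_c, dtype=object)
    sample_ids = [f"{name}-{'T' if g == 'cancer' else 'N'}{i:04d}"
                  for i, g in enumerate(group)]

    lib = rng.normal(config.library_size_mean, 0.05 * config.library_size_mean,
                     size=n_samples)
    lib = np.maximum(lib, 0.1 * config.library_size_mean)

    mu = lib[None, :] * ((1.0 - f)[None, :] * t_prof[:, None]
                         + f[None, :] * m_prof[:, None])
    r = 1.0 / config.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    lengths = np.round(
        np.exp(rng.uniform(np.log(500.0), np.log(10_000.0), size=n_genes))
    ).astype(int)

    samples = pd.DataFrame(
        {
            "group": group,
            "subtype_truth": subtype,
            "infiltration": f,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    n_t = n_a + n_b
    for col in ("os_time", "os_event", "n_segments", "tmb", "neoepitope_load"):
        samples[col] = np.nan
    if n_t > 0:
        is_b = (subtype[:n_t] == "B").astype(float)
        hazards = BASELINE_HAZARD * config.hazard_ratio**is_b
        event_t = rng.exponential(1.0 / hazards)
        if config.censoring_rate > 0.0:
            horizon = _censoring_horizon(hazards, config.censoring_rate)
            censor_t = rng.uniform(0.0, horizon, size=n_t)
        else:
            censor_t = np.full(n_t, np.inf)
        os_time = np.maximum(np.minimum(event_t, censor_t), 1e-6)
        os_event = event_t <= censor_t

        seg = rng.lognormal(
            SEGMENTS_LOG_LOC + config.tmb_shift * is_b, SEGMENTS_LOG_SD
        )
        n_segments = np.maximum(np.round(seg), 1.0)
        tmb = rng.lognormal(TMB_LOG_LOC + config.tmb_shift * is_b, TMB_LOG_SD)
        neo = rng.poisson(NEOEPITOPES_PER_TMB * tmb).astype(float)

        tumor_loc = samples.index[:n_t]
        samples.loc[tumor_loc, "os_time"] = os_time
        samples.loc[tumor_loc, "os_event"] = os_event.astype(float)
        samples.loc[tumor_loc, "n_segments"] = n_segments
        samples.loc[tumor_loc, "tmb"] = tmb
        samples.loc[tumor_loc, "neoepitope_load"] = neo

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples.index)
    lengths_s = pd.Series(lengths, index=counts_df.index, name="length_bp")

    immune_set = stromal_set = None
    if immune_idx.size and stromal_idx.size:
        immune_set = GeneSet(
            name=f"{name}_immune",
            category="immune_signature",
            gene_ids=tuple(gene_ids[immune_idx]),
        )
        stromal_set = GeneSet(
            name=f"{name}_stromal",
            category="stromal_signature",
            gene_ids=tuple(gene_ids[stromal_idx]),
        )

    return CohortDataset(
        name=name,
        counts=counts_df,
        gene_lengths=lengths_s,
        samples=samples,
        immune_set=immune_set,
        stromal_set=stromal_set,
    )


def _control_infiltration(rng, config: SimulationConfig, n_c: int) -> np.ndarray:
    """Control infiltration: near one subtype's mean, or the tumor mixture."""
    mean_a, mean_b = config.infiltration_means
    if n_c == 0:
        return np.empty(0)
    if config.control_side == "confounded":
        pick_b = rng.random(n_c) < 0.5
        means = np.where(pick_b, mean_b, mean_a)
        return _truncated_normal(rng, means, config.infiltration_sd, n_c)
    mean = mean_b if config.control_side == "B" else mean_a
    return _truncated_normal(rng, mean, config.infiltration_sd, n_c)


def generate_multi_cancer(
    configs: dict[str, SimulationConfig] | list[tuple[str, SimulationConfig]],
    confound_controls: dict[str, bool] | list[bool] | None = None,
) -> list[CohortDataset]:
    """Generate several cancer-type cohorts, optionally confounding controls.

    Cohorts flagged in ``confound_controls`` draw their control
    expression from the same tumor mixture (both subtype means), so
    downstream clustering cannot isolate the controls and the
    separability rules exclude the cohort.
    """
    if isinstance(configs, dict):
        items = list(configs.items())
    else:
        items = list(configs)
    if len(items) == 0:
        raise ValueError("generate_multi_cancer needs at least one config")
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ValueError(f"duplicate cancer-type name {dup!r}")

    if confound_controls is None:
        flags = {name: False for name in names}
    elif isinstance(confound_controls, dict):
        flags = {name: bool(confound_controls.get(name, False)) for name in names}
    else:
        if len(confound_controls) != len(items):
            raise ValueError("confound_controls length mismatch")
        flags = dict(zip(names, map(bool, confound_controls)))

    cohorts = []
    for name, cfg in items:
        if flags[name]:
            cfg = dataclasses.replace(cfg, control_side="confounded")
        cohorts.append(generate_cohort(cfg, name=name))
    return cohorts
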