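# tmetyper

Transcriptome-driven immune subtyping of the tumor microenvironment
(TME) for bulk RNA-seq cancer cohorts — a tested, reusable
implementation of the full analysis path from raw count matrices to
immune-deficient / immune-competent subtypes and their clinical and
genomic contrasts.

## The problem and who this is for

Immune checkpoint inhibitors work for a minority of patients, and
single biomarkers (checkpoint-gene expression, mutation burden) are
poor selectors in many cancer types. A transcriptome-only alternative
is to stratify each cancer cohort by its tumor microenvironment:
cluster tumors and non-cancer controls on expression, keep only
cohorts where the clustering yields clean cancer subtypes, and label
the subtypes by their inferred immune and stromal infiltration. The
immune-competent subtype (high infiltration) is then contrasted with
the immune-deficient one on survival, genomic instability, and
checkpoint-gene expression. `tmetyper` is for computational biologists
who want that pipeline as a library and CLI with every statistical
component specified, seeded and tested — including a synthetic-cohort
generator so the whole path runs without any data download.

## What it computes

For each cohort (genes × samples counts, gene lengths, sample sheet):

- **Normalization** — FPKM, TPM (`TPM_gs = FPKM_gs / Σ_g FPKM_gs × 10⁶`),
  and a variance-stabilized scale (median-of-ratios size factors,
  then log2(x+1)); log2 median-centered FPKM for heatmap-style output.
- **Subtype discovery** — complete-linkage hierarchical clustering of
  samples on the 1,000 most variable genes, trees cut at k = 2 and 3,
  with inclusion rules: a cohort is excluded when its controls
  scatter across clusters (`excluded_controls_split`) or a candidate
  subtype holds fewer than 2 cancer samples
  (`excluded_singleton_cluster`). PCA embedding with 95% confidence
  ellipses for visualization.
- **TME scoring** — per-sample single-sample gene-set enrichment
  (ssGSEA, rank weight `rank^0.25`) of immune and stromal signatures;
  ESTIMATE score = immune + stromal; tumor purity
  `cos(0.6049872018 + 0.0001467884 × ESTIMATE)` (Yoshihara et al.
  2013); cytolytic activity `CYT = √((GZMA+0.01)(PRF1+0.01))` on TPM
  (Rooney et al. 2015); marker-signature z-scores against control
  mean/SD on FPKM. The lower-scoring cluster becomes subtype A
  (immune-deficient), the higher subtype B (immune-competent); a
  cohort is retained when ≥ 3 of the 4 indicators (immune, stromal,
  CYT up in B; purity down in B) are directionally significant at
  p < 0.05.
- **Survival & genomic instability** — Kaplan-Meier curves, log-rank
  test and univariate Cox regression (HR with 95% CI) between
  subtypes, implemented from first principles; unpaired t-tests on
  log10 CNV-segment counts and log10(TMB+1); Pearson correlation of
  CYT with neoepitope load.
- **Synthetic cohorts** — negative-binomial counts whose mean mixes a
  tumor-intrinsic profile with an immune/stromal marker profile via a
  per-sample latent infiltration fraction; two subtypes differing in
  infiltration; controls; exponential survival with a configurable
  hazard ratio; subtype-shifted TMB/segment/neoepitope covariates.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from tmetyper import SimulationConfig, generate_multi_cancer, run_cohorts, summarize_cohort
from tmetyper.survival_stats import significance_stars

configs = [("SYN1", SimulationConfig(seed=1)),
           ("SYN2", SimulationConfig(seed=2)),
           ("CONF", SimulationConfig(seed=3))]
cohorts = generate_multi_cancer(configs, {"SYN1": False, "SYN2": False, "CONF": True})
results = run_cohorts(cohorts)
print(summarize_cohort(results)[["n_subtype_A", "n_subtype_B", "n_controls", "n_total", "status"]])
for res in results:
    if res.cox is not None:
        lo, hi = res.cox.ci95
        print(f"{res.name}: log-rank p={res.logrank.p:.2e} "
              f"({significance_stars(res.logrank.p)}), "
              f"Cox HR={res.cox.hr:.2f} (95% CI {lo:.2f}-{hi:.2f})")
```

prints

```
             n_subtype_A  n_subtype_B  n_controls  n_total                   status
cancer_type
SYN1                 100          100          20      220                 included
SYN2                 100          100          20      220                 included
CONF                   0            0           0        0  excluded_controls_split
Total                200          200          40      440
SYN1: log-rank p=5.71e-11 (****), Cox HR=3.18 (95% CI 2.21-4.57)
SYN2: log-rank p=7.65e-04 (***), Cox HR=1.77 (95% CI 1.26-2.47)
```

The two clean cohorts are retained and split perfectly into their
true 100/100 subtypes; the cohort whose controls were drawn from the
tumor mixture is excluded because no tree cut concentrates its
controls. Both retained cohorts were simulated with a true
subtype-B hazard ratio of 2, so the immune-competent arm shows the
expected worse survival (single-cohort HR estimates scatter around 2;
a 20-replicate recovery run in the acceptance script averages 1.99).

The same pipeline runs from the shell:

```sh
tmetyper simulate --name SYN1 --seed 1 --out sim/
tmetyper run --config run.yaml --out results/ --plot
tmetyper score --counts counts.tsv --gene-lengths lengths.tsv \
               --gene-sets sets.gmt --out scores.tsv
tmetyper survival --records survival.tsv
```

Real cohorts are supplied as TSVs (counts, two-column gene lengths,
sample sheet with a cancer/control `group` column, optional survival
and instability columns) plus a GMT whose description field marks the
`immune_signature` and `stromal_signature` sets.

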