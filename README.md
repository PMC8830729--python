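# migragen

Partial migration — migrant and resident individuals coexisting in one
population — and its genetic basis, as a tested, reusable pipeline.
Given GPS telemetry and a biallelic SNP matrix for the same animals,
`migragen`:

1. **classifies movement** — thins tracks to daily fixes, builds 95%
   fixed-kernel seasonal ranges, computes the Index of Overlap
   IO = 2·A₁₂/(A₁+A₂), and classifies each animal-year by AIC selection
   among five net-squared-displacement (NSD) models (migrant,
   mixed-migrant, disperser, nomad, resident; migrant residence bounded
   at ρ ≥ 30 days) from a data-chosen reference point (rNSD);
2. **resolves population structure** — genotype QC (call rate ≥ 0.90,
   MAF > 0.05, HWE exact test p ≥ 0.001, LD pruning 50/5/0.5,
   individual missingness ≤ 85%), centred relatedness matrix, PCA,
   maximum-likelihood admixture (EM) with 5-fold cross-validation over
   K, and Weir–Cockerham F_ST with a bootstrap CI;
3. **tests association** — a univariate linear mixed model per SNP with
   the relatedness matrix as the polygenic covariance, Wald tests,
   Bonferroni adjustment, genomic inflation factors, per-SNP variance
   explained (PVE) with 100%-renormalization over the significant set,
   and exon/intron/promoter/intergenic annotation;
4. **regresses behaviour on ancestry** — IO ~ Q (linear) and
   migrant-status ~ Q (logistic), with ecotype-random-intercept
   variants and Kruskal–Wallis / Wilcoxon group comparisons.

A synthetic-data generator (`migragen.simulate`) produces cohorts with
known truth — Balding–Nichols ancestral divergence, admixed genotypes,
a liability-scale migration phenotype, and daily GPS tracks — so every
stage is testable without field data.

The audience is movement ecologists and conservation geneticists who
have telemetry plus reduced-representation genotypes for the same
individuals and want the full behaviour-to-genotype chain with explicit,
configurable thresholds.

## Worked example

Simulate a small cohort (24 animals, 500 SNPs, two ancestral
populations at divergence 0.2, 2% of daily fixes missing) and run every
stage:

```python
from migragen.simulate import SimulationConfig, write_fixture_set
from migragen.pipeline import PipelineConfig, run_pipeline

paths = write_fixture_set(
    SimulationConfig(n_individuals=24, n_snps=500, n_causal=10,
                     fst_divergence=0.2, n_years=1,
                     missing_fix_rate=0.02, seed=7),
    "demo_fixtures",
)
cfg = PipelineConfig(
    telemetry=paths["telemetry"], vcf=paths["vcf"],
    ecotype_table=paths["truth"],
    out_dir="out", max_gap_days=7, k_range=(2,), seed=3,
)
run_pipeline(cfg)
```

(The same fixture comes from the command line via
`migragen simulate --seed 7 --out demo_fixtures --n-individuals 24
--n-snps 500`, and the stages via `migragen all --config config.yaml`.)

`out/movement_metrics.tsv` (first rows):

```
 animal_id  io nsd_class  distance_km  timing_day
animal_000 0.0   migrant      47.5753     156.572
animal_001 0.0   migrant      43.8480     151.645
animal_002 0.0   migrant      44.9845     131.122
animal_003 0.0   migrant      45.6437     139.407
```

These animals were simulated as migrants with seasonal ranges 50 km
apart and daily position noise of 5 km: their overlap index is 0 (fully
separated 95% ranges), the recovered migration distance sqrt(δ̂) sits
within a few km of the true 50, and departure timing lands near the
simulated mid-May schedule (day ~135–155).  `out/popgen_summary.json`
reports the structure stage:

```json
{
 "selected_k": 2,
 "fst": {"estimate": 0.0637, "ci_low": 0.0508, "ci_high": 0.0766},
 "cluster_sizes": [12, 12]
}
```

Cross-validation picks the simulated K = 2, and the Weir–Cockerham F_ST
between the two argmax-Q clusters is 0.064 — well below the ancestral
divergence of 0.2 that two *pure* populations would show, because these
individuals are admixed and cluster assignment mixes ancestries.  `out/ancestry_regressions.tsv` holds the
behaviour-on-ancestry table — at this toy size the ancestry effect is
not detectable (IO ~ q1: β = 0.117, se = 0.173, p = 0.508, n = 22);
study-scale recovery of the regression effects is what the reproduction
script below verifies.  `out/assoc_*.tsv` carry the per-SNP mixed-model
scans and `out/genomic_inflation.json` the λ_GC per phenotype.

Every stage writes a `manifest_<stage>.json` with SHA-256 input hashes
and the full config echo; a rerun with the same seed and inputs is
byte-identical.

## Layout

```
src/migragen/
  simulate.py     synthetic cohorts with persisted ground truth
  telemetry.py    CSV ingestion, equal-area projection, thinning, screening
  movement.py     kernel UD, isopleths, IO, NSD model family (MovementModel)
  popgen.py       QC filters, GRM, PCA, AdmixtureModel, F_ST, MAF tests
  association.py  MixedLMM scan, inflation, PVE, SNP annotation
  ancestry.py     behaviour ~ Q regressions, ecotype comparisons
  validation.py   simulation experiments behind the acceptance checks
  pipeline.py     stage orchestration, manifests, TSV/JSON outputs
  cli.py          `migragen` command line
docs/methods.md   models, defaults, numerical choices, limitations
```

See `docs/methods.md` for the model equations, parameter defaults and
what the synthetic cohort does and does not emulate.
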