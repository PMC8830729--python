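# Methods

`migragen` links individual migratory behaviour of GPS-collared animals
to genome-wide SNP variation.  This note documents the models, the
numerical choices, what the synthetic cohort does and does not emulate,
and the known limitations.

## Movement phenotypes

**Daily thinning and projection.**  Collars record at heterogeneous
intervals; every track is reduced to at most one fix per calendar day,
keeping the fix nearest local noon (ties go to the earlier fix — a
deterministic, biologically neutral rule).  Geographic coordinates are
projected once, for the whole dataset, onto a Lambert azimuthal
equal-area plane (spherical Earth, R = 6371.0088 km) centred on the data
centroid, so inter-animal distances and centroids are comparable in km.
A per-animal projection was rejected because it would break centroid
comparisons across animals.

**Seasons and screening.**  Summer is 1 July–15 September; winter is
1 December–30 April.  Winter spans the year boundary; December fixes are
keyed to the season-year of the following January–April block so each
winter is one contiguous block under one key (a season-year therefore
pairs a winter with the following summer).  The overlap index requires
at least 30 locations in each season of a season-year and at least one
year of monitoring.  Movement-model classification requires a calendar
year of coverage whose fix spacing never exceeds `max_gap_days`
(default 1, i.e. literally daily; real collars drop fixes, so the limit
is configurable and the synthetic data exercise both branches).

**Utilization distributions and the overlap index.**  Seasonal ranges
are 95% isopleths of a bivariate Gaussian kernel density with the
reference bandwidth h_ref = 0.5·(sd_x + sd_y)·n^(−1/6) on a grid with
cell h_ref/4 (grid-based, not exact level sets; the isopleth threshold
is the largest density level whose super-level set holds ≥ 95% of the
mass, polygonised by marching squares with contained contours treated
as holes).  The Index of Overlap is IO = 2·A12/(A1 + A2) ∈ [0, 1]
(0 = fully separated seasonal ranges, migrant-like; 1 = identical,
resident-like), averaged across years per animal.

**NSD model family and classification.**  The daily net squared
displacement (km², from a reference fix) is fit by five models:

    migrant(t)       = d/(1+exp((θ−t)/φ)) − d/(1+exp((t₂−t)/φ₂))
    mixed-migrant(t) = d/(1+exp((θ−t)/φ)) − (d−d₂)/(1+exp((t₂−t)/φ₂))
    disperser(t)     = d/(1+exp((θ−t)/φ))
    nomad(t)         = 4·D·t
    resident(t)      = γ,            t₂ = θ + 2φ + ρ + 2φ₂

with the residence time on the second range bounded ρ ≥ 30 days.  Fits
are trust-region nonlinear least squares with data-driven multi-starts
(d₀ from the 95th percentile of a smoothed series, θ₀ from the first
half-maximum crossing); models are compared by AIC = n·ln(RSS/n) + 2k
with k = #parameters + 1 (AIC, not AICc: at n ≈ 365 the correction is
negligible and an identical Gaussian error model keeps AICs comparable).
Ties prefer the simpler model.  The reference point is chosen from the
first 60 daily fixes (subsampling stride configurable — the default
pipeline stride is 10 days, which we found sufficient; the exhaustive
stride-1 search remains available) as the candidate whose best model has
the lowest AIC — this matters both for tracks that start mid-migration
and for residents, where a noon-noise outlier as reference inflates the
series' apparent structure.

A year is called migrant if the minimum-AIC model is migrant or
mixed-migrant (both are round-trip shapes), resident if resident;
disperser and nomad years are flagged and excluded from the binary
phenotype rather than forced into either class.  Animals whose usable
years disagree are switchers and are excluded from association input,
since a genotype is fixed for life.  Migration distance is sqrt(d) km,
timing the departure inflection θ as a numeric day (1 Jan = 1); both are
averaged across years.  The centroid distance between the seasonal
isopleths and the latitudinal shift (summer − winter centroid latitude,
by inverse projection; for inputs already on a km plane, northing/111.19)
are reported alongside, because "migration distance" can mean either.

## Genotype QC and population structure

Genotypes are biallelic dosages in {0, 1, 2, missing} read from VCF
(multiallelic records skipped with a warning).  The filter chain, with
defaults matching standard practice for RAD-seq cohorts: individuals
with > 85% missingness are dropped; loci need call rate ≥ 0.90 and
MAF strictly > 0.05; LD pruning slides a 50-locus window by 5, removing
the lower-MAF locus (tie: later position) of any pair with genotype
r² > 0.5 — this "LD set" feeds the relatedness matrix; a Hardy–Weinberg
exact-test filter (p ≥ 0.001, two-sided, conditional-on-allele-counts
exact test) then forms the "neutral set" used for PCA, admixture and
F_ST.  All thresholds live in the pipeline config.

**Relatedness.**  K = XXᵀ / Σⱼ 2fⱼ(1−fⱼ) with X the 2f-centred,
mean-imputed dosage matrix (VanRaden scaling, so the diagonal mean is
≈ 1 under Hardy–Weinberg).  The scaling is irrelevant to the mixed
model, which profiles a free variance ratio.

**PCA** standardizes by sqrt(2f(1−f)) (monomorphic loci skipped) and
eigendecomposes the individual covariance.

**Admixture.**  The binomial-mixture likelihood
L = Σᵢⱼ [gᵢⱼ ln(QF)ᵢⱼ + (2−gᵢⱼ) ln(1−(QF)ᵢⱼ)] over observed entries is
maximized by plain EM (block-accelerated schemes were deliberately left
out for simplicity and testability); the log-likelihood is monotone
non-decreasing and asserted so in the suite.  Frequencies are clipped to
[1e-6, 1−1e-6].  Default convergence is an absolute log-likelihood gain
below 1e-6, checked every 10 iterations, with 5 restarts; the heavy
validation experiments use tol 1e-4, ≤ 500 iterations and 1–2 restarts,
which we verified leaves Q-recovery and K-selection unchanged — only the
likelihood tail differs.  The EM works in float32: it is memory-bound
and the surface is flat far above float32 resolution.  K is chosen by
5-fold cross-validation that masks a random fifth of observed genotype
entries and scores masked entries by binomial deviance against the
predicted dosage 2·(QF); this masked-entry loss is our choice — the
reference tool's exact CV loss is not published.  Individuals are
assigned to argmax-Q clusters (ties to the lower index, flagged).

**F_ST.**  Weir–Cockerham (1984) variance components, ratio of averages
across loci; the 95% CI is a percentile bootstrap over loci (default
10,000 resamples).  The bootstrap choice is ours; on Balding–Nichols
cohorts the estimator recovers the divergence parameter (the suite
checks F = 0.05 within [0.04, 0.06] and a null split within ±0.005).

## Mixed-model association

Each SNP is tested in y = Wα + xβ + u + ε with u ~ N(0, σ²λK),
ε ~ N(0, σ²I), intercept-only W.  K is eigendecomposed once; after
rotation the generalized least squares collapses to weighted sums, so a
whole scan is vectorized.  λ is profiled on a 61-point log₁₀ grid over
[1e-5, 1e5] with refinement (Brent for the null; parabolic interpolation
per SNP under the alternative, which is the default — a null-λ reuse
switch exists).  The profile uses the **restricted** likelihood: the
centred relatedness matrix has a zero eigenvalue exactly aligned with
the intercept, under which the ML profile of λ increases without bound
(a ½·ln λ artifact); REML is flat there and recovers a simulated
variance ratio within a factor of two (checked in the suite).

Wald statistics (β̂/se)² are referred to χ²(1), with se² from
σ̂² = RSS_w/(n−p).  The binary migrant/resident phenotype goes through
the same linear model on 0/1 (a logistic mixed model is out of scope);
missing genotypes are mean-imputed per locus; monomorphic SNPs are
skipped with a reason.  Bonferroni: p_adj = min(1, p·m), significant if
< 0.05.  The genomic inflation factor is the median observed χ² over
the χ²(1) median (0.4549, used exactly).  Per-SNP variance explained is

    PVE = 2β²f(1−f) / (2β²f(1−f) + se(β)²·2n·f(1−f))

and the significant set is renormalized to percentages summing to 100.
SNPs are annotated exon > intron > promoter (within 2,000 bp upstream of
a gene start, strand-aware, against a user-supplied BED-like table with
0-based half-open intervals) > intergenic.

## Ancestry regressions

One Q column at a time (Q is compositional — the columns of a K=2 fit
are mirror images): OLS for the overlap index, ML logistic regression
for migrant status (perfect separation is flagged, never silently
divergent), and random-intercept-per-ecotype variants fit by ML — the
linear case via profile likelihood, the logistic case by adaptive
Gauss–Hermite quadrature with 15 nodes (per-group Newton mode finding).
A variance estimate indistinguishable from zero (below 1e-3 of the
response variance, or σ² < 1e-3 on the log-odds scale) is reported as
exactly 0 with a flag, and the fixed-model estimates are reported —
at the boundary the mixed model *is* the fixed model.  McFadden's
pseudo-R² is reported for logistic fits.  Ecotype group comparisons use
Kruskal–Wallis plus pairwise two-sided Wilcoxon rank-sum tests (exact
below 20 per group and tie-free; otherwise the normal approximation
without continuity correction, which preserves the χ² = z² identity with
Kruskal–Wallis at two groups); pairwise p-values are deliberately not
multiplicity-corrected, with a correction switch in config.

## Synthetic cohort

The generator emulates a two-lineage partial-migration cohort end to
end with persisted
truth: 190 individuals admixed between K = 2 ancestral populations
(Balding–Nichols divergence — base frequency p ~ U(0.05, 0.95), population
frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) — so the F_ST estimator has a
known target; default per-population divergence 0.017, the magnitude of
weakly diverged wild lineages), Dirichlet(0.5) admixture
proportions, 28,000 biallelic SNPs drawn Binomial(2, QF), and 57 causal
loci.  The migration liability is

    ℓᵢ = 0.55 + 1.81·Qᵢ,north + Σ_c 0.2·(g_ic − ḡ_c),

logistic into migrant status (the default log-odds ancestry effect is
1.81 and a ≈ 0.8 migrant fraction; causal dosages are
centred so the intercept controls the baseline independently of allele
frequencies).  The overlap index is drawn directly — Beta(2, 8) for
migrants, Beta(8, 2) for residents (means 0.2/0.8; the real within-class
IO distributions are unpublished, so these stand-ins are exposed in the
config) — and also *emerges* from the tracks via the kernel-UD/isopleth
machinery; tests state which path they use.  Tracks are one fix per day
at 12:00 on a projected km plane (a synthetic CRS label exercises the
reader's pass-through branch): position = active seasonal centre +
isotropic Gaussian noise (sd 5 km); migrants move 50 km between centres
on a logistic schedule (scale 3 days) around departure day 135 and
return day 290 (jitter sd 10 days), with the return clamped to at least
30 days plus four transition scales after departure so the migrant
model's ρ ≥ 30 constraint is satisfiable; residents hold one centre.
Fixes drop out at a 5% missing rate by default.  Ecotype labels are
drawn from noisy ancestry quantiles, giving groups that track ancestry
with overlap.

What the generator does **not** emulate: linkage between loci (SNPs are
independent given ancestry, so LD pruning is exercised only by planted
duplicates), genotyping error and allelic dropout, collar failure
clustering (missing fixes are independent), terrain- or memory-driven
movement, sex differences, and within-class correlation between IO and
migration distance.  Passing tests therefore demonstrate correctness of
the estimators under the stated models, not robustness to these realities.

## Validation experiments and problem sizes

`migragen.validation` packages the recurring experiments; the suite and
`scripts/acceptance.py` run them at these sizes: movement classification
on 20 migrants + 20 residents per seed (50 km separation, 5 km daily sd,
reference search over the first 60 days at stride 20 with 2 multistarts)
over 10 seeds in the suite and 5 in the script; mixed-model calibration
at n = 190, m = 2,000 over 10 seeds with an ancestry-aligned share of
20% of phenotype variance (the generator's own ancestry dependence of
behaviour, R-squared scale ~0.18)
and polygenic heritability 0.5 of the rest; admixture recovery at
n = 190, m = 5,000, F_ST = 0.15 with CV over K ∈ {1, 2, 3} for 10 seeds;
F_ST at two groups of 100 and m = 10,000; regression coverage at the
generator's default effect magnitudes over 100 seeds.

## Known limitations

- The five NSD model equations are not published by the classification
  tool the field uses; the forms above follow the movement-model family
  those names denote and are the package's single largest inference.
- The binary phenotype through a linear mixed model inherits that
  tool's behaviour: λ_GC for binary and migrant-only phenotypes at small
  n can sit far from 1 without indicating miscalibration.
- Grid-based isopleths converge with cell size; at the default
  h_ref/4 the bivariate-normal 95% area is recovered within ~3%.
- The EM admixture fit is slower than accelerated implementations and
  meant for cohorts of this order (hundreds of individuals × tens of
  thousands).
- IO from kernel ranges is bounded away from tiny values only by grid
  resolution; fully disjoint ranges give exactly 0.
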