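# Methods

This note documents the statistical machinery of `eggcomp`, the modelling
choices behind it, and what the synthetic-data generator does and does not
emulate.

## The study design being emulated

The pipeline targets a within-clutch egg-composition study in a wild blue
tit population: 39 clutches sampled in one breeding season, with the 1st and
9th egg collected from every clutch and every second egg (odd laying
positions) from 10 of them — 114 eggs in total. Each egg contributes two
proteome samples (albumen and yolk), measured label-free in 1–3 technical
LC–MS replicate runs assigned to batches in a randomised block, plus
gravimetric yolk lipids and HPLC carotenoid concentrations. Life-history
covariates are female age (yearling/adult), lay date, clutch size, egg
weight, laying order, embryo sex and paternity (within-pair/extra-pair,
with extra-pair paternity occurring only among first-laid eggs).

## Synthetic data generator (`synthdata`)

The generator's defaults are the study conditions; they are parameters of a
`StudyConfig`, not tuning knobs.

* **Design.** Clutch sizes are drawn on 9–15 (the species range is 7–15,
  but a sampled clutch must contain a 9th egg; fully sampled clutches are
  capped at 14 so that sampled laying orders stay within {1, …, 13}, the
  range the categorization scheme covers). When `target_n_eggs` is set
  (default 114) the fully-sampled clutch sizes are nudged in steps of two
  eggs until the sampled-egg count matches exactly, emulating the fixed
  size of the real collection. Extra-pair paternity is Bernoulli(13/37) on
  first eggs only, so that the overall extra-pair share of assigned eggs is
  ~12%; one random clutch has an unknown social father (paternity
  "unknown"). Lay dates are uniform integers over a 12-day window (a short,
  synchronous season); embryo sex is a fair coin independent of everything
  else.
* **Egg weight** is Gaussian around 1.16 g with total SD 0.11 g: a
  clutch-size trend of −0.029 g per additional egg, an age-dependent
  laying-order slope (+0.006 g/position for yearlings, −0.006 for adults),
  a female random intercept and a residual. The two random variances are
  calibrated against the realised fixed-effect variance decomposition so
  the between-female share of total variance equals the configured
  fraction (default 0.80).
* **Proteome.** Log intensity = baseline + fixed effects × covariates +
  per-protein female intercept + per-protein laying-order slope + MS batch
  effect + replicate noise; baselines are log-uniform over six orders of
  magnitude. The default ground truth gives laying order a non-zero effect
  for half the proteins (30% positive, 20% negative) and the remaining
  predictors sparse small effects. Dropout is missing-not-at-random:
  P(missing) is a logistic function decreasing in log intensity, with the
  intercept calibrated at generation time to the configured overall rate
  (default 15%; the real rate is not published, so it is an explicit
  parameter). Each protein carries 1–16 of the 21 first-level FunCat terms,
  small counts most common.
* **Yolk chemistry.** Six carotenoid species are log-normal with the field
  means/CVs (lutein 22.1 µg/g CV 89%, zeaxanthin 7.2/87, β-carotene 3.6/69,
  β-zeacarotene 3.5/175 and present in 67% of eggs, γ-carotene 1.7/134, its
  Z-isomer 1.2/92). All species load on one shared latent factor (60% of
  each species' log variance), which contains the laying-order decline and
  a between-female component — hence all-positive inter-species
  correlations and a single carotenoid cluster. Lipids are Gaussian around
  222.1 mg/g wet yolk with a laying-order decline and a between-female
  component.
* **What it does not emulate:** peptide-level structure, shared-peptide
  protein inference, retention-time or spectral artefacts, correlated
  missingness across replicates of a run, diet- or weather-driven temporal
  structure, and any real protein identities or annotation structure
  (FunCat terms are sampled independently of the effect structure).
  Passing tests therefore demonstrate correctness of the statistical
  machinery under the assumed generative model, not robustness to every
  pathology of real MS data. An egg's albumen and yolk samples share their
  replicate count and batch labels, a simplification of the real block
  design.

## Quantitation (`quant`)

A protein is *identified* in a sample when ≥ 2 technical replicates have
strictly positive intensity (zero is treated as not detected, the MaxQuant
convention), and *quantitated* when identified in at least ⌈n/2⌉ samples of
at least one biological group. Intensities are normalised to the total
signal of their (sample, replicate) run; missing values are then imputed
from Uniform[min, q01] where min and q01 are the minimum and the 1%
interpolated quantile of that run's observed normalised values — a
low-abundance imputation consistent with intensity-dependent dropout.
Imputation uses one RNG stream per (sample, replicate), keyed on sorted
protein ids, so results do not depend on row order and adding a protein
elsewhere does not perturb unrelated draws. Concentrations are
share × total compartment protein (mg) / compartment weight (g); shares are
renormalised within each run so the summed concentrations reproduce the
measured total exactly even after imputation added a little mass.
Per-sample abundances come from a Gaussian mixed model with the sample as
fixed factor and MS batch as random intercept (collapsing to the replicate
mean with a single batch; model failures fall back to the mean and are
logged).

## Mixed models (`infer`)

All models are Gaussian LMMs fitted by REML (statsmodels `MixedLM`) with
female identity as random intercept and laying order as random slope;
protein and carotenoid models add an assay-batch random intercept, crossed
with female via variance components in a single all-encompassing group.
Inference is Wald: z = β/SE against the standard normal, CI = β ± 1.96 SE
(matching z-and-CI style reporting without degrees-of-freedom corrections).
Continuous predictors and responses are standardised by centring and
dividing by **two** standard deviations, making their coefficients
comparable to untouched 0/1 binary predictors (yearling = 0/adult = 1,
female = 0/male = 1, within-pair = 0/extra-pair = 1). Protein responses are
rank-transformed (average ranks on ties) before standardisation, for
robustness to extreme values; rank-then-standardise was chosen because the
rank transform is the robustness device and standardisation is only a
scale convention — the z statistics are invariant to the order. Carotenoid
responses are log-transformed before standardisation. Paternity models are
restricted to first-laid eggs (paternity only varies there); fixed terms
that are constant in the modelled subset are dropped with a log message.
A fitted random slope with variance < 1e-8 triggers a refit without the
slope, flagged in the result.

Within a model, single-step multiplicity correction computes
P(max |Z| ≥ |z_k|) under the joint normal of the model's contrasts
(correlation taken from the fixed-effect covariance), by Monte Carlo with
10⁵ draws and a fixed internal seed; the adjusted value is floored at the
raw p. Degenerate covariances fall back to Bonferroni. Across models, the
same term forms a family and is Benjamini–Hochberg corrected when at least
5 models contribute; smaller families keep the single-step value.
The a-priori interaction set is exactly: female age × laying order,
female age × clutch size, embryo sex × laying order.

Variance partitions come from intercept-only LMMs:
between% = 100·σ²_female/(σ²_female + σ²_residual).

## Affinity propagation (`apcluster`)

Implemented from the message-passing updates: responsibilities
r(i,k) ← s(i,k) − max_{k′≠k}[a(i,k′) + s(i,k′)] and availabilities
a(i,k) ← min{0, r(k,k) + Σ_{i′∉{i,k}} max(0, r(i′,k))} (self-availability
a(k,k) ← Σ_{i′≠k} max(0, r(i′,k))), damped at λ = 0.9, at most 1000 sweeps,
convergence after 100 sweeps with a stable exemplar set
{k : r(k,k) + a(k,k) > 0}. Preferences (the similarity diagonal) are the
q-quantile of the off-diagonal similarities; q = 0 (the minimum) gives a
conservative cluster count and is the default everywhere. A seeded
symmetric jitter of relative size ≤ 1e-12 breaks exact ties. After
convergence the standard refinement step re-chooses each cluster's
exemplar to maximise the within-cluster similarity sum and reassigns,
iterated to stability — the same final polish reference implementations
apply. On random small instances (n ≤ 8) the resulting partitions match an
exhaustive search over exemplar subsets to within 1% of the optimal net
similarity in ≥ 90% of cases; the residual misses are one-off cluster
counts inherent to the message-passing heuristic (an independent reference
implementation misses the same instances).

Protein similarities are Pearson correlations between log-concentration
profiles; albumen and yolk are clustered separately. Batch-adjusted
abundances can be slightly negative for trace proteins and are floored at
half the smallest positive value before the log. Cluster concentration
sums are computed within each replicate and then averaged per sample. Egg
clustering uses 2-SD-standardised features (albumen and yolk cluster sums,
lipids, total carotenoids, egg weight) with Pearson similarity between egg
feature vectors — chosen for consistency with the protein stage; negative
squared Euclidean distance is available as a config alternative. Constant
features are dropped; compositionally identical eggs short-circuit to a
single cluster.

## Enrichment (`enrich`)

For each (cluster, FunCat term): the observed number of member proteins
carrying the term is compared with a null built by randomly permuting
proteins across the fixed cluster-size partition, 10,000 cycles by default.
"Enriched" means observed strictly exceeds the null 95% interpolated
quantile; multi-function proteins count under every term they carry. The
empirical p is (1 + #{null ≥ observed})/(1 + n_sim), which keeps p in
(0, 1]. No multiplicity control is applied across the (cluster, term) grid;
the result table records this in its metadata. Counts and proportions are
equivalent as "frequency" because cluster sizes are fixed under the null.

## Categorical association (`assoc`)

Non-binary predictors are categorised before testing: lay date into
half-open 4-day bins [start + 4k, start + 4(k+1)) from the season start;
laying order early = {1,3}, middle = {5,7}, late = {9,11,13}; clutch size
small = 8–10, average = 11–12, large = 13–15. Values outside a scheme
(e.g. clutch size 7) raise an error rather than being silently binned.
The functional chi-square statistic for an r×c table is

FC = Σᵢⱼ (nᵢⱼ − nᵢ·/c)²/(nᵢ·/c) − Σⱼ (n·ⱼ − n/c)²/(n/c)

with an asymptotic χ² reference on (r−1)(c−1) df — an asymmetric statistic
asking whether the columns are a (noisy) function of the rows; the
unnormalised, χ²-referenced form is used. A seeded permutation p (shuffling
the column variable, which preserves both margins; ≥ 10,000 permutations)
is reported alongside; the asymptotic value is the headline. Fisher's exact
test for 2×2 tables uses the conventional two-sided probability-ordering
rule. The egg-cluster battery runs one functional chi-square per predictor
(clutch size, lay date, laying order, female age, embryo sex, paternity)
with BH-FDR across the six tests; constant predictors are excluded with a
warning and eggs of unknown paternity leave only the paternity test.

## Workflow and reproducibility (`workflow`)

`run_pipeline` composes quantify → model → cluster → enrich → associate
from a `PipelineConfig`; every stage seed is derived from the master seed
by hashing the stage name, so re-running a configuration reproduces
byte-identical outputs, and the manifest records the config hash, seeds and
filter counts. The numbered scripts under `analysis/` are the command-line
surface: thin narrative drivers over the same library calls, writing
summary tables under `results/` and bulky regenerable intermediates under
`scratch/`.

## Validation studies (`validation`)

The `validation` module contains the simulation studies the acceptance
suite runs, at these problem sizes (chosen to characterise the estimators
well while remaining cheap to re-run):

* variance-partition recovery: 50 study-sized datasets generated at a 0.80
  between-female fraction;
* affinity propagation vs exhaustive exemplar search: 100 random planar
  instances with n ≤ 8 and a four-point two-cluster toy instance;
* enrichment type-I error: 500 datasets of 60 proteins in three clusters
  with annotations independent of clusters, 10,000 null cycles each;
* imputation: bound checks and a KS test for uniformity on 10,000 draws in
  one replicate run;
* mixed-model recovery: 200 simulations of a true standardised
  laying-order effect of 0.5 on the study design (female intercept SD 0.3,
  slope SD 0.05, residual SD 0.5), and 1000 null simulations for the
  false-positive rate. Bias is reported against the population target;
  CI coverage against the dataset-specific standardised truth
  b·SD(x)/SD(y), since the per-dataset 2-SD scaling defines the estimand
  each fit actually targets.

## Known limitations

* Wald (normal) inference ignores the finite number of females (39); at
  this design size the null rejection rate is close to, but can sit a
  point above, the nominal 5%.
* The crossed female × batch variance-component fits force zero
  correlation between the female intercept and the laying-order slope.
* Affinity propagation at q = 0 determines the cluster count from the data;
  on weakly structured synthetic features the egg-level clustering
  typically returns more clusters than strongly structured real
  compositions would.
* The enrichment null preserves cluster sizes but not any correlation
  between annotation richness and cluster membership beyond exchangeable
  proteins.
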