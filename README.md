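# shockmetab

Metabolic phenotyping of critically ill shock patients from targeted
plasma metabolomics.

Patients admitted in septic or cardiogenic shock are clinically
heterogeneous: severity scores taken at admission explain outcome only
partially. One productive way to look past the scores is to stratify
patients by their circulating metabolome — a targeted panel quantifying
~186 metabolites in six biochemical families (amino acids, biogenic
amines, acylcarnitines, glycerophospholipids, sphingolipids, sugars) —
and ask whether the resulting metabolic phenotypes carry independent
prognostic information. `shockmetab` implements that analysis end to end
as a reusable, tested library for ICU researchers working with
patient × metabolite concentration tables.

## What it computes

1. **Quality control.** A metabolite is retained only if it has ≤ 20%
   missing values within every patient group and detectable (above-LOD)
   concentrations in ≥ 50% of all samples. Below-LOD cells are imputed at
   half the metabolite's minimum measured value, missing cells at its
   median, then concentrations are log-transformed and z-scored per
   metabolite.
2. **Stratification.** The z-score matrix is projected to 2-D with UMAP
   (`n_neighbors=15`, `min_dist=0.1`, Euclidean) and clustered with
   DBSCAN (`eps=0.7`, `minPts=5`); eps can be checked against the knee of
   the k-distance curve (k = minPts − 1). Cluster ids are canonical:
   1..K by decreasing size, noise = −1.
3. **Robustness.** Clusterwise bootstrap stability: resample patients
   with replacement, re-run the embedding + clustering with fixed
   parameters, and score each original cluster by its best Jaccard match
   `|A∩B| / |A∪B|` over patients common to both sets. A sensitivity
   analysis excludes patients with max |z| > 5 over all metabolites,
   re-clusters, and cross-tabulates assignments (alluvial-plot table).
4. **Comparison.** Kruskal–Wallis (tie-corrected H, χ² p) for continuous
   variables; the Freeman–Halton exact r×c generalization of Fisher's
   test (full enumeration of margin-fixed tables under the multivariate
   hypergeometric law) for categorical ones; per-patient metabolite-family
   scores (mean z over the family) with cluster medians.
5. **Outcome model.** Logistic regression of in-hospital death on cluster
   membership (2-df categorical), APACHE II and number of organ failures
   (standardized), with univariate screening (p < 0.1), backward
   elimination (p < 0.05), events-per-variable accounting, and Harrell's
   optimism bootstrap (corrected c-index and g-index, calibration slope,
   Emax).

Because patient-level ICU metabolomics data are rarely shareable, the
package ships a first-class synthetic cohort generator
(`shockmetab.simulate`) that plants three phenotypes with family-specific
log-normal shifts, below-LOD censoring, cluster-linked severity scores
and an explicit mortality logit, so the whole pipeline is testable and
demonstrable without protected data.

## Worked example

```python
from shockmetab import (MetabolicClusterModel, MortalityModel, RunConfig,
                        bootstrap_stability, default_spec, simulate_cohort)

cohort = simulate_cohort(default_spec(rng_seed=7))   # or read_cohort(...)
results = MetabolicClusterModel(cohort.tables, RunConfig(rng_seed=7)).fit()
print(results.summary())

stability = bootstrap_stability(results, n_boot=100, seed=7)
print(stability.summary())

fit = MortalityModel.from_cohort(cohort.tables, results.labels).fit()
print(fit.summary())
print(fit.validate(n_boot=200, seed=7).summary())
```

prints

```
Metabolic phenotype clustering (UMAP + DBSCAN)
===============================================
patients:             60
metabolites retained: 130 (excluded 0)
eps / min_pts:        0.7 / 5 (k-distance suggestion: 0.629)
clusters found:       3
  cluster 1: n = 26
  cluster 2: n = 21
  cluster 3: n = 13
  noise:     n = 0
Bootstrap cluster stability (100 iterations)
mean Jaccard index: 0.982
  cluster 1: 0.996
  cluster 2: 0.985
  cluster 3: 0.967
Logistic model of in-hospital mortality
================================================
n = 60, events = 19, model df = 4, EPV = 4.75
(continuous covariates standardized; categorical reference: {'cluster': '2'})

                   coef      OR  OR_low  OR_high      p
cluster[1]        2.968  19.447   1.571  240.746  0.021
cluster[3]        1.037   2.822   0.210   37.828  0.433
apache2           1.071   2.919   1.112    7.665  0.030
n_organ_failures  1.105   3.021   1.337    6.824  0.008
Bootstrap internal validation (200 iterations, 129 degenerate resamples redrawn)
  c-index:           0.877 apparent -> 0.849 corrected
  calibration slope: 0.832
  Emax:              0.067
  g-index:           2.714 apparent -> 2.772 corrected
```

Reading this: the three planted phenotypes are recovered with no noise
points and near-perfect bootstrap stability (mean Jaccard 0.982). In the
mortality model, membership in cluster 1 (the high-risk metabolic
phenotype) multiplies the odds of in-hospital death ~19-fold relative to
the low-risk reference cluster even after adjusting for APACHE II and
organ failures; the optimism bootstrap shrinks the c-index from 0.877 to
0.849 and estimates a calibration slope of 0.83 — the expected mild
overfitting of a 4-df model on 19 events. Degenerate resamples (single
outcome class or separated fits) are redrawn and counted.

A CLI mirrors the library: `shockmetab simulate|qc|cluster|stability|
sensitivity|stats|model`, each accepting `--config` (YAML) and `--seed`.

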