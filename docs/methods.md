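# Methods

This note documents the models, conventions and numerical choices behind
`shockmetab`, in the order the pipeline runs them.

## Input model and quality control

The analysis starts from a wide patient × metabolite table of absolute
concentrations (µM) from a targeted panel organized in six biochemical
families. Each cell carries one of three statuses: `measured`,
`below_LOD` (reported but under the limit of detection) or `missing`
(absent). Several spellings of the below-LOD sentinel (`<LOD`, `< LOD`,
…) are accepted because kit-software exports vary; the set is
configurable. Patients are canonical-sorted by id at read time so seeded
downstream runs are independent of file row order.

A metabolite is excluded when (1) its fraction of `missing` cells exceeds
`qc_missing_frac` (default 0.20) within **any** patient group, or (2) its
fraction of `measured` cells over all samples falls below
`qc_detect_frac` (default 0.50). The two rules are deliberately distinct:
detectability counts `below_LOD` as not detected, the missingness rule
counts only true absences. Rule (1) nominally references patient
clusters, which do not exist before clustering; to avoid the circularity
the default grouping is the admission-cause strata (septic/cardiogenic),
and a second QC pass with discovered clusters can be run explicitly.
Both firing reasons are recorded when both rules trigger.

Imputation follows common targeted-metabolomics defaults, since no single
convention is universal: below-LOD cells get half the metabolite's
minimum measured value, missing cells its median measured value. Values
are then natural-log transformed (concentrations are strictly positive
and right-skewed) and z-scored per metabolite with the sample SD
(ddof = 1). Outlier screening operates on these z-scores; on raw
concentrations a max-|z| > 5 rule would flag almost everyone because of
the heavy tails.

## Stratification

The z-score matrix is embedded in 2-D by UMAP. "Default settings" are
not portable across UMAP implementations, so the classic defaults are
pinned explicitly: `n_neighbors=15`, `min_dist=0.1`, Euclidean metric,
and a single stored random seed. The embedding is clustered by DBSCAN
with `eps=0.7`, `minPts=5`, where a core point counts itself toward
`minPts` (the convention of the reference algorithm and the common R
implementation). Labels are canonicalized 1..K by decreasing cluster
size, ties broken by smallest member id; noise keeps the sentinel −1.

The k-distance curve (each point's distance to its (minPts−1)-th
neighbor, sorted ascending) is computed alongside, and a knee is
suggested by the maximum-perpendicular-distance-to-chord rule. The
suggestion is advisory: the configured eps always wins, reproducing the
analyst's manual choice. Whether to scale before embedding is exposed
(`scale` flag) because published pipelines often leave it unstated; the
default is log + z-score.

## Bootstrap stability

Stability follows the clusterwise-bootstrap convention (the
`clusterboot` family): per iteration, draw patients with replacement,
collapse the draw to its unique members — duplicated coordinates inflate
local density and would bias DBSCAN toward spurious cores, and the
Jaccard comparison is over patient *sets* anyway — then re-run the
embedding + DBSCAN with fixed eps/minPts on that subset. Each original
cluster with at least one sampled member scores its maximum Jaccard
index against the bootstrap clusters (noise belongs to no cluster and
can only lower scores); the iteration score is the unweighted mean over
scored clusters, and the report keeps per-iteration, per-cluster and
grand means. Iteration seeds are `seed + i`, making a 1000-iteration run
reproducible and trivially parallelizable. If a bootstrap subset is
smaller than `n_neighbors`, the embedding's neighborhood size is capped
at subset size − 1.

The sensitivity analysis excludes patients whose maximum |z| over all
metabolites exceeds 5, re-runs the full pipeline on the remainder with
identical parameters, and reports the original × reduced label
contingency (the table an alluvial plot draws). Note a structural
limitation of the max-|z| rule: k identical extreme values in one
metabolite inflate that metabolite's SD and cap the achievable z at
roughly √(n/k), so duplicated extremes can mask each other.

## Between-cluster tests

Continuous variables use the Kruskal–Wallis H with tie correction and a
χ²(k−1) p-value. The χ² p is asymptotic: on very small samples (N ≤ 8,
heavy ties) it can sit far from the exact permutation p, which the test
suite quantifies against a full-enumeration oracle.

Categorical variables use the Freeman–Halton exact r×c test, implemented
by recursive enumeration of all tables with the observed margins.
Probabilities come from log-factorials (`gammaln`); the two-sided p sums
tables whose probability does not exceed the observed table's, with a
relative tie slack of 1e-7 (the convention of the standard
implementations, which the published per-cluster outcome tables
reproduce to the printed precision). Enumeration is exact and fast for
the tables this design produces (2–3 × 2–3, N ≈ 60); completeness is
verified by the probabilities summing to 1 ± 1e-10.

Family profiles score each patient as the mean z across the family's
metabolites — a mean, not a sum, so families of 1 and of 65 metabolites
are comparable — with cluster medians and a per-family Kruskal–Wallis
omnibus p. The baseline table renders categorical cells as `n (percent)`
with round-half-up integer percents and continuous cells as
`median (min–max)`, labelled as such. Pairwise p-values are unadjusted
by default (Holm available behind a flag).

## Mortality model

The outcome model is a maximum-likelihood logistic regression of
in-hospital death on cluster membership (categorical block, K−1 df),
APACHE II and the number of organ failures, continuous covariates
z-scored for comparable effect sizes. The categorical reference defaults
to the cluster with the lowest observed event rate, so odds ratios read
as risk relative to the most benign phenotype; it is configurable.
Selection, when requested, runs a univariate screen (keep p < 0.10;
perfectly separating covariates are retained but flagged, since their
Wald p is meaningless) followed by backward elimination (drop the
largest-p non-forced term while ≥ 0.05), with categorical blocks judged
by likelihood-ratio tests and dropped or kept as a unit. Events per
variable is kept as an exact rational (events / non-intercept df).

Internal validation is Harrell's optimism bootstrap on the **fixed**
final covariate set (re-running selection inside the loop would be
needed to capture selection optimism; refitting the fixed model matches
the usual "internal validation of the final model" and is stated as
such). Per iteration: resample patients with replacement, refit, and
accumulate optimism = metric(resample fit on resample) − metric(resample
fit on original data) for the c-index (midrank ties = 0.5) and the
g-index (Gini mean difference of the linear predictor — the declared
definition of "g" here). Corrected = apparent − mean optimism. The
calibration slope is the mean over iterations of the original-data slope
from refitting the outcome on the resample-fitted linear predictor, and
Emax is the maximum absolute gap between apparent risk and the
slope-recalibrated risk over the observed predictions. Resamples with a
single outcome class, non-convergence or (quasi-)separation — detected
via separation warnings or runaway coefficients (|β| > 15 on the
standardized scale) — are redrawn and counted; an unbounded linear
predictor from a separated refit would otherwise dominate the g and
slope averages. More than ~50% failed draws aborts with an error. At the
design's scale (≈18 events, 4 df) a sizable redraw count is normal and
is surfaced in the report.

## Synthetic cohort generator

The generator is the package's stand-in for study-like data and defines
the conditions under which the pipeline is tested. Defaults: 60
patients in three phenotypes with expected proportions 13/60, 24/60,
23/60; 130 metabolites split 20/14/15/65/15/1 across the six families
(the panel's 186-analyte family composition scaled to a
post-QC-size panel). Log-concentrations are
`baseline_j + shift(phenotype, family) + sd·(λ·F + √(1−λ²)·ε)` with
baseline log-means drawn uniformly on log(0.5)–log(200) µM, within-
cluster SD 1.0, and a per-family latent patient factor with loading
λ = 0.5 — fully independent metabolites would make the clustering
problem unrealistically easy to calibrate. The default shift pattern
encodes the three phenotypes: A = +3 SD biogenic amines and sugars,
+2 SD sphingolipids; B = +3 SD glycerophospholipids, +2 SD
sphingolipids; C = baseline (uniformly low). No quantitative effect
sizes are published for such cohorts, so these are calibration choices
made once: large enough that the planted structure is unambiguous
(recovery ARI ≈ 1), which is what the recovery and stability guarantees
are asserted against; the shift-grid tests characterize behavior as the
signal shrinks toward zero.

Censoring replaces each metabolite's lowest `lod_quantile` (default 2%)
of values with below-LOD status; an additional `missing_rate` (default
1%) of cells go missing completely at random. Clinical covariates are
cluster-dependent: APACHE II ~ round(N(29/25/22, 5)) for A/B/C, SOFA ~
round(N(13/13/11, 3)), organ failures ~ Binomial(6, 0.50/0.42/0.33),
septic admission with probability 0.54/0.71/0.65. Hospital death follows
an explicit logit: intercept −1.85, phenotype offsets +1.45 (A) and
+1.35 (B) versus C, plus 0.5 per standardized-unit of APACHE II
((x−25)/5.5) and organ failures ((x−2.4)/1.3). These values were chosen
analytically so the implied phenotype-level mortality is ≈54/38/9% —
`implied_mortality()` integrates the logit over the exact covariate
distributions (rounded-normal × binomial quadrature), and the test suite
checks the Monte-Carlo rates against that oracle. ICU death is a random
80% subset of hospital deaths.

What the generator does **not** emulate: batch effects, plate drift or
any LC–MS measurement-error structure; metabolite-level biochemical
correlation beyond the family factor; comorbidity-driven confounding;
informative (outcome-dependent) missingness. Passing tests therefore
demonstrate the pipeline's correctness and behavior under a clean
log-normal phenotype model, not robustness to instrument artifacts.

## Problem sizes and numerical choices

Test and acceptance runs scale the expensive loops to sizes that keep
the full suite fast while leaving the Monte-Carlo conclusions stable:
bootstrap stability at 100–200 iterations (the per-iteration Jaccard
distribution is tight at the default effect sizes), effect-size grids
at 3 seeds per point, the small-sample optimism study at 30–40 replicate
cohorts × 40 bootstrap iterations, the large-sample optimism limit at
n = 100 000 × 15 iterations, and parameter recovery at n = 5000. The
acceptance script uses 200 stability iterations and the full 1000
validation iterations. Degenerate inputs are errors, not silent
results: empty metabolite sets, zero-variance columns under z-scoring,
metabolites with no measured value, two empty sets under Jaccard,
single-class outcomes, constant linear predictors under calibration.
Floating-point conventions: sample SDs use ddof = 1 throughout; exact-
test tie comparisons use a 1e-7 relative slack; report serialization
preserves floats at full precision for lossless round trips.

## Known limitations

- UMAP's embedding geometry is implementation- and version-dependent;
  eps = 0.7 is meaningful relative to this implementation's scale, and
  the k-distance suggestion should be consulted when porting.
- With n_neighbors larger than a (sub)population, UMAP's k-NN graph
  bridges groups and can merge small true clusters — visible in
  bootstrap draws that leave a cluster with few unique members.
- The χ² p for Kruskal–Wallis is unreliable below ~N = 10; an exact
  permutation p would be preferable there (the suite's oracle shows the
  size of the gap).
- The optimism bootstrap validates the fixed final model only; selection
  optimism from the screen/elimination steps is not captured.
- The g-index is sensitive to near-separated refits; the redraw policy
  stabilizes it at the cost of conditioning on convergence.
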