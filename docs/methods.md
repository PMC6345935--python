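# Methods

This note documents the statistical procedures implemented in `alstrat`,
the defaults they run with, and the choices made where the design was
genuinely open. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` compute.

## Data model

All clinical input is a long-format table: one row per measurement with
`subject_id, feature_name, value, delta_days`. `delta_days` counts from the
onset of clinical records (trial onset or first clinic visit — the two are
treated identically, as nothing downstream distinguishes them). Values are
stored verbatim as text and coerced through a feature dictionary
(`continuous` | `discrete`) at use time, because both kinds share one value
column. Two windows partition the first year: days 0–91 ("first three
months", the prediction input period) and days 92–365 (the outcome period);
both are inclusive, disjoint and exhaustive. Negative pre-baseline days are
accepted on input but fall outside every default window.

## Outcomes

**Progression slope.** For a subject with at least two total-score records
in the outcome window, t1 is the earliest and t2 the latest in-window day
and

slope = (ALSFRS(t2) − ALSFRS(t1)) / ((t2 − t1)/365 · 12) points/month.

Multiple records on the boundary day are averaged (a symmetric,
deterministic resolution of an unspecified case); conflicting values on a
single effective day are a degenerate-input error. Fewer than two in-window
records leaves the outcome undefined rather than raising.

**Survival.** Time to death or tracheostomy when recorded (the event day is
carried in the value column of a dedicated feature), otherwise censoring at
the last visit day. Subjects whose final record is on or before day 90 are
excluded, and an outcome time ≤ 90 — including a death exactly on day 90 —
is excluded under the same rule. Month horizons convert to day cutoffs as
round(m/12 · 365), giving 365/548/730 for 12/18/24 months.

## Scoring

Raw metrics: RMSD, Pearson correlation and the concordance index. The CI
handles censoring with Harrell's convention: a pair is comparable iff the
actual times differ and the smaller time belongs to an event; comparable
pairs score 1 (concordant), 0 (discordant) or 0.5 (prediction tie), and the
CI is the mean over comparable pairs, which reduces to the
2/(n(n−1)) Σ h(i,j) form when nothing is tied or censored. Pairs with equal
event times are incomparable. Survival predictions are probabilities at the
12/18/24-month horizons; each horizon's probabilities are scored as a
separate CI against the single (time, event) pair — higher probability must
pair with longer survival.

Nulls come from shuffling the truth-to-subject assignment (default 100,000
shuffles; tests and the acceptance script use desk-scale counts of
300–5,000, which the API exposes as `n_perm`). All metrics share each
shuffle. z = (score − null mean)/null SD, combined as
z_slope = z_CI + z_PCC − z_RMSD and z_survival = z12 + z18 + z24.

The BT comparison bootstraps subjects with replacement, recomputes the raw
metrics per resample, standardizes them against the *full-set* nulls (the
null is a property of the truth set, not of a resample) and reports the
percentage of resamples in which one set's combined z strictly exceeds the
other's. With identical prediction sets every resample ties, so BT(A, A) is
0, not 50 — the strict-inequality reading is kept deliberately; the
meaningful invariant, asserted in tests, is BT(A,B) + BT(B,A) = 100 when
ties have measure zero.

## Consensus clustering

m_ij = Σ_s ln(p/c_s) over submissions co-clustering i and j, with c_s the
shared cluster's size and p the cohort size. The natural log is a free
choice — the base rescales M uniformly and the downstream correlation
distance is scale-invariant.

**Pair FDR.** Each permutation redraws every submission as a uniformly
random assignment of its subjects to clusters of the original sizes, and M
is recomputed. For an observed score m, FDR(m) = (mean per-permutation
count of permuted pair scores ≥ m) / (count of observed pair scores ≥ m),
clipped to [0, 1] and reported as a proportion. The printed form of this
estimator in the source material is dimensionally inconsistent with the SAM
procedure it cites; this package implements the SAM-style ratio with
extreme-tail (≥) counting. Default 100 permutations; threshold 5%.
Significant pairs form a graph exported as DOT/GraphML whose connected
components, together with per-k silhouettes, are offered as *decision
support* for choosing k (`suggest_k`); k itself is a required user
parameter, chosen by eye in the original analysis.

**k-means.** "k-means with average linkage" is contradictory (linkage has
no role in Lloyd iteration), so the operative terms win: Lloyd k-means on
rows of M, distance 1 − Pearson correlation to the centroid, centroid = the
arithmetic mean of member rows, best of `n_restarts` (default 10) seeded
initializations by total within-cluster distance. An emptied cluster is
re-seeded from the subject farthest from its current centroid. A constant
row has undefined correlation; such subjects fall to the lowest cluster
index (ties everywhere break to the lowest cluster index, then subject
order). Core patients are the ⌈size/2⌉ members closest to their centroid,
distance ties broken by subject order.

## Discriminating features

Longitudinal values are summarized per (patient, window): continuous
features as mean/min/max of in-window values, discrete features as the
modal value (ties → lexicographically smallest). Missing stays missing;
all tests use pairwise-complete observations per feature.

Global screening statistics: one-way ANOVA F for continuous rows, Fisher's
exact p (as −log p, so larger = more extreme) for discrete rows. The
Freeman–Halton extension for R×C tables is computed by exact enumeration of
tables with the observed margins when the enumeration bound
Π_j C(c_j + R − 1, R − 1) is tractable (default cap 20,000), otherwise by a
seeded Monte Carlo estimate of the same two-sided table-probability
p-value. Margins are invariant under within-row permutation, so one null
reference per feature serves its observed statistic and all permutations.

Permutations shuffle each row's non-missing values across its non-missing
subjects against the fixed design (100 by default); this keeps per-cluster
sample sizes and contingency margins fixed. Observed and permuted
statistics are converted to relative ranks within their family's pooled
permutation distribution — the fraction of the pool *strictly below* the
value. Strict counting matters at desk scale: with ≤-counting the pool's
own maximum always ties at rank 1.0, placing a floor of ≈(1/n_perm)/N_true
under every FDR, so no feature could ever reach the 0.01% profile cap with
only ~60 features. With strict counting a statistic beyond the entire pool
attains FDR 0.

Ranks from both families are pooled and the FDR at threshold r is
(mean per-permutation count of permuted ranks ≥ r)/(count of observed ranks
≥ r). Because rejection sets are nested, each feature takes the minimum raw
FDR over all thresholds at or below its own rank (q-value monotonization),
making the FDR non-increasing in the rank threshold.

Pairwise contrasts run only for continuous features with global FDR < 5%
(the "ANOVA trick", which keeps the pairwise multiple-testing family
small). Welch's unequal-variance t is used — the source says only
"t-tests", and the unequal-variance form is the robust default. |t| values
from the same permutation scheme feed the same SAM-style FDR construction,
pooled over all (feature, pair) tests. The heatmap counts, per feature,
+1 for each significantly higher cluster and −1 for its counterpart, then
rescales each row linearly to [−1, +1]; an all-zero row stays 0 (a nonzero
constant row cannot occur, as wins and losses sum to zero).

## Assignment

Profiles take the top `max_features` (default 20) continuous features at
FDR ≤ `fdr_cap` (default 10⁻⁴), ordered by FDR then statistic; features
with zero training variance are dropped with a warning. Each feature is
z-normalized by the training mean/SD and each cluster's centroid is the
mean z-vector of its members. A new patient is z-normalized with the
*training* normalization and assigned to the centroid with the highest
uncentered correlation over pairwise-complete components; at least 25% of
the profile features must be observed (an unspecified case — the floor
prevents one-feature assignments), otherwise the patient is unassignable.

Cross-validation removes each fold *before* feature selection: the rank FDR
and profiles are rebuilt on the training subjects only. Folds are
stratified by consensus cluster (preserving cluster representation; not
stated explicitly in the source but consistent with its intent). Accuracy
is pooled correct/assigned across folds, optionally restricted to core
patients — the published figure refers to core patients of a restricted
real cohort and is not reproducible here, so both modes are exposed.

## Synthetic cohorts

The generator emulates the shape of pooled trial/registry data: per-cluster
linear ALSFRS-R trajectories (baseline + monthly slope + Gaussian residual,
clipped to 0–48) sampled on a jittered ~30-day visit schedule over one
year; exponential survival per cluster with administrative censoring at day
730 (any proportional-hazards-like generator suffices for CI testing);
continuous features with one-vs-rest per-cluster mean shifts in SD units
among pure-noise features; discrete features with a cluster-favored
category; and record-level missingness. Defaults are the study conditions:
400 subjects, four equally weighted clusters with baselines
40.25/40/29/35.75 points and slopes −0.48/−0.93/−0.65/−1.05 points/month
(slow, early-stage, late-stage, fast progressors; the late-stage slope is
not published and −0.65 is an interpolation consistent with its phenotype),
hazards giving median survivals of roughly 3.8/2.5/1.5/1.2 years, 5 planted
+ 50 null continuous features at a 1-SD shift, 5 three-category discrete
features with 0.6 bias, 10% missingness, and an ensemble of 30 solvers at
20% uniform relabeling noise plus 3 fully random solvers.

What the generator does *not* emulate: nonlinear or floor-effect
trajectories, visit dropout correlated with disease severity, informative
censoring, correlated feature blocks, measurement batch effects, and the
heavy (>90%) missingness of some registry variables. Passing tests
therefore demonstrate correctness of the machinery and its calibration
under clean planted structure, not clinical performance on real cohorts.

## Numerical choices and problem sizes

Determinism is end-to-end: every stochastic step takes a seed or Generator,
and the pipeline derives per-stage seeds from one base seed; identical
configs reproduce identical artifacts (hash-checked in the manifest).
Degenerate inputs are errors or excluded-with-report, never silent NaNs:
zero null SD, constant vectors in Pearson, no comparable CI pairs,
undefined ANOVA/Fisher statistics, zero-variance profile features.

Tests and the acceptance script run the same procedures at desk scale —
permutation counts of 20–5,000, cohorts of 40–400 subjects, 10–20
replicates for calibration bands — chosen so the full suite completes in
well under a minute of compute per heavy check while keeping Monte Carlo
error far from the asserted bounds.

## Known limitations

- The Fisher Monte Carlo path estimates the Freeman–Halton p with
  ~1/√B error (B = 2,000 by default); exact and MC paths can differ in the
  third decimal for borderline tables.
- The pairwise-t FDR uses the pooled-|t| SAM construction; the source's
  description ("transform t-test p-values into FDRs analogously") is
  ambiguous between this and per-test permutation p-values.
- k-means with correlation distance is not guaranteed to find the global
  optimum; restarts mitigate but do not eliminate this.
- Survival scoring assumes the per-horizon probabilities are monotone uses
  of one underlying risk; no cross-horizon consistency is enforced.
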