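# Methods

This note documents the models, defaults and numerical choices behind
metabokit, and what the synthetic-data tests do and do not demonstrate.

## Targeted peak analysis

A target is (name, MS1 m/z, optional RT, fragment m/z list). Detection
scans all MS1 centroids within a relative window |m − m₀|/m₀ ≤ tol·10⁻⁶
(tolerance relative to the *query* m/z) and returns the
maximum-intensity match; when the target carries an RT, candidates are
restricted to RT ± rt_tol. Defaults are 1000 ppm and ±5 s, the settings
used in the bundled narcotics demonstration. MS2 matching considers
product-ion scans whose precursor lies within the MS1 window and whose RT
is within rt_tol of the detected apex; per true fragment the
highest-intensity centroid inside the fragment window wins, with exact
intensity ties broken toward the lower m/z. Fragment windows may be ppm or
absolute Da; Da (±0.5) is the default because fragment targets are
typically given as nominal integer masses.

Abundance is the sum of the extracted ion chromatogram over
[RT − w, RT + w]; within one scan, centroids inside the m/z window are
summed (not maxed) — the choice is documented because either convention
is defensible for isotope shoulders. S/N is mean/sd with the sample
(n − 1) standard deviation. Two S/N modes exist: per-run over the XIC
points inside the RT window (reported by `analyze_targets`), and
per-feature across samples (used by QC filtering). Zero variance yields an
infinity sentinel with a warning rather than an error, since constant
signals are informative in QC.

## mzML I/O

Reading and writing use a self-contained lxml implementation of the PSI
mzML vocabulary (64-bit little-endian uncompressed arrays on write; 32/64
bit and zlib accepted on read). Only centroided spectra are supported;
profile-mode data are rejected with the scan index named, never silently
centroided. RT is seconds internally; minute-denominated scan times are
converted on read using the unit attribute.

## Preprocessing

* Pareto scaling: (x − mean)/sqrt(sd), per feature, sample sd. The scaled
  feature's sd equals sqrt of the original — an identity asserted in the
  tests. Zero-variance features are centered only, with a warning.
* RINT: Φ⁻¹((r − c)/(n − 2c + 1)) with the Blom constant c = 3/8
  (configurable); ties receive average ranks, which matters because RINT
  on tied data is otherwise implementation-defined. NA positions are
  preserved by every transform.
* Internal-standard normalization divides each sample's column by the IS
  abundance; a zero or missing IS value is an error naming the sample.
* `mask_zeros` converts zero cells to NA. Zeros in abundance matrices are
  censoring artifacts (non-detects); left in place they act as gross
  outliers on the log scale and destroy association power, so the
  recommended pipeline is rate-based QC → `mask_zeros` → modelling.

## Quality control

Feature metrics: missing rate over all cells, zero rate among non-NA
cells (the denominator choice is documented; the alternative — zeros over
all cells — conflates the two rates), and across-sample S/N. Filtering
keeps features passing all three thresholds and reports per-feature
reasons; it is idempotent.

Sample filtering computes 1 − correlation distances (Pearson, Spearman,
or tie-corrected Kendall tau-b; pairwise-complete on NA), clusters with
average linkage, cuts the dendrogram at a user height and removes samples
in singleton clusters. The linkage and the singleton rule are this
package's design choices — reasonable, deterministic, and not claimed to
match any particular prior tool.

## ANCOVA

Per feature, ordinary least squares of abundance on an intercept, the
trait and the covariates, using complete cases. Categorical traits must be
two-level; the reference level is the first observed in the metadata, so
a control-first design gives positive betas for case-elevated features.
The trait coefficient, its t statistic and two-sided p are reported with
Benjamini-Hochberg adjustment across features; rank-deficient or
under-determined features are skipped with a warning rather than failing
the batch. `residualize` fits the covariate-only model and returns
residuals (orthogonal to the covariates by construction) for downstream
multivariate modelling.

## PLS / PLS-DA

NIPALS with column centering and unit-variance scaling of X and Y
(internal; disable with `scale=False`). Discriminant mode one-hot encodes
class labels and predicts by the maximum dummy column, ties to the first
class. Zero-variance predictors are dropped with a warning; component
counts beyond rank(X) are truncated with a warning. The default of 2
components matches score-plot practice.

* R2Y per component uses SSₐ = (tₐᵀtₐ)(qₐᵀqₐ), the explained Y sum of
  squares on the scaled scale; these weights also enter the standard VIP
  formula VIPⱼ = sqrt(p · Σₐ SSₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSₐ), which satisfies
  Σ VIP² = p to numerical precision.
* Cross-validation: seeded K-fold (default 7, the convention of the R
  package ecosystem this workflow comes from), stratified by class in
  discriminant mode with round-robin assignment after a within-class
  shuffle. Q2Y = 1 − PRESS/TSS with held-out TSS about the training mean.
  RMSEE = sqrt(RSS/(n − A − 1)) on the full fit.
* The 95% score-plot ellipses produced by `score_table` consumers are
  normal-theory chi-square ellipses, not Hotelling ellipses — flagged
  because the two differ at small n.

## Pathway analysis

Pathways are typed graphs: gene and compound nodes, signed directed edges
(activation +1, inhibition −1; unsigned relations are dropped with a
count). Input is KGML or a node/edge TSV dialect; there is no live
database access.

* ORA: hypergeometric upper tail P(X ≥ k) with the universe restricted to
  features present in the summary tables, per omic and pooled. The
  significance rule for counting is either |beta| > threshold or
  pFDR < alpha; both are exposed because study pipelines differ on this.
* The perturbation statistic extends topology-aware pathway impact
  analysis to the joint gene+compound graph: solve
  PF = ΔE + B·PF, B[v,u] = sign(u,v)/outdeg(u), by a direct linear
  solve (damped by 0.99 when the cyclic gain makes I − B singular, with a
  warning). Accumulation Acc = PF − ΔE and t_A = Σ Acc. The null
  redistributes the multiset of observed nonzero effects over uniformly
  random pathway nodes; the two-sided p-value is the median-corrected
  bootstrap tail (seeded, default 1000 draws). The normalized score
  divides t_A by the maximum |t_A| attainable by placing the observed
  effect magnitudes on the highest-gain nodes, giving a topology-aware
  effect size in [−1, 1]; this normalization is a documented package
  choice.
* Combination: Fisher's −2(ln p₁ + ln p₂) against chi-square(4), or a
  dependence-aware empirical alternative that compares Fisher's statistic
  to its permutation null (significance labels shuffled across features).
  The latter is an approximation built for this package, not a
  re-implementation of any published dependent-combination method.
* Multiplicity: BH step-up and Bonferroni across the tested pathways; the
  number tested (m) is always reported explicitly.

## Compound identification

Element masses are most-abundant-isotope values at ≥ 6 decimals; the
[M+H]+ shift is the proton mass 1.007276 Da (not the hydrogen atom),
which reproduces published reference adduct columns at 4 decimals. The
shipped adduct registry covers M, M+H, M+Na, M+K, M+NH4, 2M+H, M−H, M+Cl
and is extensible. Deltas are computed relative to the reference
(adduct) m/z. Database snapshots are TSV dumps; a record's stored mass
must agree with its formula within 1 ppm — the bundled demonstration
snapshot stores curated masses consistent with published reference m/z
values, which differ from formula-derived masses in the 4th decimal, as
curated databases do. Ties in delta break by db_id.

## Calibration

Weighted least squares with weights 1, 1/x or 1/x² (chosen for response
noise growing with concentration), linear or quadratic form. R² and
adjusted R² (1 − (1 − R²)(n − 1)/(n − p − 1)) are computed on the
weighted scale, about the weighted mean. Outlier rules:

* Cook's D > 4/n, computed on the whitened (sqrt-weight) design;
* the 95% prediction interval for a new observation at each standard's
  concentration (a confidence band on the mean would flag far too
  aggressively on calibration data — documented divergence risk);
* back-calculation bias: the point's re-estimated concentration off by
  more than 20% under the current iteration's model.

Each (form, weight, rule) scenario iterates flag → remove-all-flagged →
refit to a fixed point (max 5 iterations, floor of 4 retained points for
linear and 5 for quadratic; all-at-once removal is the documented choice
where worst-first would also be defensible). Near-perfect fits skip
influence diagnostics entirely. Scenarios are ranked by adjusted R²
descending, ties by fewer removed points then the simpler form. Inversion
solves the linear or quadratic equation, accepting the real root inside
the fitted concentration range (±5% span slack); two in-range roots or
none raise with diagnostics, and responses outside the fitted response
range warn about extrapolation.

## Synthetic data

The feature-table generator emulates a two-group study with covariates:
log-scale Gaussian abundances (baseline N(10, 1) per feature), a planted
group shift of delta·sd on a known feature subset, a linear age effect on
every feature, and NA/zero cells sprinkled at fixed rates. Defaults —
30 samples per group, 200 features with 20 planted at delta = 2, unit
noise, 2% missing and 2% zero — describe a moderately powered targeted
study. The pathway generator builds random signed graphs (10 genes,
3 compounds, 12 edges per pathway by default) and plants all effects in
the first pathway.

What the generators do *not* emulate: correlated feature blocks,
batch/drift structure, intensity-dependent missingness, heavy-tailed
abundance errors, or realistic pathway topology. Passing tests therefore
demonstrate correctness of the estimators and calibration of their null
distributions under idealized conditions, not performance on real
cohorts.

Problem sizes in the test-suite and acceptance computations (2000
features for null calibration, 100–200 replicates for power and detection
rates, 200-draw bootstrap nulls, 6–20 pathways) were chosen as the
smallest sizes at which the binomial noise of the measured rates is well
inside the asserted margins.

## Known limitations

* Untargeted feature finding, RT alignment, profile-mode centroiding and
  vendor formats are out of scope; inputs are centroided mzML.
* The dependence-aware p-value combiner is an explicit approximation (see
  above); for strict reproduction of a published dependent-combination
  method, plug a custom strategy into `combine_p`.
* Quadratic calibration inversion refuses ambiguous (two-in-range-roots)
  responses rather than guessing.
* PLS-DA class prediction is by maximum dummy column; no probabilistic
  calibration is attempted.
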