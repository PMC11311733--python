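# Methods

This note documents the statistical models behind `coronadx`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Data model

The quantification unit is the protein group; each serum sample is measured
in five nanoparticle (NP) channels, so an observation is a log2 MaxLFQ
intensity indexed by (sample, NP, protein group). Missingness is represented
by absent rows; explicit nulls are canonicalized to absent on ingest, and the
two are semantically identical everywhere. Tables are read and written as
UTF-8 TSV/CSV (long form, or wide protein × sample matrices melted on read);
annotation maps come from two-column TSV or GAF 2.x (Cellular Component
aspect only).

## Normalization

For protein p, channel j, sample s, the fold change is
FC(p,s,j) = y(p,s,j) − m(p,j), with m(p,j) the cohort median across samples.
The shift of (s,j) is the median of FC over a *reference set* of proteins
detected in at least 80% of samples (boundary inclusive); normalized
intensity is y − shift. Only reference proteins inform shifts, but all
records are normalized. A (sample, NP) with no observed reference protein
keeps shift 0.

The reference medians m(p,j) are an explicit argument
(`protein_np_medians`). Against a *fixed* reference the shift fit is an
exact projection: re-fitting returns zeros and a per-sample additive offset
is absorbed exactly — these are the properties the acceptance tests assert,
and the semantics used to normalize held-out samples against a training
cohort inside cross-validation. When medians are recomputed from the
normalized output instead, the composed operation is only approximately
idempotent (order statistics move); a unit test documents the size of that
residual. No iteration is performed: one pass, as in standard practice.

## Composition covariate

Serum samples vary in how strongly extracellular blood-fraction proteins
dominate the corona. Per sample, the covariate is the median fold change
(relative to cohort protein-NP medians) over observed (protein, NP) pairs
annotated "Extracellular", pooled across NPs — one value per sample, because
the downstream models consume one value per sample. Samples with no
annotated observation get a null, mean-imputed where a complete covariate is
needed. On synthetic cohorts with composition SD 0.5 the estimate correlates
with the simulated truth at r > 0.95 (n = 100–200).

## Detection filtering and MNAR imputation

Protein–NP series absent in ≥60% of samples are excluded (strict: exactly
60% missing is excluded). For the differential stage, each protein's
best-covered channel (ties to the lowest NP index) is completed by drawing
missing entries from Normal(I₀ − 1.8σ, 0.3σ), where I₀ and σ are the mean
and SD of **all** observed log2 intensities in the dataset — the
down-shifted, narrowed law encodes the assumption that missing values sit
below the detection limit. Because σ pools the full between-protein dynamic
range, imputed values land near the dataset's low-abundance tail regardless
of the protein's own level; this is deliberate and matches the stage's
left-censoring interpretation. Other channels contribute observed values
only. Each (protein, NP) series draws from its own seeded stream (seed ×
CRC32 of the series key), so results are independent of execution order and
parallelism. Imputation happens once, before all model fits, with the seed
recorded in `ImputationParams`.

## Differential abundance model

Per protein, with plate i, NP j, subject k:

    Y_ijk = β₀ + β₁·CaseStatus_k + β'·(age, draw year, appearance outlier,
            composition) + u_i + v_j + w_ij + z_k + ε_ijk

u, v, w, z are independent Gaussian variance components (plate, NP,
plate×NP, subject within plate). Proteins observed in a single channel drop
v, w, z and keep the plate intercept. Case codings: definition 1 (cancer vs
no cancer), definition 2 (grade group ≥2 vs the rest), or a three-level
coding with no-cancer reference and two indicator coefficients.

Fitting is REML with the relative variances γ_f = σ_f²/σ² profiled: for
fixed γ the GLS β and σ̂² are closed-form, so only the γ vector is optimized
(Nelder–Mead on log γ, bounds e⁻¹² to e⁸). All quantities are evaluated in
random-effect space via the Woodbury identity, with the largest factor
(usually subject) absorbed analytically through its diagonal one-hot Gram
matrix; the per-evaluation cost is cubic in the *remaining* random-effect
columns, independent of n. This runs ~5× faster than the general-purpose
alternatives at this design size, which is what makes the 500-protein
calibration suites practical; the solver is cross-checked in the test suite
against statsmodels `MixedLM` and R `lme4` on shared fixtures (β and SE agree
with lme4 to ~1e-3 relative; statsmodels' reported SE can deviate by a few
percent at boundary fits, its variance components agree). Rank-deficient
fixed-effect designs drop dependent columns via pivoted QR (coefficient 0,
SE ∞). Rows are canonically sorted before each fit so results are exactly
invariant to input ordering.

p-values for β₁ are Wald tests with a normal reference on the REML fit — a
deliberate, documented definition (no degrees-of-freedom correction such as
Satterthwaite). At the reference conditions (200 subjects, 5 channels) the
normal reference is accurate: measured type-I error 4.8–5.2% across seeds at
the 5% level on 500-protein null cohorts. Benjamini–Hochberg correction runs
across converged fits within a contrast (statsmodels implementation,
verified against the step-up definition by brute force); significance is
q < 0.05. Non-converged proteins are retained in output, flagged, and
excluded from the BH family.

Calibration at the defaults (measured, and re-asserted by the acceptance
tests): planted-effect bias +0.001 log2 units, 95% CI coverage 0.953,
type-I 0.041–0.052. Calibration is assessed at a mostly-null proteome (10%
planted): planting effects in *all* proteins contaminates the fold-change
shifts (the normalization assumes most proteins unchanged) and visibly
biases β — a real property of the method worth knowing when interpreting
cohorts with pervasive signal.

## 1D annotation enrichment

Per term, member values (mixed-model β) are compared against non-members by
a two-sided Mann–Whitney U; the score is the rank-biserial correlation
s = 2U/(n₁n₂) − 1 ∈ [−1, 1], positive when members rank high. Midranks
handle ties; p is exact by enumeration when n₁·n₂ ≤ 400 and untied,
otherwise the tie-corrected normal approximation. BH across tested terms;
terms with fewer than 3 scored members are skipped. s is invariant under
strictly monotone transforms and exactly antisymmetric under negation. The
default input is all proteins' β values; callers can restrict to the
significant set.

## Classifier pipeline

Features are (protein, NP) pairs. Per training cohort: drop features with
>60% missingness (strict); fold-change normalize; fit per feature
Y_ik = β₀ + u_i + Composition_ik + ε_ik (plate random intercept via the same
REML solver) and replace intensities by residuals; zero-impute missing
entries (absent means not present in the sample); record pre-imputation
coverage. Held-out samples are transformed with training statistics only:
training medians and reference set, training Eq.-model coefficients, plate
BLUPs (u_k shrunk by γn_k/(1+γn_k); unseen plates get 0). A test asserts
that corrupting held-out intensities changes neither the training feature
matrix nor the feature ranking (no leakage).

Ranking: two-sided Wilcoxon rank-sum p per feature (asymptotic, tie
corrected), ties broken by |rank-biserial| then column name. Redundancy
filter over the top-1000 pool, visited in rank order: feature F is excluded
iff some pool feature G with corr(F,G) > ρ has strictly higher coverage;
comparisons run against the full pool regardless of other features'
retention. Correlation is signed Pearson on residualized entries (absolute
mode behind a flag). The filter is verified exactly against an independent
naive implementation on hundreds of random instances.

Classification: random forest (500 trees by default) on the top-m surviving
features, probability scores. The (m, ρ) grid defaults to
m ∈ {20, 40, 50, 80, 100, 125, 160, 200} × ρ ∈ {0.5, 0.6, 0.7, 0.8};
nested CV uses 10 stratified outer folds, inner 10-fold CV tuning mtry over
{√d/2, √d, 2√d} by AUC, and 3 repeat seeds. Tests and the acceptance script
run reduced sizes (4-point grids, 3–5 outer folds, 50–100 trees, one seed),
which preserve every structural property being checked; the defaults remain
the full design. An optional PSA window (e.g. 4–10 ng/mL) restricts
subjects before any statistic is estimated. Any scorer honoring
fit/predict_proba can replace the forest.

Metrics: AUC (Mann–Whitney with midranks), average PPV (area under
precision–recall in average-precision form), average NPV (the same
computation on 1−scores, 1−labels, i.e. the NPV–specificity curve). All
three are verified against exhaustive threshold-sweep oracles. Model
selection maximizes the sum of z-scored metrics across configurations
(population SD; zero spread gives z = 0; ties to smaller m then smaller ρ).

## BBC-CV

Out-of-fold scores are pooled per subject (averaged over the repeat seeds;
treating repeats as rows is available behind a flag) into a subjects ×
configurations matrix. Each of B = 500 bootstrap iterations resamples
subjects with replacement, selects the best configuration on the in-bag rows
by the composite criterion, and evaluates it out-of-bag; the benchmark score
is evaluated on the *identical* out-of-bag subjects, giving paired deltas.
Draws with single-class in-bag or out-of-bag sets are redrawn, keeping B
fixed. Point estimates are means over the out-of-bag distribution; CIs are
2.5/97.5 percentiles. On 32 null configurations at n = 200 the pooled
best-config AUC is ~0.58 while the BBC point estimate stays at ~0.50 — the
winner's curse the procedure exists to remove.

Held-out validation uses a one-sided paired DeLong test for the AUC
difference (structural components with midranks; zero difference with zero
variance yields p = 0.5 by continuity) and a paired bootstrap (10⁴
resamples, ties at zero counted half) for average PPV/NPV differences.

Feature importance: per (configuration, seed, fold), permutation importance
of the fold model on its held-out portion (accuracy drop over 5 permutation
repeats, standardized by the repeat SD). Summaries weight each
configuration's fold-averaged importances by its BBC selection frequency,
with absent features contributing zero; inclusion frequency is the
selection-weighted fraction of fold models containing the feature.

## MaxID

Greedy maximum coverage on a boolean sample × peptide matrix: repeatedly
select the sample covering the most uncovered peptides; ties to the
lexicographically smallest sample id (the published tie rule is unknown;
determinism matters more than the choice). Stops at k samples, at a
coverage target fraction, or when gains reach zero. Coverage is submodular,
so gains are non-increasing and the greedy prefix is ≥ (1 − 1/e) × optimal —
asserted against exhaustive optima on small matrices, with exact optimality
on disjoint constructions.

## Study design utilities

Plate assignment deals shuffled cases and controls round-robin across plates
of 15, bounding the plate-wise case-fraction deviation by 1/plate-size.
"Obvious imbalance" is quantified as any Kruskal–Wallis (age, PSA) or χ²
(cohort, race, case status) p < 0.05 across plates, triggering
rerandomization up to a retry budget; an exhausted budget returns the
best-balanced plan flagged `balanced=False`. The 70/30 split stratifies on
case status × race × age and PSA quartile bins, rounding ⌊f·n⌉ per stratum;
singleton strata go to training.

## Synthetic cohort generator

Observations follow
y = μ_p + fc_p·case_k + u[p, plate] + v[p, NP] + w[p, plate, NP] + z[p, k] +
t_k·λ_p + ε, with all random effects drawn independently per protein
(matching the per-protein model), base means μ_p uniform over 14–22 log2
units (8 units of dynamic range), planted |log2FC| ~ Gamma(4, effect/4)
with random signs, composition scalars t_k loading (λ = 1) only on the 25%
of proteins carrying the "Extracellular" annotation. Defaults: 200 subjects,
300 proteins, 5 NPs, plates of 15 filled by proportional case/control
interleaving, 10% planted differential proteins at mean effect 1.0,
variance components (plate, NP, plate×NP, subject, residual) =
(0.3, 0.5, 0.2, 0.5, 0.3) SD, composition SD 0.5.

Missingness is logistic in the true intensity relative to the grand mean
(intercept −3.0, slope −0.5 per log2 unit): ≈5% missing at the grand mean,
≈15% two units below, ~8–10% overall — the left-censoring the imputation
assumes, at the clean end of what protein-level serum DIA data shows after
detection filtering. An MCAR switch holds the probability constant for null
experiments. PSA is log-normal clipped to [0.1, 50] so a 4–10 ng/mL window
has nontrivial membership; benchmark risk scores are binormal with the
case-mean offset √2·Φ⁻¹(AUC) (default target 0.70), logistic-mapped to
[0, 1]. The peptide identification matrix draws detection probabilities from
Beta(0.2, 2), producing saturating accumulation curves. Same parameters and
seed give byte-identical outputs.

What the generator does **not** emulate: peptide-level structure and
roll-up, retention-time or instrument drift, cohort-specific storage
effects, correlated protein modules beyond the single composition factor,
non-Gaussian heavy-tailed intensity noise. Passing tests therefore
demonstrate correctness of the estimators under the assumed variance
structure and censoring mechanism — not that real serum cohorts satisfy
those assumptions.

## Numerical and reproducibility choices

Tolerances: normalization exactness asserted at 1e-9 (fixed reference);
oracle agreements at 1e-12; REML optimizer xatol 1e-4 on log-variances.
Degenerate inputs: single-level factors are dropped; rank-deficient designs
use pivoted QR; constant features are retained but flagged (forests handle
them); single-class folds raise. Every stochastic step takes an explicit
seed, derived streams stay below 2³¹, and two end-to-end runs under one seed
produce byte-identical tables — asserted by the determinism test.

Problem sizes in the test and acceptance suites (200 subjects × 300–500
proteins for calibration, 20 bootstrap replicates of 32 null
configurations, reduced classifier grids) were chosen to give the binomial
and Monte-Carlo precision each assertion needs on a single CPU.
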