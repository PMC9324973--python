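# Methods

## The design being modelled

A recall-by-genotype study contrasts two groups drawn from the tails of a
weighted genetic risk score (GRS). Because genotype is fixed at conception,
group membership is (to first order) independent of the environmental and
behavioural confounders that afflict observational BMI–metabolite
comparisons, and tail selection concentrates the exposure contrast: the
expected standardized difference in a downstream trait between the upper
and lower q-tails of a score explaining r² of that trait's variance is

    d = 2 · sqrt(r²) · φ(Φ⁻¹(1 − q)) / q,

the truncated-normal tail-mean identity. At q = 0.30 and r² = 0.06 this is
d ≈ 0.57 — the package's reference design throughout.

## Synthetic cohort generator

`rbgmet.simulate` draws the full causal chain:

1. **Genotypes**: dosages Binomial(2, MAF) per variant, MAF ~ U(0.05, 0.5),
   independent across variants. No linkage disequilibrium is modelled —
   the score the design assumes uses near-independent variants, and LD
   would change nothing downstream of the score.
2. **Score and BMI**: BMI = μ_sex + σ_sex·(√r²·GRS_z + √(1−r²)·ε), so the
   score explains exactly r² (default 0.06) of within-sex BMI variance.
   Sex-specific means/SDs default to 24.9 (4.44) kg/m² male, 25.0 (5.42)
   female; sex is Bernoulli(0.4 male); age ~ N(24.5, 0.8) years. Weight,
   fat mass, lean mass and waist-hip ratio are deterministic-plus-noise
   functions of BMI. An optional age profile scales the genetic effect per
   age, producing the characteristic divergence of the recall groups from
   early childhood when a longitudinal BMI series is requested.
3. **Metabolome**: on a latent log scale, each metabolite is
   z = sign·√|R²|·BMI_z + √(1−|R²|)·(√ρ·F_c + √(1−ρ)·ε), with F_c a shared
   per-cluster factor (within-cluster residual correlation ρ, default 0.6)
   and abundance = exp(log 10⁶ + z), a log-normal peak-area scale (Model-1
   inputs are rank-normalized anyway; a positive scale is needed only so
   fold changes are meaningful). Missing cells are masked in **exact**
   counts — uniformly (MCAR) or from the bottom of the distribution
   (left-censoring, the detection-limit mechanism) — so the generated
   missingness pattern, and hence every QC disposition, is a deterministic
   oracle for tests.

The default panel composition (`default_metabolome_spec`) is 1,216
metabolites: 895 clean endogenous + 205 endogenous with >20% missingness
(excluded by QC) + 10 clean xenobiotics + 68 high-missing xenobiotics
(presence/absence) + 38 xenobiotics detected in fewer than 11 samples
(excluded), i.e. 973 analyzed traits (905 continuous, 68 binary). Twenty-
nine clean endogenous metabolites carry true BMI effects with |R²| drawn
from U(0.17, 0.32) — chosen so that detected effects land at |β| ≈ 0.2–0.4
SD under a 0.56-SD BMI contrast — in a cluster layout of one 11-block, one
4-block, one 2-block and 12 singletons (15 clusters), 25 negative and 4
positive. One presence/absence xenobiotic carries a latent R² = 0.30 with
50% left-censoring, which yields a detection odds ratio near 0.6.

The default *eligible pool* for study-scale fixtures is 1,250, so the full
30% tails are 375 per group; `select_recall_groups` also accepts an
`n_per_group` cap (most extreme first) for designs that assay fewer samples
than the tails contain.

**What the generator does not emulate**: real LD and allele-frequency
spectra, assay batch/drift structure, non-normal metabolite distributions
beyond log-normality, genuine biological pathway correlations, and
genotyping error. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artefact of real cohort data.

## Preprocessing rules

- Sample QC: exclude samples with >50% missing cells or beyond ±5 SD on
  either of the first two principal components of the median-filled,
  standardized log-abundance matrix. These thresholds are this package's
  defaults (chosen so clean data lose no samples), fully configurable.
- Dispositions: missingness **strictly greater** than 20% triggers the
  rule (exactly 20% is retained); endogenous → excluded, xenobiotic →
  presence/absence unless detected in fewer than 11 samples (→ excluded).
  Only the <11-present rule is applied to binary traits by default; a
  symmetric (≥11 absent) rule exists but is off.
- Imputation (continuous block only): `forest` is an iterative
  ensemble-regression imputer (scikit-learn `IterativeImputer` with
  extra-trees estimators, run on the log scale, observed cells untouched,
  seed-deterministic); `median` is the deterministic fallback. The forest
  imputer's contract — iterative, reproducible, beating column-mean
  imputation on MCAR data with correlated features — is what the tests
  enforce; it is not a numerical clone of any particular R implementation.
  The analysis drivers use `median` at the 905-metabolite scale, where the
  tree ensemble would dominate runtime without affecting any reported
  quantity (Model-1 inputs are re-ranked after imputation).
- Transformation: rank-based inverse normal with Blom offsets,
  y = Φ⁻¹((rank − 3/8)/(n + 1/4)), average ranks for ties; the offset is
  configurable. Blom is the metabolomics/GWAS convention.

## Association models

Model 1 is OLS of the transformed metabolite on group (low = 0); with a
binary regressor this is algebraically the pooled-variance two-sample
t-test (β = difference of means; R² = t²/(t² + df)), an identity the test
suite asserts at 1e-10 against a hand-written closed form that also powers
the vectorized resampling loop. Model 2 is a maximum-likelihood logistic
fit with Wald CIs; complete separation is flagged and falls back to a
Fisher exact p with no odds ratio. The pseudo-R² is the variance-function
form R²_V = 1 − Σ[(y−μ̂)²/V(μ̂)] / Σ[(y−μ̄)²/V(μ̄)], V(μ) = μ(1−μ).
BH correction is applied separately to the Model-1 and Model-2 families;
a combined-family option exists but is off. Log₂ median fold change uses
the raw (untransformed, unimputed) matrix over observed cells only; a zero
median or an empty group yields an undefined (NaN) value, not an error.

## Power

`analytic_power` evaluates the two-sided two-sample noncentral-t power at
ncp = √R²·d_BMI·√(n/2) with df = 2n − 2. d_BMI may be supplied directly,
derived from group means over a reference SD, or derived from (q, r²) via
the tail identity. The reference SD defaults to the **full-cohort**
sex-pooled SD √((σ_M² + σ_F²)/2), not the within-group SDs — within-group
SDs are shrunk by the selection itself and understate the population
scale. `min_r2_for_power` inverts the monotone power function by Brent
root-finding to 1e-6. `simulate_power` is the independent Monte Carlo
cross-check, drawing the full selection → BMI → metabolite chain per
replicate. Where scipy's noncentral-t tail underflows to NaN (very large
ncp), the normal closed form Φ(ncp − z₁₋α/₂) + Φ(−ncp − z₁₋α/₂) is used;
for the group sizes involved the two agree within 0.005.

The reference design (375/group, d_BMI = 2.78/4.954 = 0.561, α = 0.05)
gives 92.9% power at R² = 0.20 and a minimum detectable R² of 0.133 for
80% power. The published planner that motivated these targets reports 94%
and 0.126 with unpublished internals; the chain model reproduces both
within ~1.5 points / 0.008, which is the documented contract.

## Robustness analyses

- **Adjusted models**: covariates enter as fixed effects; categorical
  covariates expand to indicator contrasts against the most frequent
  level; collinear columns are dropped with a warning.
- **Resampling**: 100 iterations of a 50/50 group-stratified split;
  discovery instance = BH < 0.05 within the discovery half, joint instance
  = replication-half nominal p < 0.05 with concordant sign; robust at ≥ 20
  joint instances. The split ratio, per-half rules and iteration count are
  package defaults (the protocol this emulates published only the
  20-instance threshold); all are configurable and logged.
- **Clustering**: average-linkage tree on 1 − |Spearman ρ| cut at 0.5;
  each cluster's representative is the member most |correlated| with the
  cluster's first principal component (singletons represent themselves).
  This is a deliberate, documented approximation to "independent principal
  variables" representative selection, whose exact published variant is
  not specified; the cut height is configurable. Distances use |ρ|, so the
  partition is invariant to sign flips and input order (tested).
- **Measured-BMI models**: additive, interaction (product-term p equals
  the nested-model F-test p, tested), and per-group modes.
- **Diet tests**: ordinal preferences vs group by Wilcoxon rank-sum;
  preference → metabolite slopes with and without sex + group adjustment.

## Pipeline and reproducibility

`run_pipeline` executes score → recall → characterization → QC →
association → power → robustness, writing every artifact as tab- or
comma-separated text plus a JSON manifest whose stage counts must
reconcile. One global seed fans out to per-stage seeds via a CRC32 hash of
the stage name, so stages are individually reproducible and two runs with
the same config are byte-identical (tested). In synthetic mode the
metabolome is generated **after** recall, on the recalled samples only —
a recall study assays only what it recalls — so the generator's intended
dispositions refer to the assayed set.

## Problem sizes used by the test suite and drivers

Study-scale fixtures use a 1,250-person eligible pool (940 variants), 375
per tail, and the 1,216-metabolite panel; calibration checks use n =
20,000; the Monte Carlo power cross-check uses 20,000 replicates; the
global-null false-discovery sweep uses 500 simulations of 905 tests; the
resampling checks use 100 iterations. These sizes give Monte Carlo errors
comfortably inside every asserted tolerance while keeping the whole suite
in the tens of seconds.

## Known limitations

- The power model treats the metabolite as jointly normal with BMI and
  analyses as pooled-variance t; heavy censoring or strong non-normality
  on the raw scale is only handled insofar as rank-normalization repairs
  it.
- The forest imputer is a contract-compatible stand-in, not a numerical
  replica of any specific published imputer; imputation is pluggable.
- Single-study internal resampling quantifies stability, not external
  replication.
- A realized cohort can draw a tail contrast noticeably away from the
  design expectation (SE ≈ 0.06 SD at 375/group); the bundled drivers
  report both the realized and the design-value power for exactly this
  reason.
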