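# Methods

## Scope

`pedlmm` implements two-stage ("GRAMMAR-type") mixed-model association
scans for quantitative traits in family cohorts with repeated
measurements, plus the machinery needed to evaluate them without any
external data: pedigree kinship, genotype QC, a synthetic cohort
generator, and a replicate power protocol.  Everything below is the
package's own account of what is computed and why.

## Kinship and the relationship matrix

Expected kinship is computed by the classical recursion over a
topologically ordered pedigree: φ(a,a) = ½(1 + φ(father_a, mother_a)),
φ(a,b) = ½(φ(father_a, b) + φ(mother_a, b)) for b processed before a.
Founders are taken as unrelated and non-inbred, so kinship between
families is exactly zero and the matrix is block-diagonal.  The
random-effect covariance used by all models is the additive
relationship matrix A = 2Φ, i.e. Var(G) = A·σ²_G.  (Some notational
traditions write Var(G) = Φσ²_G with Φ already meaning the
relationship matrix, others 2Kσ²_G with K the kinship matrix; this
package standardizes on A = 2 × kinship throughout.)  Pedigrees must
be complete: a half-specified parent is rejected rather than patched
with a dummy founder, which keeps the recursion's preconditions exact.
Individual IDs are treated as opaque strings and must be globally
unique, because kinship, genotype and phenotype structures are keyed
by IID alone.  X-chromosome kinship is not implemented (the intended
analyses are autosomal).

The recursion is verified in the test suite against an independent
Monte-Carlo oracle that gene-drops two uniquely labelled alleles per
founder and counts identity-by-descent over 10⁵ replicates, including
an inbred full-sib-mating fixture (self-kinship 0.625).

## Quality control

`apply_qc` excludes samples first (missing-genotype fraction strictly
above 0.5 by default), then filters SNPs on statistics recomputed from
the retained samples:

| filter      | default | boundary semantics                      |
|-------------|---------|-----------------------------------------|
| MAF         | 0.01    | fails strictly below the threshold      |
| call rate   | 0.90    | fails strictly below the threshold      |
| HWE p value | 1e-6    | fails at p ≤ threshold (inclusive)      |

The Hardy–Weinberg test is the exact conditional test: given the
allele counts, it enumerates every attainable heterozygote count and
sums the conditional probabilities no larger than the observed one,
with log-factorial accumulation for numerical stability.  The exact
test was chosen over the chi-square because it is stable at low
counts; a chi-square variant is available for cross-checking
(`hwe_method="chisq"`).  HWE is tested on all retained samples despite
relatedness — matching common QC practice on family data — with an
optional restriction to a caller-supplied subset (e.g. founders) via
`hwe_sample_ids`, off by default.  After sample exclusion, dosages are
re-coded if needed so the counted allele is the minor allele among
retained samples; every per-SNP failure reason is recorded in the
`QCReport`.

## Stage 1: the polygenic mixed model

For each outcome mode the model is y = Xβ + Zg + e with
g ~ N(0, σ²_G A) and e ~ N(0, σ²_e I).  The four modes collapse the
long-format phenotype table differently:

* **baseline** — one row per individual, wave-1 phenotype and
  covariates (age, sex, smoking, medication);
* **mean** — one row per individual; outcome and age are means across
  waves, smoking and medication are taken at wave 1;
* **longitudinal_A** — one row per observation, time-varying
  covariates, no explicit time term;
* **longitudinal_B** — longitudinal_A plus a numeric time score
  z_t ∈ {1, 2, 3} as a common linear trend.

The polygenic term is the only random effect, in all modes: the
longitudinal models deliberately contain no separate non-genetic
subject intercept and no random slope, mirroring the model family the
package exists to study.  The mean-outcome model is likewise fitted
"as written", with an unstructured residual variance — no attempt is
made to model the fact that a mean of three measurements has smaller
sampling variance.  Medication is an ordinary covariate; no
blood-pressure imputation for treated individuals is attempted.

Estimation is REML (not ML: it removes the fixed-effect degrees of
freedom from the variance estimates, which matters at p = 5–6
covariates).  The implementation eigendecomposes M = ZAZᵀ once at
observation level — one code path for balanced and unbalanced designs —
so that for a given variance ratio δ = σ²_e/σ²_G the covariance is
diagonal in the rotated basis; β and σ²_G are then profiled out
analytically and the restricted likelihood is maximized over δ by a
100-point log-scale grid on [1e−5, 1e5] followed by bounded local
refinement to 1e−8 on log δ.  After the search, the exact σ²_G = 0
corner (pure OLS) is evaluated in closed form and returned whenever it
is at least as likely, so the boundary case degenerates to ordinary
least squares exactly rather than to δ = 10⁵.  Fixed effects are GLS
at the optimum; the polygenic prediction is the BLUP
ĝ = σ̂²_G A Zᵀ V̂⁻¹(y − Xβ̂).

The stage-2 outcome is the **conditional** residual
ê = y − Xβ̂ − Zĝ — the BLUP is subtracted, not just the fixed-effect
fit — averaged within individual in the longitudinal modes.

Correctness anchors (all in the test suite): a dense-formula 2-D
grid-search oracle on n ≤ 12 family fixtures (agreement within 1e−4
log-units); exact degeneration to OLS at σ²_G = 0; equivalence with a
standard two-level random-intercept model (statsmodels MixedLM) when
A ∝ I with balanced repeats; invariance under individual reordering;
and recovery of (σ²_G, σ²_e) = (20, 10) within 10% averaged over 200
simulated trio cohorts of 600 individuals.

## Stage 2: residual association scan

Each SNP is tested by OLS of the per-individual residual on an
intercept plus minor-allele dosage (complete cases per SNP; no dosage
imputation), with a two-sided p value from the t distribution on
n_used − 2 degrees of freedom.  Additive 0/1/2 coding only.  SNPs with
fewer than 3 complete cases or constant dosage are untestable and
carry no rank.  Ranking is by ascending p, ties broken by genomic
position then SNP id, so results are deterministic.  No
multiple-testing or genomic-control correction is applied: the
intended comparisons are rank-based and use raw p values.

A caveat documented here and measured in the acceptance checks: the
residual test is **conservative** under polygenic structure, because
BLUP subtraction removes part of the family-shared signal that
transmitted genotypes also carry.  At high heritability (the default
generator conditions give h² = 2/3 in trios) the empirical type-I
error at nominal 0.05 is ≈ 0.024–0.031 and the null p-value
distribution is visibly non-uniform in the conservative direction;
at h² ≈ 0.4 the rate is ≈ 0.04.  The deflation is strongest in the
longitudinal and mean modes (type-I ≈ 0.016 and 0.019 under the same
conditions), whose averaged residuals have the smallest noise relative
to the shrunken signal.  Against *permuted* dosages — which break the
genotype–family alignment — the p values are uniform, as the scan's
property tests assert.

## Synthetic cohorts

The generator emulates a pedigree-based longitudinal blood-pressure
panel: configurable family structures (trios by default, 200 families
≈ 600 individuals; nuclear and three-generation layouts available),
three exam waves five years apart, and a dense SNP panel
(2,000 by default) produced by gene dropping — founder alleles are
Bernoulli draws at each SNP's frequency (uniform on [0.05, 0.5] by
default), offspring receive one uniformly chosen allele per parent.
One causal variant is planted with MAF 0.367 and position 47,956,424,
matching a well-known blood-pressure-associated common variant in
*MAP4* on chromosome 3 (rs6442089), so that fixtures resemble the
motivating cohort.  SNPs are otherwise independent; no linkage
disequilibrium is simulated.

Phenotypes for individual (i,j) at wave t are

```
y_ijt = β₀ + β_age·age + β_male·male + β_smoke·smoke + β_med·med
        + v·z_t + γ·SNP + G_ij + s_ij·(z_t − z̄) + ε_ijt
```

with G ~ MVN(0, 2Φσ²_G) sampled through an eigen-factor of the
relationship matrix, subject slopes s_ij ~ N(0, slope_sd²), and iid
ε ~ N(0, σ²_e).  The subject-specific slopes are centered at the
mid-study wave: they perturb any single wave (adding slope_sd² to the
baseline noise) but cancel from a subject's mean, which is precisely
the mechanism by which traits with volatile trajectories reward
longitudinal over baseline analysis.  Defaults: σ²_G = 20,
σ²_e = 10 mmHg², β_age = 0.4/yr, β_male = 3, β_smoke = 2.5,
β_med = −6, v = 1.5, γ = 4 mmHg per allele copy.  Two presets differ
only in trajectory volatility and level: `sbp-like`
(slope_sd = 0.5, intercept 120) and `dbp-like` (slope_sd = 4,
intercept 80); the magnitude separating them is a package choice, not
an estimate.  A `null` preset sets γ = 0.

Genotypes and covariate trajectories (ages by generation; smoking with
10%-per-wave switching; near-absorbing medication uptake) are drawn
once per configuration and held fixed while phenotypes are redrawn per
replicate, mirroring designs that pair real covariates and genotypes
with repeated phenotype simulations.  Replicate r uses the child seed
stream `SeedSequence(master, spawn_key=(r+1,))`, recorded in each
table's metadata so any single replicate can be replayed.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: linkage disequilibrium, genotyping
error, ascertainment, non-normal phenotypes, time-varying SNP effects,
gene–environment interaction, and missing phenotype waves.

## Power evaluation

`estimate_power` runs every requested mode on each of n_replicates
(default 200) phenotype replicates over one fixed genotype set and
counts, per criterion, the replicates in which the causal SNP is
selected: rank ≤ N (top-N) or p strictly below α (cutoff) — both
inequalities deliberately strict/inclusive as stated, so a p exactly
at the cutoff does not count.  Selection sets are nested, so the
estimated proportions are monotone in N and α by construction;
binomial standard errors are attached.  A replicate whose pipeline
fails is dropped from that mode's denominator and logged; an
untestable causal SNP counts as not selected.

Because genotypes, covariates and therefore the design matrices are
fixed across replicates, each mode's eigendecomposition and per-SNP
dosage statistics are computed once and reused; a full 200-replicate,
4-mode, 2,000-SNP run completes in well under a minute on one CPU.

At the default effect size (γ = 4 ≈ 1.3 residual SD) all modes
saturate near proportion 1.0 at the default cohort size, so the
volatile-trajectory comparison (`dbp-like`: longitudinal ≥ baseline at
matched criteria) holds with ties; the mechanism is still visible in
the stage-1 variance decomposition, where the baseline mode's residual
variance absorbs the full slope_sd² while the longitudinal mean does
not.  Under the stable-trajectory preset the ordering may legitimately
reverse and is reported, not asserted.

## Numerical choices and degenerate inputs

* δ search bounds [1e−5, 1e5], 100 grid points, refinement tolerance
  1e−8 on log δ; the exact OLS corner is checked afterwards.
* Eigenvalues of ZAZᵀ (and of A) below −1e−8 × max raise; tiny
  negatives are clipped to zero, with a warning for A.
* Rank-deficient fixed-effect designs raise an error naming the
  collinear columns (QR with pivoting).
* Stage-2 p values are clipped into (0, 1]; a perfect fit is floored
  at a tiny positive residual sum of squares rather than reporting
  SE = 0.
* Ties in ranking, monomorphic SNPs, all-missing SNPs, empty QC
  results, and all-untestable scans all have defined, tested behavior
  (monomorphic → HWE p = 1, MAF 0; all SNPs removed → warning, not
  error; empty ranking → warning).
* Default master seed for all simulations: 20180818.

## Known limitations

The conservativeness of the residual test at high heritability is
inherent to the two-stage design and is reported, not corrected (no
GRAMMAR-gamma factor, no exact per-SNP mixed-model test).  The
mean-outcome model's residual variance conflates measurement and
sampling variance.  The longitudinal models ignore serial correlation
beyond the polygenic term.  Binary PLINK files, VCF input, X-linked
kinship, dosage imputation and multivariate (two-trait) models are out
of scope.
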