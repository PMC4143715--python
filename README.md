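# pedlmm

Two-stage linear mixed-model association scans for pedigree-based
longitudinal GWAS.

## The problem

Family cohorts measured repeatedly over time — for example several
hundred related individuals with systolic/diastolic blood pressure,
age, smoking and medication recorded at three exam waves, plus a dense
SNP panel — pose two problems for association testing: relatedness
(phenotypes of relatives are correlated through shared polygenes) and
repeated measures (how should three correlated measurements per person
enter a per-SNP test?).  `pedlmm` implements the GRAMMAR family of
answers, for analysts comparing how the choice of outcome — baseline
measurement, mean across waves, or full longitudinal data — affects
the power to detect a variant.

## The model

Stage 1 fits, once per outcome definition, the polygenic linear mixed
model

```
y = Xβ + Zg + e,    g ~ N(0, σ²_G A),    e ~ N(0, σ²_e I)
```

where A = 2Φ is the additive relationship matrix from the pedigree
(Φ the kinship matrix, computed by the classical recursion), X carries
the covariates (intercept, age, sex, smoking, medication, optionally a
linear time score), and Z maps observations to individuals.  Variance
components are estimated by REML after one eigendecomposition of
`Z A Zᵀ`, which reduces the profiled restricted likelihood to a
one-dimensional search over the variance ratio δ = σ²_e/σ²_G.

Stage 2 takes the conditional residuals `ê = y − Xβ̂ − Zĝ` (per
individual; the mean over waves in longitudinal modes) and regresses
them on each SNP's minor-allele dosage by simple OLS, ranking SNPs by
p value.  Four outcome modes are provided: `baseline`, `mean`,
`longitudinal_A` (time-varying covariates) and `longitudinal_B`
(adds a common linear time trend).

Around the scans sit the standard supporting pieces: PLINK-style
ped/map/fam text I/O, the usual pre-association QC filters (minor
allele frequency, call rate, an exact Hardy–Weinberg test,
sample-level missingness), a synthetic family-data generator
(gene-dropped genotypes with a planted causal variant, replicate
longitudinal phenotypes), and a replicate power-evaluation protocol
that counts how often the causal SNP is recovered by top-N rank or
p-value cutoff.

## Worked example

```python
import pedlmm as pl

cfg = pl.preset("dbp-like", n_families=100, n_snps=500)
ped, genotypes, phenos = pl.simulate_dataset(cfg, n_replicates=1)
result = pl.run_pipeline(ped, genotypes, phenos[0], mode="longitudinal_A")
print(result.stage1.summary())
```

prints

```
Polygenic linear mixed model (REML)
====================================================
mode:             longitudinal_A
observations:     900
individuals:      300
converged:        True
REML loglik:      -2933.8720
sigma_g2:         22.1084
sigma_e2:         27.2166
h2 (sg2/(sg2+se2)): 0.4482
----------------------------------------------------
effect              coef          se         z
const            81.9916      1.2509     65.55
age               0.4545      0.0197     23.08
male              3.8867      0.6121      6.35
smoke             2.6422      0.5584      4.73
med              -4.8597      0.6040     -8.05
====================================================
```

The stage-1 fit splits the phenotypic variance into a polygenic part
(σ²_G ≈ 22, shared along the pedigree) and a residual part
(σ²_e ≈ 27, which under this volatile-trajectory preset also absorbs
the subject-specific slope variation), and estimates each covariate's
fixed effect in mmHg.  The scan table then ranks every SNP:

```
      SNP      BETA       SE            P  RANK
rs6442089  0.988326 0.123436 2.661991e-14     1
 snp00214 -1.029714 0.284363 3.446230e-04     2
 snp00157  0.376473 0.134155 5.342289e-03     3
```

Here the planted causal variant (MAF 0.367) is recovered at rank 1;
`BETA` is the effect of one minor-allele copy on the residual scale.

The same pipeline is available from the shell:

```
pedlmm simulate --preset dbp-like --out sim/
pedlmm qc --ped sim/cohort.ped --map sim/cohort.map --out-prefix sim/qcd
pedlmm scan --fam sim/cohort.fam --ped sim/qcd.ped --map sim/qcd.map \
            --pheno sim/pheno_rep000.tsv --mode longitudinal-a --out scan.tsv
pedlmm power --preset dbp-like --replicates 200 --out-prefix power
```

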