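# priorblup

Genomic selection with GWAS-derived prior marker information.

In sheep and other livestock, genomic best linear unbiased prediction
(GBLUP) estimates breeding values for traits such as weaning weight from
genome-wide SNP genotypes, but it assumes every marker contributes equally
to the trait. `priorblup` implements the prior-marker refinement of that
scheme: a FarmCPU-style association scan on a discovery population ranks
markers, the top-k% "prior" markers and the remaining markers build two
separate VanRaden relationship matrices on a validation population, and the
two kinships are blended by their REML genetic-variance shares before
prediction. The package is aimed at animal-breeding researchers who want a
transparent, fully scriptable implementation of this pipeline — from PLINK
files and quality control through cross-validated accuracy — plus a
simulator that generates populations with the matching statistical
structure (LD, polygenic + QTL architecture, herd/birth-type effects) for
method evaluation.

## The model

GBLUP fits the mixed model

    y = Xb + Zu + e,   u ~ N(0, G σ²ₐ),   e ~ N(0, I σ²ₑ)

where `y` are phenotypes (kg), `X` carries herd and birth-type fixed
effects, and `G` is VanRaden's genomic relationship matrix

    G = Z Z′ / (2 Σᵢ pᵢ(1 − pᵢ)),   Z = M − 2p

with `M` the allele-dosage matrix and `pᵢ` the observed frequency of the
counted allele. Variance components are estimated by average-information
REML (with EM fallback steps), heritability is `h² = σ²ₐ/(σ²ₐ+σ²ₑ)`, and
breeding values solve Henderson's mixed-model equations, predicting
validation animals through their genomic relationships to the training set.

The prior-marker refinement partitions the markers into the GWAS top-k%
set (kinship `G₁`) and the remainder (`G₂`), fits a single-kinship REML
model with each, and blends

    G₃ = γ G₁ + (1 − γ) G₂,   γ = σ²_G₁ / (σ²_G₁ + σ²_G₂).

Prediction accuracy is scored by five-fold cross-validation: the mean
Pearson correlation between held-out GEBVs and fixed-effect-adjusted
phenotypes, divided by √h². "Promotion" is the percent change of the G₃
accuracy over the plain-G baseline.

The association scan is a FarmCPU-style iteration: a fixed-effect marker
scan with current pseudo-QTNs (large-effect markers promoted to covariates)
alternates with a random-effect step that re-selects the pseudo-QTN set by
the REML likelihood of a kinship built from the candidate markers
themselves, until the set stabilizes.

## Worked example

```python
from priorblup import SimConfig, simulate_population, run_two_group_design

cfg = SimConfig.scaled_down(600, 1500, n_qtl=10, h2_target=0.3, seed=42)
geno, pheno, truth = simulate_population(cfg)
report = run_two_group_design(geno, pheno, fractions=(0.05, 0.10),
                              seed=1, directions=("1to2",))
print(report.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

which prints

```
direction  prior_fraction matrix  genetic_variance  environmental_variance  heritability  weight  accuracy  promotion_pct
     1to2             NaN      G             4.484                   6.281         0.417     NaN     0.451            NaN
     1to2           0.050     G1             1.521                   9.122         0.143   0.269       NaN            NaN
     1to2           0.050     G2             4.144                   6.697         0.382   0.731       NaN            NaN
     1to2           0.050     G3             3.951                   6.623         0.374     NaN     0.544         20.560
     1to2           0.100     G1             2.016                   8.675         0.189   0.338       NaN            NaN
     1to2           0.100     G2             3.941                   6.898         0.364   0.662       NaN            NaN
     1to2           0.100     G3             4.225                   6.424         0.397     NaN     0.504         11.730
```

Reading the table: group 1 (300 animals) was scanned with FarmCPU; on
group 2 the plain all-marker GBLUP reaches a cross-validated accuracy of
0.451 with h² ≈ 0.42. Blending the top-5% prior kinship (weight γ = 0.269,
set by the two single-kinship REML genetic variances 1.521 and 4.144) with
the remainder kinship raises accuracy to 0.544, a promotion of +20.6%;
the top-10% prior gives +11.7%. Within a scenario the G₁ and G₂ weights
always sum to one, and every heritability equals its row's
σ²ₐ/(σ²ₐ+σ²ₑ) exactly.

A statsmodels-style object API sits underneath for finer control:

```python
from priorblup import GBLUP, condition_psd, vanraden_grm

g = condition_psd(vanraden_grm(geno))
result = GBLUP.from_tables(pheno, g).fit()   # AI-REML
print(result.summary())                      # variance components, h2, fixed effects
gebv = result.predict(["ind0001"])           # GEBV table, "ind0001" withheld
```

There is also a thin CLI (`priorblup simulate / qc / gwas / grm / reml /
predict / pipeline`) wiring PLINK filesets and delimited phenotype tables
to the same functions.

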