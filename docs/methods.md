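# Methods

This note documents the statistical models implemented in `priorblup`, the
design decisions behind them, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Data model and quality control

Genotypes are biallelic autosomal SNP dosages in {0, 1, 2} counting the A1
allele of the PLINK `.bim` file (column 5), with a reserved integer
sentinel for missing calls; coordinates are 1-based as in `.bim`. The QC
cascade applies, in order, per-marker missingness, per-sample missingness,
minor-allele frequency and a Hardy–Weinberg exact test, each stage on the
matrix surviving the previous one — so, e.g., allele frequencies are
computed after high-missingness samples are gone. Default thresholds
follow common PLINK practice (`--geno 0.1 --mind 0.1 --maf 0.01 --hwe
1e-6`) and are overridable. The HWE filter is the standard exact test on
genotype counts (sum of probabilities of heterozygote counts no more
likely than the observed one, no mid-p correction), computed with
log-gamma arithmetic; a chi-square variant is available. Missing calls are
replaced by the marker's mean observed dosage before any numeric analysis;
haplotype-phasing imputation is out of scope, and with chip-scale
missingness (a few percent) mean imputation perturbs the relationship
matrix negligibly relative to the marker-sampling noise.

## VanRaden relationship matrices and blending

The kinship is VanRaden's first estimator: dosages column-centered by
`2pᵢ` and the cross-product scaled by `2Σpᵢ(1−pᵢ)`. `pᵢ` is the observed
frequency of the *counted* allele in the samples actually present in the
matrix, not the folded minor-allele frequency — folding would break both
the centering and the exact identity that the all-marker G equals the
denominator-weighted recombination of any marker partition (a property
the test suite checks to 1e-10). Monomorphic markers carry no information
and are dropped from the denominator with a warning.

Prior/remainder blending follows the trait-specific multi-kernel idea:
`G₃ = γG₁ + (1−γ)G₂` with `γ` the share of the genetic variance explained
by `G₁`, where the two variances come from two *separately fitted*
single-kinship REML models. A joint two-component fit would be the more
efficient estimator of the same shares but is deliberately out of scope:
the separate fits match how per-matrix variance components and
heritabilities are conventionally tabulated, and the enforced constraint
γ + (1−γ) = 1 makes the weights interpretable regardless.

Matrices destined for REML are conditioned by diagonal inflation (default
ε = 1e-6, doubled until the smallest eigenvalue clears 1e-8). Prediction
itself never inverts G — it works through `V = σ²ₐG_tt + σ²ₑI`, which is
positive definite whenever σ²ₑ > 0 — so conditioning only matters for
badly rank-deficient kinships built from few markers (e.g. the pseudo-QTN
kinships inside the association scan).

## REML and GBLUP

Variance components maximize the restricted likelihood by
average-information updates with step-halving and an EM-style
scaled-gradient fallback whenever the AI step is not an ascent step.
The records-block of G is eigendecomposed once per fit, making each
iteration O(n²); starting values are σ²ₐ = σ²ₑ = var(y)/2, components are
floored at 1e-8 × var(y), and convergence requires the log-likelihood to
move by less than 1e-8. The reported log-likelihood omits the additive
constant −(n−p)/2·log 2π, which affects no comparison the package makes.
A genuinely flat or boundary-peaked likelihood (small n, weakly
informative kinship) is reported honestly: σ²ₐ clamps to 0, h² = 0, and
cross-validated accuracy — which divides by √h² — is declared undefined
rather than fabricated.

Breeding values solve Henderson's mixed-model equations on the training
records, in the equivalent variance-matrix form
`û = σ²ₐ G[:, t] V_t⁻¹ (y_t − X_t β̂)` with β̂ the GLS fixed-effect
estimate. All individuals share one relationship matrix; a validation
animal's GEBV flows through its relationship to the training set, so an
exact genotype copy of a training animal receives exactly its GEBV. On any
kinship of the form ZZ′/d this construction is algebraically identical to
ridge-penalized marker BLUP with penalty σ²ₑd/σ²ₐ; the test suite holds
the two routes together to 1e-6, which is the strongest single correctness
guard in the package.

Fixed effects (herd, birth type) are treatment-coded with the first level
as reference; aliased columns are detected by pivoted QR and dropped with
a log message.

## The association scan

The scan regresses the phenotype on each marker alongside the fixed
covariates and the current pseudo-QTN dosages, reporting the marker
coefficient's two-sided t-test p-value. It is computed by Frisch–Waugh
residualization against the shared covariate block, vectorized over
markers; markers collinear with the covariates are flagged with p = 1.
Markers inside a pseudo-QTN's 1 Mb spacing window (including the
pseudo-QTN itself) are tested with that pseudo-QTN removed from the
covariates, preventing self-masking artifacts.

The iterative model alternates this fixed-effect scan with a
random-effect selection step: candidates are the spacing-filtered most
significant markers with p < 0.01, candidate set sizes {2, 4, 8, 16} are
scored by the REML likelihood of a kinship built from the candidate
markers, the previous set is always kept among the options (making the
accepted likelihood non-decreasing across iterations), and iteration
stops when the selected set repeats or after 10 iterations. Two guards
matter in practice: if the first scan's smallest p-value is above 0.01/m
the iteration stops immediately with no pseudo-QTNs — without this, chance
top markers promoted to covariates inflate the null false-positive rate
several-fold — and no genomic-control correction is applied (QQ data are
exported for inspection instead). Principal components are not default
covariates; the default fixed effects are herd and birth type only, with
PCs available through the design interface if population structure
warrants them.

Prior-marker selection takes the round(fraction × m) smallest p-values
(round-half-even), breaking ties by (p, chromosome, position). The
genome-wide significance threshold is Bonferroni's α/m, with α
configurable because both α = 0.05 and α = 1 readings are in circulation
for chip-scale scans.

## Cross-validated accuracy and the two-group design

Accuracy is computed by k-fold (default 5) cross-validation: per fold, a
fresh REML + GBLUP fit on the remaining folds, GEBVs for the held-out
animals through the shared relationship matrix, and the Pearson
correlation between held-out GEBVs and fixed-effect-adjusted phenotypes
(`y − Xβ̂` under the training fit; a raw-phenotype option exists). The
fold-mean correlation is divided by √h², with h² taken from the
full-group REML fit on the same matrix — one h² per matrix, as genetic
parameters are conventionally reported. Dividing by h² itself instead of
√h² is available as an option; the choice rescales all accuracies by a
common factor and leaves every promotion percentage unchanged. A single
CV repetition is the default, with paired fold assignments available for
matrix-to-matrix comparisons.

The two-group driver reproduces the full experimental layout: random
halves, FarmCPU on the discovery half, per-fraction G₁/G₂/G₃ construction
and REML on the validation half, five-fold CV for G₃ and the plain-G
baseline, in both directions. The report mirrors the conventional
genetic-parameter table (matrix, variances, heritability, weight,
accuracy, promotion).

One protocol property deserves emphasis: the blend weight γ and the h²
denominators are estimated on the whole validation group, including
animals that later serve as held-out folds. This is deliberate — it keeps
γ and the variance components fold-independent, as the tabulated layout
requires — but it means the blended matrix is weakly adapted to the trait
even when the "prior" markers are chosen at random: across 40 simulated
polygenic populations the random-prior blend showed a small positive
accuracy offset (≈ +0.015 ± 0.005) over the baseline. The pipeline's
claim therefore rests on the *additional* gain from GWAS selection, which
in matched simulations is several times that machinery offset
(≈ +0.09 vs ≈ +0.004 under the paired two-group protocol); the negative
control in the test suite asserts exactly that separation.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: by default
1007 ewes, 41,956 SNPs on 26 autosomes of 100 Mb (≈ one marker per 62 kb),
weaning weight with mean 28.27 kg and SD 3.19 kg, herd and birth-type
fixed effects of ±1–2 kg, and a narrow-sense heritability target of 0.30,
inside the 0.12–0.40 range typical for this trait.

Haplotypes come from a first-order Markov chain: a standard-normal latent
AR(1) process along each chromosome with correlation `exp(−d/ld_rho)`
between adjacent markers, thresholded at each marker's allele-frequency
quantile (frequencies uniform on [maf_min, 1−maf_min], with a post-hoc
floor so no marker drifts below the configured MAF). `ld_rho` is the LD
correlation length in bp (default 500 kb, giving r² ≈ 0.6 at 60 kb
decaying to ≈ 0.02 by 2 Mb, a sheep-like decay); 0 gives free
recombination. The trait is the sum of a QTL component (default 10 QTL
carrying half the genetic variance, normal effects, optional
allele-frequency scaling) and a polygenic background over all remaining
markers, rescaled so the in-sample TBV variance hits the target exactly,
plus independent normal residuals; phenotypes are recorded to 2 decimals.

Scaled-down fixtures use `SimConfig.scaled_down(n, m)`, which shrinks the
chromosome length in proportion to the marker count so the full-design
marker density — and hence the LD structure and the effective number of
independent genome segments per marker — is preserved. This matters: the
same marker count spread over full-length chromosomes is nearly LD-free,
which makes h² almost unidentifiable at desk-scale n (REML collapses to
the σ²ₐ = 0 boundary on unlucky draws) and would misrepresent the design
being emulated. A side effect is that scaled fixtures tag the genome more
tightly per marker than a sparse 50K chip, so simulated accuracies
(≈ 0.3–0.55 for plain G at n = 500) sit above the low end observed with
real chip data; directional and relative comparisons are unaffected.

What the generator does *not* emulate: pedigree and family structure,
selection over generations, genotyping error, allele-frequency spectra
shaped by demography, and population stratification beyond what the
Markov LD induces. Passing tests therefore demonstrate correctness of the
estimation machinery and the direction of the prior-marker effect under a
clean additive architecture — not that the pipeline's gains transfer to
any particular real population.

## Problem sizes and numerical choices

Simulation-based checks run at: REML recovery n = 1000 × m = 5000 over 20
seeds; the two-group directional comparison n = 1000 × m = 2000 over 10
seeds with prior fractions 5–20%; the scan type-I error n = 300 ×
m = 1000; tiny-instance likelihood oracles at n = 12 (restricted to
interior optima, since boundary estimates are clamped by design and a
relative comparison there is ill-posed); the SNP-BLUP duality at
n = 50 × m = 200. These sizes were chosen once as the smallest instances
at which each quantity is statistically stable.

Tie-breaking and edge rules are fixed and tested: marker selection sorts
by (p, chromosome, position); k-fold splits differ in size by at most one;
a fold whose GEBVs have zero variance records r = 0 with a warning;
promotion is undefined at a zero baseline; blending requires at least one
positive variance share and identical sample order in both kinships.

## Limitations

- Single trait, one record per animal; no maternal effects, repeated
  records, multi-trait models or single-step (pedigree + genomic) H
  matrices.
- The γ weights come from separate single-kinship fits, not a joint
  two-kernel REML; with strongly correlated kinships the separate fits
  overstate both shares (their interpretation, not the constraint, is
  affected).
- Bayesian whole-genome regression alternatives are out of scope.
- Accuracy against *true* breeding values is available only in simulation
  (where the generator's truth object exists); on real data the
  phenotype-based accuracy with the √h² denominator is what the package
  reports.
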