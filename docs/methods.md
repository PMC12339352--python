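# Methods

`saltol` evaluates saline–alkali (salt/alkalinity) stress tolerance in a
rice resource population grown under a control (CK) and a stress (AK)
field treatment over multiple years, and maps the resulting tolerance
phenotype with a kinship mixed-model GWAS. This note records the models,
the defaults and why, the numerical choices, and what the synthetic data
do and do not demonstrate.

## Phenotype model and the synthetic trial

The generator emulates a trial of `n_accessions` genotypes × `n_years`
years × 2 treatments with one plot-mean observation per cell and nine
yield-related traits (DW g, PH cm, TN, GN, TGW g, SR proportion, PL cm,
PW g, DH days). For accession *i*, year *j*, treatment *l* and trait *t*:

    y_ijlt = r_il · (μ_t + g_it + yr_jt + gy_ijt) + s_lt + gl_ilt + e_ijlt

with `g ~ N(0, VA_t)`, `yr ~ N(0, VY_t)`, `gy ~ N(0, VAY_t)`,
`gl ~ N(0, VAL_t)`, `e ~ N(0, Ve_t)`, and a per-accession tolerance ratio

    r_i,CK = 1,   r_i,AK = base + Σ_k β_k (x_ik − x̄_k) + ε_i,  ε ~ N(0, sd²)

clipped below at 10⁻³, where `x_ik` is the dosage of causal SNP *k*. Two
design choices matter and are deliberate:

* **The ratio multiplies the systematic part, not the realized CK value.**
  Multiplying the noisy CK observation would inflate the AK residual
  variance to roughly `r²Ve + Ve`; drawing fresh residuals per cell keeps
  both treatments at the stated `Ve`, so the REML model below is exactly
  correctly specified and the written-in components are the estimands.
* **Genotype×treatment effects are drawn for both treatments.** A
  stress-only interaction term is a half-variance component under the iid
  random-effects model and would bias its own recovery test; symmetric iid
  draws make `VAL` well defined.

Defaults are chosen once as field-realistic: trait means at typical
high-latitude japonica values (e.g. PH 95 cm, DH 100 d), variance
components scaled to the trait mean (genotype SD 12%, year / G×Y / G×L
SDs 4%, residual SD 8% of the mean), giving trait CVs in the 8–35% band
expected of a diverse resource panel. The stress ratio defaults to
`base = 0.8` (moderate stress depresses growth ~20%) with residual ratio
SD 0.05. SR is clipped to [0, 1] and count traits at 0 after simulation.

Genotypes are unlinked biallelic SNPs, dosage Binomial(2, p) with p
uniform on `maf_range` (default 0.05–0.5), spread over 12 chromosomes
with strictly increasing positions; an optional block-copy mode (founder
column copied with 10% per-call resampling) provides local LD for
region-level tests. Causal SNPs are drawn among markers with MAF ≥ 0.15:
a planted signal should segregate at common frequency to be a meaningful
recovery target at these sample sizes. Randomness uses one master seed
with named sub-streams (genotypes / effects / ratio / noise / genes), so
redrawing phenotype noise leaves genotypes untouched.

What the generator does **not** emulate: population structure and
relatedness (accessions are exchangeable draws), realistic LD decay and
recombination maps, trait-specific genetic correlations beyond those the
shared ratio induces, spatial field trends, and missing data patterns.
Passing recovery tests therefore demonstrates correctness of the
estimators under their assumed model, not robustness to confounding by
structure — on real panels the kinship term and PC covariates carry that
burden and λ should be inspected.

## Descriptive statistics

CV is `100·SD/mean` with the sample (n−1) SD. The Shannon–Weaver index
`H′ = −Σ Pi ln Pi` (nats) defaults to treating each distinct observed
value as a class — for n distinct plot means this gives the `ln n`
ceiling (ln 450 ≈ 6.11) — with the germplasm-standard k-class binned mode
(tails beyond μ±2σ, equal-width interior classes) as an option; the
grouping rule materially changes H′ and is always worth stating.
Correlations are pairwise-complete Pearson with t-distribution p-values.

## PCA, clustering, and the sign convention

PCA is an eigendecomposition of the sample correlation matrix of the
standardized (z-scored, mean-imputed) matrix; eigenvalues sum to the
trait count and per-component score variance equals the eigenvalue.
Because the membership step below is **not** sign-invariant, each
component is deterministically flipped so its largest-|loading| trait is
positive, and the flip pattern is reported in provenance. Retention rules:
Kaiser (`eigenvalue_gt(1)`), cumulative proportion (`cumulative_ge(0.8)`,
the default for the tolerance index), or fixed k. Clustering is Ward
minimum-variance (Ward.D2 updates) on Euclidean distances of the
standardized matrix, cut by maxclust, labels renumbered in order of first
appearance for determinism.

## Comprehensive tolerance score D

For one year, the tolerance index is `Si = 100·AK/CK` per accession and
trait (8 stress-responsive traits when SR is dropped via `drop_sr`; all 9
by default, configurable). The index matrix is standardized, decomposed
by correlation PCA, and components retained to 80% cumulative variance.
Per retained component the membership value is the min–max normalization
`Ui = (Si − Smin)/(Smax − Smin)` over accessions; weights are
`Wi = PVi/ΣPVi`; and `D = Σ Ui·Wi ∈ [0, 1]`, ranked descending with dense
ranks. D is invariant to accession/trait order and to positive rescaling
of index columns (correlation PCA), but **not** to the PC sign convention
or to additive shifts of a trait — both documented because they silently
change rankings if altered. Degenerate components (`Smax = Smin`) map to
0.5 with a warning.

## ANOVA, variance components and heritability

The fixed-effects ANOVA fits G + Y + L + G×Y + G×L by least squares with
sum-to-zero contrasts and Type III sums of squares (the design is
unbalanced the moment any plot is lost), F-testing each term against the
residual. The REML model (statsmodels `MixedLM`) treats year and
treatment as fixed and genotype, G×Y and G×L as iid random components;
negative components cannot occur under the profiled parameterization and
boundary (zero) solutions are accepted with a warning. Broad-sense
heritability across L treatments and Y years is

    R = VA / (VA + VAL/L + VAY/Y + Ve/(L·Y)) ∈ [0, 1].

## Mixed-model GWAS

The scan is the standard kinship MLM with P3D: VanRaden method-1
`K = ZZᵀ / 2Σp(1−p)` from mean-imputed dosages; eigendecomposition
`K = U S Uᵀ`; the null-model variance ratio `δ = σe²/σg²` estimated once
by REML on the rotated data (profiled restricted likelihood optimized
over log₁₀δ ∈ [−5, 5], bounded Brent, xatol 10⁻⁶); then each marker
tested by weighted least squares in the rotated basis with weights
`1/(sᵢ + δ)`, a two-sided t test on n − p − 1 df with the residual scale
re-estimated per marker. With K = I the procedure reduces exactly to the
OLS t test, which is the oracle equivalence the tests assert. Leading
eigenvectors of K (default 3) enter as fixed covariates. Markers are
pre-filtered at MAF ≥ 0.05 and missingness ≤ 20% (defaults; the filter is
reported), the Bonferroni cutoff is `log₁₀(m)` on the −log10 scale using
the post-filter marker count, p-values are floored at 10⁻³⁰⁰ for the log
transform, and `λ = median(χ²)/0.4549` is always reported but never used
to correct. Compression of the kinship into group means (as in
compressed-MLM software) is intentionally not implemented: it is an
efficiency device, not a statistical necessity at these problem sizes.

A note on reporting: some published tables print the signed `log₁₀(p)`
(negative) in a column labelled −LOG10(P); this package reports
`−log₁₀(p)` as a positive magnitude throughout.

## Candidate regions and variant classification

Around each significant marker a ±150 kb window (the reported LD-decay
scale for temperate japonica; configurable) is intersected with the gene
models, 1-based inclusive with the window clipped at coordinate 1 and
edges inclusive. The nearest gene is the minimal distance to the gene
span (0 inside a gene, with exon/intron context from the exon intervals;
ties broken by lower start). Region variants are classified exonic >
intronic > intergenic by interval overlap and SNP vs InDel by allele
length (any allele ≠ 1 bp ⇒ InDel). This is a region-level
classification, not a transcript-consequence predictor: no codon or
splice-site effects are computed.

## Problem sizes and what the checks compute

The recovery checks run at deliberately desk-scale sizes chosen as the
smallest that make the statistics stable: variance-component recovery at
200 accessions × 2 years × 2 treatments over 20 replicate seeds (medians
within 20% of truth); GWAS null calibration and power at 300 accessions ×
2,000 markers (λ within [0.9, 1.1], planted causal SNP the top hit in
≥90% of seeds). `scripts/acceptance.py` recomputes the same quantities
end-to-end from fresh simulations at the given seed. Real-data figures
from any specific field trial (per-trait F values, H′ values, cluster
sizes, variety scores) depend on unpublished phenotype records and are
not reproduced here; the package reproduces the *procedure* and its
worked analytic anchors (the Bonferroni threshold, the −log10 p
transforms, the nearest-gene distance arithmetic).

## Known limitations

* REML via `MixedLM` scales to a few hundred genotypes comfortably; very
  large panels would want a dedicated average-information REML.
* The single-marker GLS re-estimates the residual scale per marker
  (EMMAX-style t test); for small n this is slightly conservative
  relative to a full per-marker REML.
* Mean imputation (missing dosages, missing index cells) is simple and
  biased toward the mean; the imputation counts are logged so heavy
  missingness is visible.
* The tolerance index is undefined where CK = 0; such cells are left
  missing rather than extrapolated.
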