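# Methods

## Scope and model

`pleioscore` implements a pleiotropy scan: given per-trait catalogs of
published genome-wide significant lead variants and a genotyped case-control
cohort, it (i) builds one weighted genetic score per trait, (ii) quantifies
how much of each trait's own variance its score represents, (iii) tests
scores and individual variants for association with the disease under
covariate adjustment and FDR control, (iv) conditions candidate variants on
the known disease variants to remove pure-linkage signals, and (v) groups
the surviving novel variants into distinct loci.

### Genetic scores

For trait *t* with oriented weights `w_j ≥ 0` (log OR / log HR / slope,
always on the log or slope scale) and effect-allele dosages `d_ij`,

    S_it = ( Σ_j w_j d_ij ) / w̄_t ,   w̄_t = mean_j w_j .

Orientation flips any variant with a negative published effect (alleles
swapped, frequency complemented, sign negated), so the effect allele is
always the risk-/trait-increasing one.  The average-weight normalization
makes one score unit equal one risk allele of average effect.  Two
consequences worth noting: the score is invariant to rescaling all of a
trait's weights by a positive constant, and adding one effect-allele copy of
variant *j* moves the score by exactly `w_j / w̄_t`.  `w̄_t` is computed over
the variants actually present after filtering, keeping the "average risk
allele" interpretation within the analyzed set.  Missing dosages are
mean-imputed per variant (the cohort column mean, i.e. twice the cohort
allele frequency) — the standard dosage-score convention.

### Variance explained

*Binary traits.*  A liability-threshold model: with HWE genotype frequencies
`f_g` from the effect-allele frequency, solve one-dimensionally for the
baseline risk `K₀` such that `odds(K_g) = odds(K₀)·ORᵍ` and `Σ f_g K_g`
equals the trait prevalence (Brent's method on K₀ ∈ (0,1); the mean risk is
monotone in K₀ so the root is unique).  With `T = Φ⁻¹(1−K)` and threshold
shifts `m_g = T − Φ⁻¹(1−K_g)`, the liability-scale variance of one variant
is `Σ f_g m_g² − (Σ f_g m_g)²`.  Per-trait totals sum per-variant values
(additivity assumption; LD between a trait's lead variants is assumed
negligible by construction of the ±1 Mbp lead rule).

*Continuous traits.*  From the published slope, its standard error, and the
GWAS sample size n, `r² = z²/(z² + n − 2)` with `z = slope/se` — the exact
identity linking the t statistic and r² in simple linear regression.

*Survival traits.*  No liability mapping exists for hazard ratios; log-HR
variants contribute to scores but are flagged "not estimable" for variance.

Prevalences and GWAS sample sizes are required inputs with no defaults;
their absence raises an explicit configuration error rather than a silent
assumption.

### Association and multiple testing

All models are maximum-likelihood logistic regressions (statsmodels Newton
optimizer) of case status on the target plus covariates — age, sex, DNA
source (whole-genome amplified or not), and the first two genotype principal
components by default (the PC count is configurable; two is the default
everywhere).  p-values are Wald tests, matching how log OR ± SE are reported
in GWAS practice.  Designs are checked for rank before fitting (the
offending column is named via QR pivoting); perfect separation, or any
|coefficient| > 30, raises a separation error.  Convergence: ≤ 50 Newton
iterations at tolerance 1e-10.

FDR is controlled with the Benjamini–Hochberg step-up at 1%, separately
within the score family and the variant family; subgroup analyses (age < 75
vs ≥ 75; men vs women; cases restricted to GA or to NV + mixed against all
controls; population-based samples only) are descriptive and receive no
additional family-level correction, since no subgroup-level discovery claims
are made.  Strata with fewer than 50 cases or controls are flagged
underpowered but still reported.  The conditional screen appends the known
variants' dosage columns to the covariates and recomputes q-values on the
conditioned p-values; a candidate that *is* a known variant is skipped.

### Loci and consequences

LD is the squared Pearson correlation of dosages, computed on controls only
— case ascertainment distorts LD at disease loci.  A locus around a lead is
the span of all variants within ±1 Mbp having r² > 0.5 to the lead, extended
by 100 kbp on each side (floored at position 1).  Candidates inside any
known-locus interval (inclusive 1-based bounds) are "known"; novel intervals
that overlap or touch merge into distinct loci (a zero-base gap is not
physical separation).  Coordinates are 1-based inclusive throughout; BED
I/O converts to 0-based half-open at the file boundary only.  Protein
consequences `p.<ref><pos><alt>` classify as synonymous exactly when the
reference and alternate one-letter residues agree.

## The simulator: what it emulates and what it does not

Genotypes: haplotypes from a latent-Gaussian copula — within an LD block the
latent variables share a common factor with loading √ρ, thresholded at
Φ⁻¹(eaf); dosage is the sum of two independent haplotypes.  This reproduces
the only LD feature the analysis consumes, pairwise r², with direct control;
it makes no attempt at realistic human LD decay, demography, allele-frequency
spectra, or imputation error.  Blocks are restarted at every variant-set
boundary (each trait's set, the disease-private set), so cross-set
dependence arises only from the pleiotropy specification — with sharing
switched off, every score is genuinely null.

Phenotypes: liability `L = Σ_j β_j (g_j − 2p_j) + covariate terms + ε`, with
ε scaled so the population Var(L) = 1 and case iff `L > Φ⁻¹(1 − K)`.  This
is the same generative family the liability variance computation assumes, so
the generator doubles as a ground-truth oracle.  Case subtypes are a fixed
multinomial (GA 0.35 / NV 0.45 / mixed 0.20); covariates are age ~
N(76, 7²) clipped to [55, 98], 57.8% female, 30% whole-genome-amplified DNA,
two standard-normal PCs, and a 19% population-based flag — magnitudes chosen
to resemble a large elderly ophthalmic case-control collection.  Simulated
catalogs mark every variant as an independent signal (each carries its own
generative effect), so co-located variants within a block legitimately
bypass lead pruning.

Passing tests on this generator show the estimators are correct *under the
liability model with clean block LD*; they cannot show robustness to
population stratification beyond two PCs, cryptic relatedness, imputation
error correlated with case status, or real LD structure.

## Calibration studies (tests and acceptance script)

* **Liability forward consistency** — for (eaf, OR, K) on the grid
  {0.1, 0.3, 0.5} × {1.1, 1.5, 2.5} × {0.01, 0.1}, disease is forward
  simulated from the solved penetrances and the realized prevalence and
  per-allele OR are compared with the inputs (2% relative band).  Draws are
  grouped — multinomial genotype counts, binomial case counts —
  distributionally identical to individual-level simulation; 2×10⁷ draws per
  cell keep the Monte-Carlo error of the rare-disease cells (K = 0.01) well
  inside the band, which it would not be at 10⁶.
* **Score recovery** — one pleiotropic trait (20 variants, half carrying a
  0.08 per-allele liability effect; prevalence 0.05, a realistic late-stage
  figure for an elderly cohort), 5,000/5,000 case-control draws, 100 seeds.
  The reference value is exact, not simulated: with equal weights the score
  is an allele count whose joint distribution with disease status follows by
  convolving per-variant genotype distributions through the liability model,
  and the infinite-sample balanced case-control logistic slope is obtained
  by Newton iteration on that discrete joint.  Coverage counts estimates
  within 3 SE of this truth.  Covariate liability effects are zero in these
  studies (the fitted models still adjust for them), isolating the genetic
  recovery question.
* **Null calibration** — 10 traits, no sharing, disease driven only by
  private variants; 2,000/2,000 per replicate, 200 replicates; the mean
  fraction of traits reaching q < 0.01 stays at or below 1%.
* **Conditional screen** — a candidate whose haplotype copies a causal known
  variant's allele with probability √0.9 (hence dosage r² ≈ 0.9) and has no
  direct effect; at n = 10⁴ it must be raw-significant (p < 0.01) and
  conditionally null (p > 0.05).  The conditioned p-value is uniform by
  construction, so ~95% of seeds satisfy the second condition, leaving the
  ≥ 90% success bound over 100 seeds comfortable margin.

Problem sizes above (population head-room factor 1.6 over the expected case
count, grouped draws, enumeration truths) were chosen so each study is
statistically sharp at desk scale.

## Numerical choices and degenerate inputs

* Penetrance solve: Brent on K₀ ∈ (1e-14, 1−1e-14), xtol 1e-14; failure or a
  homozygote risk reaching 1 raises a numerical/domain error echoing inputs.
* Lead-selection ties on p break by chromosome (natural order), then
  position, then variant id — determinism across runs.
* Strand-ambiguous (A/T, C/G) variants are accepted but flagged; no
  frequency-based strand flipping is attempted (silent misorientation is
  worse than a flag).  Structural-variant alleles are opaque tokens and pass
  orientation untouched when the risk allele is labelled.
* Effect sizes published as OR/HR are log-transformed at ingestion
  (`exp_scale` column); the catalog stores the log scale uniformly.
* Zero published effects are kept with weight 0 (and a warning); a trait
  whose surviving weights are all zero has no defined score and is skipped.
* Monomorphic dosage columns make LD and logistic fits undefined: LD raises
  a domain error; screens capture the per-variant error and continue.
* p-values that underflow to 0 (near-perfect score correlations) are clipped
  to 1e-300 before BH, whose domain is (0, 1].

## Known limitations

* No mixed models or relatedness correction (cohorts are assumed unrelated),
  no survival modelling, no heritability estimation beyond the per-variant
  additive liability model, and no pathway enrichment or variant-effect
  prediction — consequence strings are classified, not generated.
* The published mean variance explained across the 60 real trait catalogs
  can only be recomputed from the journal's supplementary per-trait tables
  (variant effect sizes/frequencies plus per-trait prevalences and sample
  sizes); those are not redistributable with the package, so that check
  remains unsatisfied until the converted tables are supplied under
  `data/supplement/`.
* Proxy substitution keeps the original variant's position (the proxy's
  coordinates are not in the catalog row); locus definition around a
  substituted proxy can therefore be off by the proxy distance, bounded in
  practice by the r² > 0.95 requirement.
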