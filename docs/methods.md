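# Methods

## The causal model

Let X be a blood biomarker (total homocysteine, folate, or cobalamin, in
SD units) and Y log-transformed eGFR. Each instrument SNP j has a true
per-allele effect γj on X and, through X, an effect θ·γj on Y; an invalid
instrument additionally has a direct (pleiotropic) effect αj on Y:

    βYj = θ·γj + αj,        βXj = γj.

Two-sample MR observes β̂Xj ~ N(γj, σXj²) from an exposure GWAS and
β̂Yj ~ N(θγj + αj, σYj²) from an independent outcome GWAS, and estimates
θ. The three instrumental-variable assumptions are: relevance (γj ≠ 0,
enforced by genome-wide significance p < 5e-8), independence from
confounders, and exclusion restriction (αj = 0). The estimator battery
spans progressively weaker versions of the last two: IVW assumes all αj =
0; MR-Egger allows a common directional α under InSIDE (instrument
strength independent of direct effects); the penalized weighted median
allows up to half the weight to be invalid; the contamination mixture
allows an arbitrary invalid subset provided valid variants form the
dominant likelihood group.

## Estimators

**Wald ratio.** θ̂j = β̂Yj/β̂Xj with first-order SE σYj/|β̂Xj|. The
second-order SE (adding β̂Yj²σXj²/β̂Xj⁴) is available behind a flag; with
the packaged instruments (minimum |z| ≈ 5.7) the difference is negligible,
and the first-order form is the two-sample convention.

**Fixed-effects IVW.** Precision-weighted ratio average, equivalently
zero-intercept WLS of β̂Y on β̂X with weights σY⁻². Its analytic SE
(Σ β̂Xj²σYj⁻²)^(-1/2) treats exposure effects as fixed, again the standard
two-sample convention.

**MR-Egger.** WLS with free intercept after re-expressing every variant
on its exposure-increasing allele (Egger is not invariant to allele
coding; a fixed orientation convention is required and this is the
field's). SEs come from a parametric bootstrap: each replicate redraws
β̂Xj and β̂Yj from normal distributions centered on the observed values
with the reported SEs, re-orients, and refits; the SE is the SD of
replicate estimates and p-values are two-sided normal. Bootstrap
replicates default to n_boot = 1000, which puts the Monte-Carlo error of
the SE near 2%.

**Penalized weighted median.** Order the ratios θ̂j ascending with
normalized weights wj = se(θ̂j)⁻²/Σw; the estimate interpolates θ̂ at
cumulative weight 1/2 using sj = (Σi≤j wi − wj/2)/Σw. Penalization
computes Qj = wj(θ̂j − θ̂WM)² against the unpenalized estimate and
multiplies each weight by min(1, 20·qj), qj the upper χ²₁ tail of Qj —
the originating method's convention; the factor 20 is configurable. SE by
the same parametric bootstrap (penalization applied within each
replicate).

**Contamination mixture.** Profile log-likelihood over a grid of
candidate θ: each variant contributes the larger of a valid term
(θ̂j ~ N(θ, se²)) and an invalid term (θ̂j ~ N(0, se² + ψ²)). The default
dispersion ψ = 1.5 × SD of the ratios follows the method's reference
convention; the default grid has 5001 points spanning the ratio range
±2 max se, widening and retrying if the maximum lands on an edge. The 95%
confidence set is every grid point within the χ²₁ 0.95 quantile of the
profile maximum and may be a union of disjoint intervals; the reported
`ci_low`/`ci_high` are its envelope and `se` is the envelope-implied
half-width/1.96. The p-value is a likelihood-ratio test of θ = 0.

**Reporting.** θ is on the natural-log eGFR scale; tables report
100·(exp(θ) − 1) percent change. The exact transform is used rather than
the ×100 small-effect approximation (they differ by < 0.005 points at
these effect sizes). The two-sided p < 0.05 convention is attached to
outputs as a flag, never used to filter rows.

## Harmonization and Steiger filtering

Outcome records are aligned to the exposure's effect allele: label match →
kept; swapped labels → effect negated and frequency reflected; complement
match (strand flip) is accepted only when the exposure reports both
alleles. The packaged instrument tables print only the effect allele, so
they harmonize in effect-allele-only mode: an effect allele matching
neither outcome allele is dropped as non-overlapping, because strand
cannot be disambiguated from one allele. Palindromic variants (A/T, C/G)
default to frequency inference: drop when either study's frequency is
within 0.08 of 0.5, flip when aligned frequencies straddle 0.5 — the
common two-sample practice; a hard `drop` policy is available, and which
was used is logged per SNP. Duplicate outcome rows for an rsid raise
rather than silently picking one (meta-analysis dumps contain multi-allelic
duplicates).

Steiger filtering drops variants with r²(outcome) > r²(exposure). The
default r² is t-based, r² = t²/(t² + n − 2) with t recovered from the
p-value in log space, because it needs only printed quantities; the
allele-frequency form 2·eaf(1−eaf)β² is available for SE-free per-SD
inputs. Ties are kept; the audit log records both r² per SNP.

All p-value ↔ quantile conversions go through `scipy.special.ndtri_exp` /
`log_ndtr` on the log scale: genome-wide instruments reach p ≈ 1e-104 and
a naive inverse CDF underflows near 1e-15.

## Allele-score arm

The score is sᵢ = Σj dosageᵢj·βj with dosages flip-corrected to the
instrument's effect allele, standardized to unit SD so coefficients read
"eGFR per 1 SD of score" (the replication convention); results are
invariant to positive rescaling of the weights. eGFR uses the CKD-EPI 2009
creatinine equation with the race coefficient omitted (2021 convention; a
flag restores it for strict replication of older studies). Regression is
OLS on complete cases per model — main: age, sex, genotyping batch, PC1–10;
clinical: + hypertension, diabetes, obesity — with the N actually used
reported per model. A printed table footnote in the source analysis calls
the model "logistic"; with a continuous eGFR outcome that is read as a
typo and linear regression is implemented. Score coefficients are reported
on the raw mL/min/1.73 m² scale.

## Synthetic data

The summary generator draws eafs uniformly (default 0.1–0.9), true γj
either from the packaged homocysteine set — in which case the printed
(β, eaf) pairs are used whole, since instrument strength is the pair — or
half-normal, and SEs from the per-allele variance approximation
σ² ≈ 1/(2·eaf(1−eaf)·n) at n_exp = 44,147 and n_out = 567,460. The default
θ = −0.0095 log-eGFR/SD makes the IVW %-change ≈ −0.95, so recovery tests
run at the magnitudes the real analysis operates at. Pleiotropic effects
are expressed per exposure-increasing allele (the orientation in which
"directional" is defined) and assigned to a random invalid subset — a
deterministic subset would correlate pleiotropy with instrument strength
and silently violate InSIDE. `inside_violation` adds correlation between
|γ| and α for InSIDE-violation studies. Optional allele scrambling
re-expresses outcome records on the opposite allele; one root seed is
split into per-component streams, so toggling scrambling (or any later
component) never changes the effect sizes drawn.

The cohort generator emulates a 40–69-year population cohort: genotypes
Binomial(2, eaf), exposure = standardized-genotype score + shared
confounder U + noise (unit total variance), log eGFR centered at
log(92.5) with residual SD 0.16, a −0.004/yr age slope, and creatinine
back-derived through CKD-EPI so the recorded creatinine, age, and sex
reproduce the simulated eGFR exactly. Covariates: 54% female, 5 genotyping
batches, 10 standard-normal PCs, comorbidity prevalences 25/5/24%
(independent of genotype), 5% missing phenotype and 1% missing comorbidity
flags, both MCAR.

What the generators deliberately do not emulate: LD between instruments
(the packaged sets are pre-pruned at r² < 0.1), population stratification
beyond noise PCs, non-normal effect distributions, sample overlap between
the two GWAS, and the outcome GWAS's actual phenotype variance — outcome
SEs use the unit-variance approximation, which is conservative relative to
the real log-eGFR scale (SD ≈ 0.15). Passing tests therefore demonstrate
correctness of the estimators under the assumed sampling model, not
robustness to those real-data features.

## Simulation sizes and numerical choices

Recovery checks use 500 replicates of 16-SNP datasets (bias and coverage),
robustness checks 200 replicates, and cohort coverage 200 replicates at
n = 20,000, sizes at which Monte-Carlo error is well below the quantities
being checked while the whole suite stays interactive. Bootstrap counts
inside repeated-simulation loops are reduced (200–250) since the
Monte-Carlo error they add is symmetric and small relative to the coverage
bands tested.

The pleiotropy-robustness scenario uses mean α = 0.02, SD 0.005 on 30% of
instruments: chosen so the invalid group's ratio shift is ≈ 8–10× the
per-ratio SE, i.e. a statistically separable cluster — the regime the
contamination mixture's grouping model addresses. The mixture's recovery
there is scored on a coarse 101-point grid whose 2-step tolerance matches
the estimator's own 95% half-width; on the 5001-point reporting grid a
2-step band would be far below sampling noise and would measure the noise,
not the method.

## Known limitations

* The parametric bootstrap SE for median-type estimators is intrinsically
  conservative when true effects are homogeneous: replicates are redrawn
  around observed, already noise-dispersed ratios, inflating the replicate
  SD by up to √2 (measured ≈ 1.2 here), so penalized-weighted-median CIs
  over-cover slightly (≈ 98%) in the no-pleiotropy regime. This mirrors
  the reference implementations' behavior; it is conservative, never
  anti-conservative.
* Reconstructed instrument SEs inherit the rounding of the printed betas
  and p-values.
* The contamination-mixture point estimate is grid-discretized; its
  resolution is the grid step, and no continuous refinement is attempted.
* No proxy-SNP lookup for non-overlapping variants, no LD-aware modelling,
  no random-effects IVW or heterogeneity statistics, no multivariable MR —
  all outside this analysis's design.
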