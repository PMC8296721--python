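# Methods

This note records the statistical model, the conventions and defaults the
package commits to, what the synthetic-data generator does and does not
emulate, and the study conditions behind the validation suite. Nothing here
states an empirical result that the tests or `scripts/acceptance.py` do not
themselves compute.

## Two-sample MR model

Instruments are SNPs with summary associations (β̂_Xj, σ_Xj) on the exposure
and (β̂_Yj, σ_Yj) on the outcome, estimated in non-overlapping samples so
the two noise terms are independent. Under relevance, independence and
exclusion, each ratio β̂_Yj/β̂_Xj estimates the causal effect θ; the
estimators differ in how they pool ratios and in which invalidity patterns
they tolerate.

* **IVW**: weighted regression of β̂_Y on β̂_X through the origin, weights
  σ_Y⁻². Default inference is *multiplicative random effects*: the
  fixed-effect SE is scaled by max(1, √(Q/(J−1))). Rationale: real
  instrument sets routinely show strong heterogeneity (large Q) while IVW
  remains the headline estimator; the multiplicative model tolerates
  overdispersion without down-weighting any SNP. The scale factor is
  floored at 1 so the random-effects SE can never be smaller than the
  fixed-effect SE. A fixed-effect flag exists. p-values use the normal
  distribution.
* **MR-Egger**: each SNP is oriented so β̂_Xj ≥ 0 (both members of the pair
  negated together — the estimate is invariant to the original coding),
  then weighted least squares with a free intercept. The intercept
  estimates mean directional pleiotropy in the oriented frame; the slope is
  a consistent causal estimate under InSIDE. SEs carry the same
  max(1, √(Q/(J−2))) inflation; p-values use the t distribution on J−2 df,
  the convention for small-J intercept inference.
* **Weighted median**: ratios sorted with normalised weights
  w_j = β̂_Xj²/σ_Yj² (the first-order inverse ratio variance); the estimate
  interpolates the ratio at cumulative-midpoint probability 0.5
  (p_j = Σ_{k≤j} w_k − w_j/2). Equal weights and odd J reduce to the sample
  median. SE from a seeded parametric bootstrap (default 1000 replicates,
  resampling β̂_X and β̂_Y from normals centred at the observed values).
* **Weighted mode**: argmax of a weighted normal-kernel density over the
  ratios, bandwidth h = factor × 0.9 × min(sd, IQR/1.34) × J^(−1/5) with
  weighted sd/IQR analogues (Silverman-type rule; factor defaults to 1 —
  no canonical choice exists, so it is exposed). The argmax is found by
  evaluating the density at every ratio and refining within one bandwidth
  of the best point; a fixed evaluation grid would lose the density spike
  whenever stray extreme ratios stretch the range. If all ratios coincide
  (zero bandwidth) that common ratio is returned. SE by the same bootstrap.
* **Cochran Q**: Q = Σ v_j (r_j − θ̂)² with first-order weights
  v_j = (β̂_Xj/σ_Yj)², df = J−1; for Egger, residuals about the fitted line
  and df = J−2. Note the first-order weights ignore exposure-side sampling
  error: with θ ≠ 0 and comparable sample sizes Q is mildly overdispersed
  (inflation factor ≈ 1 + θ²σ_X²/σ_Y²) even under perfect homogeneity. The
  calibration study therefore uses an exposure GWAS an order of magnitude
  larger than the outcome GWAS (the no-measurement-error regime in which
  the χ² reference is exact).
* **Radial scan**: per-SNP contributions Q_j = v_j (r_j − θ̂_IVW)², which
  sum to the IVW Q exactly. The default rule flags SNPs contributing more
  than 5% of total Q — the fraction wording matches how the analysis this
  package operationalises describes outlier removal — with a χ²(1)
  upper-α rule available, since common radial-MR practice uses the latter.
  One simultaneous pass, no iteration; if several SNPs each exceed the
  threshold they are all removed together, and removing every SNP is an
  error rather than an empty re-estimate.

### Wald ratio

Single-SNP base case: β̂_Y/β̂_X with first-order (delta-method) SE
σ_Y/|β̂_X|. β̂_X = 0 is an error rather than an infinity.

## Harmonization

Outcome records are aligned to the exposure's effect allele: identical
pairs copy; swapped pairs negate the outcome beta and complement its EAF;
strand-complement pairs are complemented first. Palindromic SNPs (A/T,
C/G) map onto themselves under complementation, so alleles alone cannot
resolve the strand: if either side's EAF is within the intermediate window
of 0.5 the SNP is dropped, otherwise the allele frequencies orient it
(matching minor/major sides ⇒ same allele). The window defaults to
|EAF − 0.5| ≤ 0.08, i.e. 0.42–0.58 — the usual range in MR harmonization
practice; both the window and the infer-vs-drop behaviour are
configuration, since neither is a settled convention. Duplicate SNP ids are
resolved before pairing by keeping the smallest-p record (deterministic,
favours the strongest signal). Every shared SNP ends in the harmonized set
or in the dropped log with a reason; positions are 1-based and are used
only by clumping windows, never by estimation.

## Instrument QC

* **Clumping** is greedy on ascending p (ties broken lexicographically on
  SNP id, making output invariant to input row order): a SNP is retained
  iff no already-retained SNP on the same chromosome lies within the window
  (default 10,000 kb) and none (any chromosome) exceeds the r² threshold
  (default 0.001). SNPs absent from the LD matrix are treated as
  uncorrelated with a warning, mirroring clumping against an incomplete
  reference panel. The LD matrix is an input (square or long format); the
  package never computes LD from genotypes.
* **F statistics**: per-SNP F = β²/SE². The combined value for an
  instrument list is the arithmetic mean (reported with min and median) —
  a single "combined" number needs an aggregation rule and the mean is the
  natural default; per-SNP F < 10 triggers a warning, not exclusion, since
  F is reported for assessment rather than screening.
* **Steiger filtering** uses the t-statistic transform
  r² = t²/(t² + n − 2) for the variance explained on each side and drops a
  SNP when r²(outcome) > r²(exposure). The default is the raw comparison;
  a Fisher-z directionality test (drop only when the reversal is
  significant at α) is available. For binary outcomes the transform is
  applied on the log-odds scale and flagged approximate. In the pipeline
  Steiger runs after clumping and after harmonization — it needs the paired
  outcome associations — and before estimation.

## MVMR

The design is the union of SNPs passing the significance threshold for any
exposure, jointly clumped with rank = best p across exposures; every
retained SNP's association with each exposure and the outcome is pulled
from a full lookup and harmonized pairwise to the primary exposure's
allele. Estimation is weighted least squares of β̂_Y on the K exposure
columns (weights σ_Y⁻², no intercept), SEs inflated by
max(1, √(Q_mv/(J−K))), t inference on J−K df. SNP counts are attributed to
the discovery list with the smaller p (ties to the primary trait).
Per-exposure instrument strength is summarised as the plain mean marginal
F and labelled as such — it is not a conditional F statistic, which is out
of scope. Collinear exposure columns raise an error naming the offending
pair. One covariate at a time matches the conditioning design this mirrors
(height, BMI, educational attainment each conditioned separately).

## Synthetic-data generator

Summary statistics are simulated directly on the summary scale: for a
variance-standardised trait the sampling SD of a per-allele estimate is
σ = 1/√(2 n p (1−p)) at allele frequency p and sample size n. This skips
individual-level genotypes entirely — adequate for every consumer here and
orders of magnitude faster; the approximation is exact in the large-n
limit. Exposure and outcome noise are independent draws (two
non-overlapping samples). Defaults: J = 100 SNPs, n = 100,000 per sample,
θ = 0.2, MAF ~ Uniform(0.05, 0.5), σ_b = 0.05 (per-SD effect scale giving
mean per-SNP F ≈ 90 at n = 100k, consistent with combined-F values in the
50–150 range typical of well-powered lung-function instrument lists).

Directional pleiotropy is defined in the *exposure-increasing allele
orientation*: α_j ~ N(μ_α, τ_α²) drawn independently of b_j (InSIDE holds)
and entering the coded frame as sign(b_j)·α_j. This is the frame in which
an Egger intercept measures directional pleiotropy; with unoriented coding
a nonzero μ_α would cancel out of both IVW and the Egger intercept and the
concept would be vacuous. Reverse-causal SNPs have b_j = 0 and a direct
outcome effect d_j ~ N(0, reverse_sd²); they emulate outcome-driven hits
contaminating an instrument list. A configurable fraction of SNPs receives
palindromic allele pairs. Positions are spread >10 Mb apart across 22
chromosomes so the default clumping window never clumps independently
simulated SNPs.

The mediation variant adds SNP→covariate effects g_j with
b_j = γ·g_j + own component and outcome effects θ_direct·b_j + δ·g_j; the
truth records θ_direct and the implied confounded univariable slope
θ_direct + δγσ_g²/var(b). The LD variant draws block-correlated effect
estimates (shared-component construction with pairwise correlation √r²;
tag SNP carries the causal effect, others attenuated by √r²) and emits the
matching block-diagonal r² matrix.

**What the generator does not emulate**: realistic LD from haplotypes,
sample overlap, selection/winner's curse (instruments are not re-selected
on significance unless a study does so explicitly), survivor bias,
population stratification, and binary traits beyond a log-odds-scale
normal approximation with an effective n. Passing tests therefore validate
the estimators and QC logic under the stated generative model, not the
behaviour of real GWAS data with those complications.

## Validation-study conditions

All Monte-Carlo comparisons use a fixed convention: a replicate mean is
"within Monte-Carlo error" of its target when it lies within 4 estimated
standard errors. Study sizes were chosen so each property's systematic
terms are resolvable below that band, and are small enough that the whole
suite runs in well under a minute on one CPU:

* *Oracle equivalence*: 10⁴ random 3–10-SNP instances against explicit
  weighted normal-equation solves.
* *IVW recovery*: θ = 0.2, J = 100, n = 100k both samples, 500 replicates;
  mean within 0.01 of θ and CI coverage in [0.92, 0.97]. (At this
  instrument strength the regression-dilution bias is ≈ θσ_X²/σ_b² ≈ 0.002,
  well inside the band.)
* *Null calibration*: θ = 0, 1000 replicates, nominal 0.05. The
  random-effects floor max(1, ·) makes the test slightly conservative
  (rate ≈ 0.04), inside the binomial band.
* *Egger pleiotropy recovery*: μ_α = 0.02, τ_α = 0.01, J = 200, 500
  replicates, sample size and effect scale set deep in the asymptotic
  regime (mean F ~ 10⁷). Egger carries O(σ_X/σ_b) finite-sample biases —
  regression dilution and sign misorientation of weak SNPs — so the
  consistency check must push those below the Monte-Carlo resolution;
  the intercept's sampling scale is invariant to the effect scale, so this
  isolates exactly the bias terms.
* *Robustness ordering*: 40% invalid instruments, μ_α = 0.01, τ_α = 0.005,
  n = 500k, 500 replicates; the weighted median must beat fixed-effect IVW
  in absolute bias in ≥95% of replicates. The outcome sample size is large
  so the median's own quantile bias (∝ σ_Y) is small against IVW's
  pleiotropy bias (independent of n).
* *Steiger*: n = 1M ("large n": detection probability of a reverse SNP is
  ≈ 1 − E[2Φ(|t_X|/s) − 1] with s = reverse effect in outcome-SE units,
  so it improves with outcome precision), 10 reverse SNPs among 60, 200
  replicates. Reverse removal is assessed on the reverse SNPs directly —
  they carry no exposure effect, so the filter is their only defence —
  while false removal is assessed on valid SNPs at genome-wide
  significance, the set that actually enters an instrument list.
* *Clumping*: 300 random ≤20-SNP instances against an independent
  dictionary-style rule evaluation, plus the {3,4,5}-block LD fixture
  (exactly 3 index SNPs).
* *MVMR attenuation*: zero direct effect, γ = 0.4, δ = 0.3, σ_g = 0.05,
  σ_b = 0.035, J = 300, exposure/covariate GWAS n = 353,315 and outcome
  n = 132,452 (the sample sizes of the design this mirrors: an unadjusted
  UK-Biobank exposure GWAS against a CHARGE/COGENT-scale outcome GWAS),
  500 replicates. The implied univariable slope is
  δγσ_g²/var(b) ≈ 0.18 — materially non-zero — while the MVMR direct
  effect must sit at zero within Monte-Carlo error and attenuate the
  univariable estimate in ≥95% of replicates.
* *Q calibration*: 50 SNPs, 1000 replicates, exposure n = 1M vs outcome
  n = 100k (see the Q discussion above), no palindromic alleles so exactly
  50 instruments survive; mean Q within Monte-Carlo error of 49.

## Numerical choices and degenerate inputs

* Bootstrap replicates default to 1000 with a mandatory seed; all
  randomness flows through `numpy.random.default_rng`.
* Weighted-median interpolation clamps outside [p_1, p_J] to the extreme
  ratio (the dominant-weight limit behaves correctly).
* Zero β̂_X makes ratios undefined: Wald/median/mode raise a named error;
  Egger orientation maps sign 0 to +1.
* Ties in clumping rank are broken on SNP id; equality at the palindrome
  window boundary drops (≤).
* All-zero exposure effects, constant oriented Egger design, rank-deficient
  MVMR designs, empty instrument sets after QC, and a radial scan flagging
  every SNP are all explicit errors, never silent degenerate fits.

## Known limitations

Correlated-instrument (generalized) IVW, MR-PRESSO/contamination-mixture
estimators, conditional F statistics, proxy-SNP lookup and genotype-based
LD are out of scope. The binary-trait path reuses the quantitative-trait
noise model on the log-odds scale and is approximate. First-order radial
weights only. The Egger estimator — like any implementation that orients on
observed signs — has finite-sample bias at weak instrument strength; this
package documents it rather than hiding it, and the validation isolates the
asymptotic property.
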