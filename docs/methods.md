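# Methods

## The sinusoid model and the SFI

An ordered correlation profile is the vector of Pearson correlations
y_k between an external variable and the K = 10 value types, arranged
by circular position x = 1..10 in the order conformity, tradition,
benevolence, universalism, self-direction, stimulation, hedonism,
achievement, power, security. The fitted model is

    y = a + b·sin(c·x + d)

with box constraints chosen to reflect what the parameters mean for
correlation data:

| parameter | meaning | bounds | default rationale |
|---|---|---|---|
| a | vertical offset (correlation units) | [−1, 1] | correlations cannot exceed ±1 |
| b | amplitude (correlation units) | [−1, 1] | same |
| c | angular frequency (radians/position) | [0.85, 0.95]·2π/K | the K circle positions span 85–95% of one period; spacing on the value circle is not assumed exactly equal |
| d | phase (radians) | [−π − c_hi, π − c_lo] | wide enough that the phase at x = 1, namely c + d, reaches every point of the circle: effectively unrestricted |

The frequency band has a second defensible reading — the *period*
measures 0.85–0.95·K position units, i.e. c ∈ [2π/(0.95K), 2π/(0.85K)]
— exposed as `c_convention="period-units"`. The default ("circle") is
used everywhere, including calibration; the two bands barely overlap,
so the choice is part of the statistic's definition and the null
calibration always uses the same convention as the observed fit.

Fit quality is the Sinusoidal Fit Index,

    SFI = [Σ(y_k − ŷ_k)²/(K−1)] / [Σ(y_k − ȳ)²/(K−1)] = SSR / TSS,

the residual variance of the fit over the variance of the profile.
Since b = 0, a = ȳ is always feasible for correlation data, SSR ≤ TSS
and SFI ∈ [0, 1]; SFI = 1 − R² of the fitted curve. SFI is undefined
(an error) for a zero-variance profile; numerically, total sums of
squares below 1e−20 are treated as zero (correlations are O(1)).

## Optimization

Two fitters share the same objective and constraints:

* `fit_sine` — bounded quasi-Newton (L-BFGS-B) with analytic
  gradients, multi-started from a deterministic grid: phases d covering
  one period crossed with amplitude signs b = ±0.5, frequency at the
  band midpoint, offset at the profile mean (16 starts by default; the
  SSR surface is multimodal in d). Convergence at ftol 1e−14; results
  are deterministic, and a seed matters only if extra random starts are
  requested. Parameters are canonicalized to b ≥ 0 via the sine
  identity (b, d) → (−b, d + π), with d wrapped into its box.
* `fit_profiles` — the batch fitter used for calibration. For fixed c
  the model is linear in (a, b·cos d, b·sin d), so the SSR is minimised
  exactly in closed form on a 65-point grid over the narrow c band,
  refined by parabolic interpolation and an exact re-solve at the
  refined frequency. Rates are insensitive to the grid (33 vs 257
  points changes nothing at 20 000 profiles). The rare profile whose
  unconstrained optimum leaves the a/b box — impossible for profiles
  well inside [−1, 1] — is re-fitted with the bounded `fit_sine`.

The two agree to |ΔSFI| < 1e−5 on random profiles (asserted in the
tests, along with agreement of both against an independent dense
grid-search oracle to 1e−6 in SSR).

Dropping one value type (`refit_excluding`, the benevolence sensitivity
analysis) re-indexes the remaining points contiguously to 1..K−1 and
rescales the c band to the new K. A consequence worth knowing: because
re-indexing shifts the points after the gap and the K = 10 and K = 9
frequency bands barely overlap, removing a point that lies exactly on
the fitted curve is *not* guaranteed to keep the SFI from rising unless
the dropped point is the last one (or the frequency sits in the bands'
overlap).

## Monte-Carlo calibration

Null profiles are K i.i.d. draws per profile, either uniform(lo, hi)
(default (−0.5, 0.5), the band where value-external correlations
typically fall) or normal(mean, sd) with draws beyond |1| clamped to ±1
(defaults sd 0.1 and 0.3, mean 0). The false-positive rate at a
threshold t is #{SFI < t}/n with *strict* inequality, reported with the
binomial Monte-Carlo standard error; the empirical p-value of an
observed SFI is the same left-tail count at the observed value (smaller
SFI = better fit). Raw SFI samples are retained by default (10⁵ floats
is trivial storage) so new thresholds and exact p-values need no
re-run.

One seeded generator fills the n × K draw matrix profile-by-profile,
so a longer run extends a shorter one's prefix under the same seed, and
results are identical however the fits are batched. Default n = 100 000
per null, matching the scale at which the published false-positive
rates (sub-1% at SFI < 0.20) are stable to ~0.03 percentage points.

## Value-survey scoring conventions

* Ratings are validated as integers on −1..7 (the instrument is
  discrete); non-integer or out-of-range values are rejected.
* Ipsatization uses each participant's available (non-missing) items;
  type scores average the available assigned items. A participant with
  all items missing (or a type with none) is an error rather than a
  silent NaN; listwise deletion is deliberately avoided.
* The 2 items outside the 10 types stay in the ipsatization mean but
  feed no type score. Which 2 of the 56 they are is instrument lore;
  the default fixture uses the last two placeholder ids.
* Cronbach's alpha uses the covariance form k/(k−1)·(1 − Σs²ᵢ/s²_T) on
  raw item ratings (alpha on standardized items differs unless item
  variances are equal). Complete-case respondents only.
* The scale scorer is generic: reverse-keyed items recode as
  lo + hi − rating; the score is the mean of keyed, non-missing items.

## Polygenic scoring conventions

* Strict inequalities at both thresholds (p < P_T, r² < 0.2).
* Pruning is full-pairwise greedy in ascending p (ties broken by SNP
  id), exact and deterministic at desk scale; window-based pruning of
  large cohort tools is an approximation of this. r² is the squared
  Pearson correlation of dosages over pairwise-complete samples;
  constant SNPs have undefined r² and never veto retention. Every
  removal is logged as (removed, retained partner, r²).
* Alleles align by direct/complement label matching only; palindromic
  (A/T, C/G) pairs cannot be oriented without strand information and
  are dropped in strict mode (default).
* Missing hard calls: per-SNP mean imputation (the convention of
  standard scoring tools), switchable to complete-case with per-sample
  renormalisation.
* The divisor is the SNP count m; whether the average should instead be
  per allele (2m) is ambiguous in the field's phrasing, so it is a flag
  (`divisor="n_alleles"`), which rescales every score by ½ and changes
  no correlation.
* Inputs are assumed post-QC; imputation, LD reference panels, dosage
  data and X-chromosome handling are out of scope.

## Synthetic data: what it emulates, what it does not

`gen_value_responses` draws two standard-normal participant factors and
gives every item of a value type the loading (cos θ, sin θ) of that
type's angle (equally spaced on the circle by default), plus item
noise; the continuous score is scaled (spread 1.8 about the midpoint 3)
onto the −1..7 grid, rounded and clamped. Closed form: two type *means*
correlate loading²·cos Δθ / √((loading² + noise²/k_a)(loading² +
noise²/k_b)). Defaults (loading 1, noise sd 1.3, item counts 7/9/6/4/
6/5/6/2/3/6) give moderate-to-good internal consistency (alphas ~0.6–
0.8 at n = 81), matching a typical value survey. Rounding and clamping
attenuate correlations by a few percent; oracle tolerances (±0.05)
absorb this.

`gen_external_trait` solves weights w through the observed value-score
correlation matrix R (least squares) so the trait w'Z + residual has
population correlations equal to the projection of the target sinusoid
onto the achievable space; infeasible targets (implied R² ≥ 1, or
projection residual beyond 0.05) raise with the residual reported. Note
that against *ipsatized* scores a flat non-zero profile is infeasible —
ipsatized type scores sum to ≈ 0, so their correlations with anything
must roughly balance. The residual scale affects only the trait's
units, not its correlations.

`gen_genotypes_with_trait` draws independent binomial(2, maf) hard
calls (maf uniform in (0.05, 0.5)), effect sizes ln OR ~ N(0, 0.05),
and p-values as the two-sided normal tail of ln OR/sd (so small p ⇔
large effect; with all-zero effects the p-values are uninformative
uniforms). The trait is target_rho·z(score) + √(1−target_rho²)·noise,
where the score is computed by the package's own threshold→align→
prune→average chain, making target_rho (default 0.22, the magnitude of
the reported score-trait association) the population score-trait
correlation by construction. An optional within-block Gaussian-copula
AR(1) haplotype mode exists solely to exercise LD pruning; realistic LD
maps, population structure and Hardy-Weinberg violations are not
simulated.

`gen_cohort` wires the three measures together at study scale (81
participants, 500 SNPs by default): the questionnaire trait and the
genetic score receive *separate* liability draws sharing only the
value-structured component (so their mutual correlation is an emergent
~0.3 at population scale, the order of the reported trait-score
association, rather than a dialled constant), and genotype samples are
rank-matched on the polygenic score to the genetic liability so the
score inherits the planted sinusoidal profile.

Because the generators use idealized circumplex geometry, independent
SNPs and normal latents, passing tests demonstrate the *pipeline's*
correctness and calibration — not that real survey or genotype data
satisfy the model's assumptions (equal angular spacing, linear factor
structure, post-QC genotypes).

## Problem sizes and runtime choices

Calibrations run at the full n = 100 000 per null (a few seconds with
the batch fitter). Synthetic-recovery checks use n = 5000 cohorts;
pipeline end-to-end tests use a 400-participant cohort so profile
sampling noise (SE ≈ 1/√n per correlation) stays well below the planted
amplitude, while the analysis drivers run at the study's own n = 81,
where an SFI near 0.05–0.2 is typical for a planted amplitude of 0.22.

## Known limitations

* With n = 81 participants each profile correlation carries a sampling
  SE of ~0.11, so observed SFIs fluctuate substantially around the
  planted structure; the calibration bounds false positives but says
  nothing about power, which at this n is modest.
* The 9-value re-fit convention (contiguous re-indexing with rescaled
  frequency band) is one of two defensible readings; the alternative
  (keep original positions with a gap) would generally fit better.
* Which SD produced the published truncated-normal false-positive rate
  is not documented anywhere we can check, so both SDs are always
  computed and reported; their rates are nearly identical anyway
  because SFI is scale-invariant until the ±1 clamp binds.
* Empirical p-values are resolution-limited to 1/n; a profile better
  than every null sample reports p = 0.
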