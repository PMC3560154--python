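# Methods

`rnaseqpower` simulates two-condition bulk RNA-Seq count data under a
hierarchical negative-binomial model and measures how experimental-design
choices — biological replication, sequencing depth, and multiplexing — change
the false and true positive rates of exact-test differential-expression (DE)
calls. This note records the model, the algorithms, the numerical choices,
and the limits of what the simulations can show.

## The count model

The read count of transcript *i* in lane *j* is modelled as

    K_ij ~ NB(mean = μ_i, var = μ_i (1 + φ_i μ_i)),

the gamma-Poisson mixture that arises when the transcript's molar
concentration in the prepared library varies across biological replicates
with a Gamma law and sequencing adds Poisson shot noise. φ_i ≥ 0 is the
dispersion; φ = 0 recovers Poisson. Internally we use the shape
parameterisation r = 1/φ, p = r/(r + μ). Sums of n i.i.d. replicates are
again NB with mean nμ and dispersion φ/n — this closure is what makes the
exact conditional test tractable.

## Synthetic transcriptome populations

The generator (`GeneratorConfig`) produces a per-transcript population
(μ_i, φ_i):

* **Abundance**: log10 μ ~ Normal(0.9, 0.8) truncated to μ ∈ [1, 10⁵],
  spanning roughly four decades, then rescaled once so the expected lane
  total equals `library_size` (default 10⁶ at desk scale). This is a
  modelling choice standing in for an empirical abundance distribution.
* **Dispersion**: the power-law trend φ = c μ^(α−2) with c = 0.364,
  α = 1.700 (a log–log-linear dispersion–mean relationship estimated from
  lymphoblastoid-cell-line RNA-Seq), with lognormal scatter of
  σ_φ = 0.35 decades, clamped to [10⁻⁴, 10].
* **Differential expression**: a random ⌊0.075 t⌋ of transcripts are
  up-regulated with factor θ = 1 + X and a disjoint ⌊0.075 t⌋
  down-regulated with θ = (1 + X)⁻¹, X ~ Exp(1); the rest keep θ = 1.
  Treatment counts are NB(θ_i μ_i, φ_i) with dispersion unchanged. At
  t = 46,446 this yields exactly 6,966 regulated transcripts.
* **Effectively DE**: transcripts with θ ≤ 0.83 or θ ≥ 1.20 (boundaries
  inclusive) count as true positives; the analytic fraction among induced
  transcripts is (e^(−0.2) + e^(−(1/0.83−1)))/2 ≈ 0.8168, about 5,690 of
  6,966 in expectation.

A population can instead be estimated from a real transcript-by-lane count
matrix: lane totals are equalised to the smallest lane by
without-replacement subsampling, transcripts averaging under one read per
lane are culled, and per-transcript NB maximum-likelihood estimates are
taken across lanes.

Sequencing-depth loss is simulated by thinning each lane to
round-half-even(d × total) reads with a multivariate hypergeometric draw
over transcripts — sampling reads without replacement, so thinning composes
(50% of 50% has the same law as 25%) and a thinned matrix is always a
pointwise subsample of its parent.

## The exact conditional test

For each transcript with per-condition sums (S_A, S_B), S = S_A + S_B, the
null hypothesis fixes a common per-lane mean μ̂ = S/(n_A + n_B). The pooled
sums are NB(n_A μ̂, φ/n_A) and NB(n_B μ̂, φ/n_B); conditioning on S, the
p-value is

    p = Σ { P(a) : P(a) ≤ P(S_A) } / Σ_a P(a),
    P(a) = pmf_A(a) · pmf_B(S − a),  a = 0..S,

i.e. the total conditional probability of all apportionments no more
probable than the observed one. Ties are included with a relative tolerance
of 10⁻¹² to absorb floating-point equality. S = 0 returns p = 1.

Numerics: the enumeration is exact (no tail truncation). log P(a) is built
by a cumulative sum of one-step log ratios over a flat array of all
(transcript, a) pairs, processed in ~4·10⁶-point chunks; per-transcript
additive constants cancel in the normalisation, so only the ratio
recurrence's precision matters (cumsum error grows like √S · ε and is
negligible at the depths simulated). A lane with a balanced design and
equal condition sums gets p = 1 exactly whenever the pooled shape n/φ ≥ 1
(conditional law unimodal at the centre — always the case in the designs
studied); for n = 1 and φ > 1 the conditional law is U-shaped and the
central split is the *least* probable outcome, a documented property of
probability-ordering tests on discrete supports.

## Dispersion strategies

All strategies treat φ as common across conditions and feed the same exact
test; they differ only in how φ_i is estimated.

* **tagwise-squeeze** (edgeR-like). Counts are scaled to the
  geometric-mean lane total and rounded (a simple stand-in for
  quantile-adjusted counts; simulated libraries are depth-matched, so this
  is nearly the identity). The common dispersion maximises the conditional
  log-likelihood — given the per-condition sums the mean drops out — summed
  over transcripts; per-transcript conditional-ML estimates are then
  squeezed towards it with weight w = prior_df/(prior_df + residual_df),
  residual_df = lanes − conditions, prior_df defaulting to 10. With one
  lane per condition the strategy falls back to common-only.
* **max-parametric** (DESeq-like). Per-transcript conditional-ML
  estimates (the mean-free likelihood avoids the severe downward bias of
  plain ML when group means are fitted from a handful of lanes) are fitted
  to φ(μ) = a + b/μ by a gamma-family identity-link GLM, iterated with
  outlier exclusion (points whose ratio to the current curve is outside
  (10⁻⁴, 15) are dropped and the curve refitted) because raw estimates at
  small n include values clamped near zero and huge outliers that would
  otherwise dominate the fit. The final dispersion is the maximum of the
  per-transcript estimate and the fitted curve — deliberately conservative.
* **powerlaw** (NBPSeq-like). The same per-transcript estimates are
  regressed in log–log space and every transcript is forced onto
  φ = c μ^(α−2). This is the simple regression form rather than a full
  summed-conditional-likelihood maximisation; recorded as an approximation.
* **oracle**. The simulation's true φ_i, for calibration studies.

Per-transcript maximisations run on a shared log-φ grid over
[10⁻⁸, 50] (40 coarse points, three 9-point zoom rounds, final relative
resolution under 1%), vectorised across all transcripts.

Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest`; size factors default to unit (simulated
libraries are depth-matched), with median-of-ratios and TMM available.

## Experiments and evaluation

Rates are percentages at significance level α (percent): a call is
100·p < α. Under the null the FPR over all transcripts should match α.
With induced DE, FPR counts effectively-non-DE transcripts called at
100·p_adj < α and TPR the effectively-DE ones; 100 − FPR and TPR are
specificity and sensitivity. High/low-count strata split at a mean of 100
counts over the control replicates (boundary low). Transcripts whose test
is undefined after depth loss (zero total) keep p = 1 and stay in all
denominators so rates remain comparable across depths.

The runner provides three experiment families: null calibration across n
and strategies; a replication × depth power grid in which each repetition
simulates once at full depth and thins to every depth (so depth
comparisons are paired); and multiplex scenarios n ∈ {2, 3, 4, 6, 8, 12,
32, 96} at depth exactly 1/n. Repetition summaries report the median and
the 5th–95th percentile band. All randomness derives from one root seed
through key-derived child streams (stage, repetition, n, depth), so any
cell is independently reproducible and a multiplex cell coincides
bit-for-bit with the matching power-grid cell.

Default problem sizes are desk scale: t = 20,000 transcripts and 10⁶
reads per lane (a full-transcriptome preset t = 46,446 is available), 10
repetitions for DE grids and 100 for null calibration, both configurable.
The bundled acceptance script uses 3 grid repetitions.

## Calibration tolerances

Null calibration with oracle dispersions is evaluated at n = 12, the
largest replication of the study, where the discreteness of the
conditional support is smallest; the FPR at α = 1% is required to sit
within 3 binomial standard errors of 1%. The p-value distribution check
allows no anti-conservative excess of the empirical CDF over the uniform
beyond 0.01, and a super-uniform deficit of at most 0.08 on [0, 0.9] —
the deficit is the expected signature of discrete conditional supports
among low-count transcripts, which also produce the documented point mass
at p = 1 (equal condition sums).

## What the simulations do and do not show

The generator reproduces the count model's variance structure, the
dispersion–mean trend, a wide abundance range, exchangeable depth-matched
lanes, and exponential-tailed regulation. It does **not** model lane or
flow-cell batch effects, barcode or GC/length bias, technical-replicate
variance components, correlated transcripts, or isoform structure —
conclusions about those require real data.

Two quantitative limits deserve emphasis. First, absolute TPR levels
depend strongly on the joint abundance–dispersion population; the built-in
log-normal abundance law places the median transcript near μ ≈ 10 at desk
scale, where detection power is shot-noise limited. Consequently TPR falls
faster with sequencing depth here (TPR at 15% depth is roughly half its
full-depth value even with oracle dispersions) than in studies whose
populations concentrate detection power in high-count,
dispersion-dominated transcripts, for which depth reduction to ~15% costs
little. The qualitative orderings — TPR increasing with n at every depth,
FPR conservatism of the max-parametric strategy, fold-change-criterion FPR
growing as depth falls and being damped by a pseudocount — are robust to
this choice; the depth-robustness *magnitude* is not. Second, the
strategies emulate the dispersion-estimation logic of the corresponding R
packages but are not bit-for-bit ports; version-specific internals
(exact qCML weighting schemes, sharing modes) are out of scope.
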