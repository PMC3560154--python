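# rnaseqpower

Power and error-rate simulation for two-condition RNA-Seq
differential-expression (DE) experimental designs.

Planning an RNA-Seq DE experiment means trading off biological replication
against sequencing depth against cost, increasingly under multiplex designs
that pack *n* barcoded samples into a lane at average depth 1/*n*. This
package lets methodologists and experimentalists quantify those trade-offs
on synthetic data with known truth: it simulates transcriptome-wide counts
under a hierarchical negative-binomial model, calls DE with an exact
conditional test under interchangeable dispersion-estimation strategies
(emulating the edgeR, DESeq and NBPSeq approaches), and measures false and
true positive rates across replication, depth and multiplex scenarios.

## Model and test

Counts follow K ~ NB(mean = μ, var = μ(1 + φμ)) per transcript and lane —
a gamma-Poisson hierarchy with dispersion φ capturing library-preparation
and biological variability on top of Poisson shot noise. Dispersions track
the power-law trend φ = c·μ^(α−2) (defaults c = 0.364, α = 1.700) with
lognormal scatter. DE is induced in 15% of transcripts by a regulating
factor θ = 1 + X (up) or (1 + X)⁻¹ (down), X ~ Exp(1); transcripts with
θ ≤ 0.83 or θ ≥ 1.20 are the "effectively DE" ground truth. Depth loss is
without-replacement read subsampling per lane.

For each transcript the test conditions on the total count S = S_A + S_B:
under the null the pooled per-condition sums are NB with a common per-lane
mean, and

p = Σ{P(a) : P(a) ≤ P(S_A)} / Σ_a P(a),  P(a) = pmf_A(a)·pmf_B(S−a),

with Benjamini–Hochberg adjustment across transcripts. Dispersion
strategies: `tagwise-squeeze` (per-transcript conditional-ML squeezed
towards the common dispersion), `max-parametric` (max of per-transcript
estimate and a fitted a + b/μ trend), `powerlaw` (all transcripts on a
fitted c·μ^(α−2)), and `oracle` (true simulation values). See
`docs/methods.md` for the full account.

## Worked example

```python
from rnaseqpower import (GeneratorConfig, ExactNBTest, build_parameter_population,
                         draw_regulating_factors, label_effective_de,
                         simulate_counts, subsample_depth)
from rnaseqpower.metrics import fpr, tpr

gen = GeneratorConfig(t=5000, library_size=250_000)
pop = build_parameter_population(gen, seed=1)
pop = label_effective_de(draw_regulating_factors(pop, seed=2))   # 15% DE
counts = simulate_counts(pop, n_reps=4, seed=3)                  # 4 vs 4 lanes

res = ExactNBTest(counts, strategy="deseq").fit()
print(res.summary())
labels = pop.effective_de
print(f"FPR  = {fpr(res.p_adj, labels, alpha=1.0):.3f}%")
print(f"TPR  = {tpr(res.p_adj, labels, alpha=1.0):.2f}%")

thin = subsample_depth(counts, 0.15, seed=4)                     # 15% depth
res15 = ExactNBTest(thin, strategy="deseq").fit()
print(f"TPR at 15% depth = {tpr(res15.p_adj, labels, alpha=1.0):.2f}%")
```

prints

```
Exact NB differential-expression test
================================================
transcripts tested        5000
conditions                control vs treatment (4 vs 4 lanes)
dispersion strategy       max-parametric
size factors              unit
median dispersion         0.3283
DE calls (BH p_adj < 0.01)  47  (0.94% call rate)
FPR  = 0.046%
TPR  = 7.26%
TPR at 15% depth = 2.58%
```

Of 5,000 transcripts, 47 are called DE at BH-adjusted p < 0.01. Against
the known truth the false positive rate among effectively-non-DE
transcripts is 0.046% — the DESeq-like strategy is deliberately
conservative, well under the 1% significance level — while 7.3% of the
effectively-DE transcripts are detected with only 4 replicates per
condition; thinning every lane to 15% of its reads costs sensitivity but
produces no false-positive inflation.

Grid experiments run through the runner or the CLI:

```sh
rnaseqpower power-grid --ns 2,4,8 --depths 1.0,0.5,0.15 \
    --repetitions 5 --seed 1 --outdir results/grid
rnaseqpower multiplex --ns 2,4,8,12 --repetitions 5 --seed 1 \
    --outdir results/multiplex
```

Each writes tidy per-repetition TSVs plus median / 90%-interval summaries.

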