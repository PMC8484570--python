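# driftarch

Simulation and Bayesian inference of complex-trait genetic architecture
under genetic drift.

## The problem

GWAS-era models of genetic architecture often link a SNP's effect size to
its allele frequency through a shape parameter *S*:

    β_i ~ N(0, σ_β² [f_i(1 − f_i)]^S)

*S* < 0 means rarer variants carry larger effects — the signature of
negative selection; *S* = 0 decouples effect from frequency.  But *S* is a
property of the population in which selection shaped the trait.  When a
trait evolved in one population (for humans, the pre-out-of-Africa
ancestor, proxied by present-day Africans) and is analysed in another,
genetic drift has moved the allele frequencies, and both the observed
heritability and the inferred *S* are distorted.  How much, and in which
direction, depends on the drift distance *F_st*, on how rare causal
variants were treated by nature (bounded vs unbounded effect sizes), and
on the analyst's minor-allele-frequency (MAF) threshold.

`driftarch` is for statistical geneticists who want to quantify these
biases on synthetic data and to correct them.  It provides:

- **freq panels & drift** — ancestral allele-frequency panels (uniform,
  Beta, or neutral-SFS ∝ 1/p) pushed through the Balding–Nichols drift
  kernel: f | p, F_st ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so E(f) = p and
  Var(f) = F_st·p(1−p).
- **trait simulation** — effects from the architecture model, binary
  genomes x ~ Bern(f), phenotypes y = Σβx + N(0, V_e), V_e fixed so
  h² = 0.5 in the evolving population, and observed heritability after
  drift and MAF thresholding.
- **inference** — a drift-naive baseline (*simple model*: uniform priors
  S ~ U(−2,2), σ_β ~ U(0,2) and the likelihood above at the observed
  frequencies) and a *drift model* that treats each observed frequency as
  a Balding–Nichols draw around a latent ancestral frequency p_i, tying
  effects to p_i instead.  Both are sampled by an adaptive
  Metropolis-within-Gibbs MCMC with split-Rhat convergence gating
  (runs with Rhat(S) ≥ 1.2 are discarded).
- **F_st estimation** — a Weir–Cockerham estimator from two-population
  frequency summaries (ratio of averages across SNPs) plus a
  method-of-moments estimator for simulation QC.
- **sweeps** — desk-scale experiment grids over MAF thresholds and F_st
  values with retention and credible-interval-coverage summaries.

## A worked example

```python
import driftarch as da
from driftarch.sweep import simulate_dataset

ds = simulate_dataset(L=2000, S_true=-1.0, fst=0.1, seed=11)
data = ds.inference_data()          # drops fixed SNPs, carries known F_st
for model in ("simple", "drift"):
    res = da.fit(model, data, n_chains=4, n_iter=2000, seed=42)
    lo, hi = res.ci_S()
    print(model, round(res.median_S(), 3), (round(lo, 3), round(hi, 3)),
          round(res.rhat_S, 3))
```

prints (exactly, given the seeds):

```
simple -0.362 (-0.394, -0.336) 1.001
drift -0.883 (-0.962, -0.807) 1.023
```

The trait was simulated at S = −1 and its frequencies drifted at
F_st = 0.1.  The drift-naive model is strongly attenuated toward 0
(−0.36): drift has decorrelated observed frequency from effect size.  The
drift model, integrating over latent ancestral frequencies with F_st
treated as known, recovers ≈ −0.9 for this realisation; across replicate
datasets its posterior median is centred on −1 and its 90% interval
covers the truth at roughly the nominal rate.

The `examples/` directory has one short script per capability
(simulation & observed h², inference, F_st estimation, sweeps); each
prints the numbers it computes and what they mean.  The same operations
are scriptable from a shell via the thin CLI:

```sh
driftarch fixture --L 500 --S -1 --fst 0.1 --seed 7 --out fixtures/run1/
driftarch infer --model drift --input fixtures/run1/inference_input.tsv \
    --fst 0.1 --chains 4 --iter 2000 --seed 7 --out posterior.tsv
driftarch fst --freqs two_pop.tsv
driftarch sweep --config sweep.yaml --kind fst --out results/
```

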