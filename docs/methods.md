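# Methods

## Generative model

A complex trait with `n_causal` causal SNPs is simulated in an *evolving
population* (the population in which selection shaped the architecture):

1. **Ancestral frequencies.**  p_i are drawn i.i.d. from a configurable
   distribution: `uniform(a, b)` (default uniform(0.001, 0.999)),
   `beta(a, b)`, or `neutral-sfs(p_min)` with density ∝ 1/p on
   [p_min, 1−p_min].  Inference conditions on frequencies, so this choice
   mainly controls coverage of the frequency axis; the uniform default
   spreads information evenly, while the neutral SFS emulates the
   rare-heavy spectrum of a real sequencing panel.
2. **Causal-SNP selection.**  `unbounded` mode admits every segregating
   SNP (p > 0); `bounded` mode requires p > 0.01, which caps the per-SNP
   effect variance at [0.01·0.99]^S (≈ 101 for S = −1) instead of letting
   it grow without bound as p → 0 (≈ 20001 at p = 5e-5).
3. **Effects.**  β_i ~ N(0, σ_β² [p_i(1−p_i)]^S), σ_β² = 1 by default
   (the scale is arbitrary; only the frequency dependence matters).
4. **Variance components.**  V_g = Σ β_i² p_i(1−p_i) — the additive
   variance of Σβx under Bernoulli genomes — and V_e = V_g(1−h²)/h² with
   h² = 0.5, fixed once in the evolving population and *not* rescaled
   afterwards.  (Some treatments write V_g = Σ β p(1−p) without the
   square; the Bernoulli genome model forces the squared form, and
   h² = 0.5 by construction only holds with it.)
5. **Drift.**  Observed frequencies come from one Balding–Nichols
   episode: f_i | p_i ~ Beta(p_i(1−F)/F, (1−p_i)(1−F)/F), with
   E(f_i) = p_i and Var(f_i) = F_st·p_i(1−p_i).  Fixed SNPs (p ∈ {0,1})
   pass through unchanged.  SNPs are independent — no linkage
   disequilibrium is simulated — and drift to multiple target populations
   follows a star phylogeny (independent episodes from the shared
   ancestor).
6. **Cohorts** (optional, for validation oracles): binary genomes
   x_ki ~ Bern(f_i), phenotypes y_k = Σ_i β_i x_ki + N(0, V_e).

Observed heritability in a target population is V_g(target)/(V_g(target)+V_e)
with V_g recomputed over SNPs whose minor-allele frequency min(f, 1−f)
exceeds the chosen MAF threshold.  Thresholds are interpreted on the
minor allele throughout.

## Inference models

Both models see per-SNP pairs (f_i, β_i) with effect sizes treated as
known (no GWAS estimation error, no SNP-selection/spike-and-slab
component — causal SNPs are known by construction).

**Simple model** (drift-naive baseline):

    S ~ U(−2, 2),  σ_β ~ U(0, 2),  β_i ~ N(0, σ_β² [f_i(1−f_i)]^S).

**Drift model:** each observed f_i is one Balding–Nichols draw around a
latent ancestral frequency p_i, at an F_st supplied by the caller and
treated as known (estimating it jointly per trait would be
inconsistent); effects are tied to the ancestral frequency:

    f_i ~ Beta(p_i(1−F)/F, (1−p_i)(1−F)/F),
    β_i ~ N(0, σ_β² [p_i(1−p_i)]^S),

with independent flat priors on each p_i.  Fixed SNPs (f ∈ {0,1}) have
zero likelihood and are removed in preprocessing.

**Frequency floor.**  A floor (default 1e-4) regularises any frequency
that is raised to the power S: the simple model's observed f_i are
clamped to [floor, 1−floor] (symmetrically at both tails, so allele
labelling is irrelevant), and the drift model's latent p_i are bounded to
the same interval.  The drift model's *observed* frequencies enter only
through the Beta kernel, which is well behaved at extreme f, so they are
deliberately left unclamped: clamping them measurably biases S downward
(extreme-drift SNPs are exactly the informative ones) while bounding the
latent frequencies leaves recovery unbiased.

## Sampler

An adaptive random-walk Metropolis-within-Gibbs over (S, log σ_β,
logit p_i), chosen to keep the artifact self-contained:

- Given (S, σ_β) the latent p_i are conditionally independent, so the
  whole p-block updates componentwise in one vectorised accept/reject
  step with per-coordinate step sizes.
- In the simple model, (S, log σ_β) is a near-linear posterior ridge
  (slope −mean(log f(1−f))/2); S is proposed jointly with a compensating
  shear in log σ_β (unit Jacobian, symmetric), which removes the slow
  ridge diffusion.  In the drift model S uses small local proposals
  instead: large sheared jumps can carry a chain into a known spurious
  mode at S > 0, where the latent frequencies equilibrate and trap it,
  whereas local moves guided by the current p reliably find the global
  mode.
- Step sizes adapt toward 44% acceptance in windows of 50 during warmup
  (default: warmup length = number of kept iterations).
- Chains initialise overdispersed: S ~ U(−2,2), σ_β ~ U(0.1,1.9), and
  p_i at the floored observed f_i with N(0, 0.05) logit jitter —
  initialising p at f speeds convergence without changing the stationary
  distribution.
- Convergence is gated on plain split-Rhat of S (each chain halved;
  sqrt(((n−1)/n·W + B/n)/W)); a run is `retained` iff Rhat(S) < 1.2,
  mirroring the known failure mode where a chain sticks at S > 0 and
  drives Rhat ≥ 1.5.  Other parameters are reported but not gated.
  Constant chains return Rhat = 1 with a warning.

Correctness of the sampler is checked against two independent oracles in
the test suite: a dense 2-D grid integration of the simple model's
posterior (exact up to quadrature), and term-by-term scipy log-density
sums for both log-posteriors.  During development the drift model was
additionally validated against a semi-analytic quadrature posterior that
integrates each latent p_i out numerically (the factorised structure
makes this exact at moderate L).

## Default scales

Experiments default to desk scale: L = 2000 SNPs for recovery studies,
4 chains × 1000–2000 kept iterations after an equal warmup, 3–10
replicates per cell.  These sizes make every directional claim testable
in minutes on one CPU; all of them are config-controlled, and larger
panels only tighten the posteriors (a full-size run is the same code at
L = 10⁴–10⁵).

## F_st estimation

`weir_cockerham_fst` implements the two-population Weir–Cockerham ANOVA
estimator on allele-frequency summaries (per-SNP frequencies and allele
counts), pooled across SNPs as a ratio of averages — the convention of
the standard GWAS toolchain.  SNPs monomorphic in the pooled sample are
skipped (zero denominator) with a logged count; the reported value is
clipped to [0,1] with the raw value retained.  Under the star model (two
populations each drifted at F from a shared ancestor) the estimand is F
itself: E[(f1−f2)²]/2 = F·p(1−p) and E[f(1−f)] = (1−F)·p(1−p), so the
large-n ratio converges to F — Balding–Nichols is exactly the coancestry
model the estimator targets.  `bn_moment_fst` (Σ(f−p)²/Σp(1−p)) recovers
the drift parameter of a single episode when the ancestor is known and
serves as simulation QC.  Genotype-level corrections that need observed
heterozygosity are out of reach of frequency summaries and out of scope.

## What the synthetic generator does and does not emulate

The generator reproduces the *model-internal* phenomena exactly: drift
attenuates the naive estimate of S (increasingly with F_st), the drift
model corrects it, misspecifying the supplied F_st shifts the estimate
monotonically, and MAF thresholding is harmless in the evolving
population itself.

It does **not** emulate real out-of-Africa cohort structure: linkage
disequilibrium, the bottleneck's non-martingale joint site-frequency
spectrum, or finite-sample frequency estimation.  That matters for sign
predictions.  Balding–Nichols drift is a martingale with
E[f(1−f)] = (1−F_st)·p(1−p), so under this generator genetic variance
*shrinks* in expectation and observed heritability falls below the
constructed 0.5, and the naive model's S is attenuated toward 0.  In
real resampled human cohorts the opposite directions are reported for
unthresholded analyses (observed h² above the constructed value,
|S| inflated): those effects ride on the empirical joint SFS of the
out-of-Africa bottleneck, which no Beta-kernel episode reproduces.
Passing tests here therefore demonstrate the drift-correction machinery
under its own assumptions, not those cohort-specific directions.

## Numerical choices and edge cases

- All randomness flows from one integer seed through named
  `numpy.random.SeedSequence` spawn keys (`driftarch._rng`), so each
  pipeline stage is independently reproducible and replicates are
  statistically independent.
- Proposals that leave a prior's support are rejected outright; no
  accepted draw can lie outside S ∈ (−2,2), σ_β ∈ (0,2), or
  p ∈ [floor, 1−floor].
- A sampler failure (non-finite draws) marks the run not-retained with a
  diagnostic instead of raising; sweep cells that fail become
  not-retained rows instead of aborting the grid.
- Serialisation uses a fixed `%.9g` float format, UTF-8 and Unix
  newlines, so identical inputs give byte-identical TSVs and the fixture
  generator's SHA-256 manifest is stable across platforms.
- Latent-frequency draws are stored thinned (default every 10th kept
  iteration) to bound memory at large L.

## Known limitations

- Haploid/binary genomes exactly as modelled (x ~ Bern(f)); no diploid
  0/1/2 dosages, dominance, epistasis or pleiotropy.
- One drift episode per target population; no within-population
  structure and no archaic-admixture scenario.
- F_st is an input to the drift model, never jointly inferred; the
  sensitivity of S to a misestimated F_st is documented and tested but
  not corrected.
- The drift model's known spurious mode at S > 0 is handled by retention
  (Rhat gating) rather than by tempering or mode-jumping proposals;
  at desk scale nearly all runs are retained.
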