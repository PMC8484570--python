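"""Bayesian inference of the architecture shape parameter S.

Two models are fit to observed (frequency, effect-size) pairs:

* the **simple model** (drift-naive baseline, a BayesS-style model with
  causal SNPs known):

      S ~ U(-2, 2),  σ_β ~ U(0, 2),
      β_i ~ Normal(0, σ_β² [f_i(1-f_i)]^S)

* the **drift model**, which treats the observed target-population
  frequency f_i as a Balding–Nichols draw around a latent ancestral
  frequency p_i at known fixation index F_st, and ties the effect size to
  the *ancestral* frequency:

      f_i ~ Beta(p_i(1-F_st)/F_st, (1-p_i)(1-F_st)/F_st),
      β_i ~ Normal(0, σ_β² [p_i(1-p_i)]^S),

  with independent Uniform(0, 1) priors on each latent p_i.

The sampler is an adaptive random-walk Metropolis-within-Gibbs over
(S, log σ_β, logit p_i).  Given (S, σ_β) the latent p_i are conditionally
independent, so the p-block is updated componentwise in a single
vectorised accept/reject step; step sizes adapt per block during warmup
toward an acceptance rate of 0.44.  Convergence is gated on the split-Rhat
of S across chains: runs with Rhat(S) >= 1.2 are flagged not retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit

from ._rng import stage_rng, stage_seed_sequence

__all__ = [
    "PRIOR_S",
    "PRIOR_SIGMA_BETA",
    "RETENTION_RHAT",
    "InferenceData",
    "PosteriorResult",
    "RetentionReport",
    "preprocess",
    "simple_model_logpost",
    "drift_model_logpost",
    "fit",
    "rhat",
    "replicate_runs",
]

logger = logging.getLogger(__name__)

PRIOR_S = (-2.0, 2.0)
PRIOR_SIGMA_BETA = (0.0, 2.0)
RETENTION_RHAT = 1.2
DEFAULT_FREQ_FLOOR = 1e-4

_LOG2PI = np.log(2.0 * np.pi)
# log of the flat prior density 1/4 on S times 1/2 on sigma_beta
_LOG_PRIOR_CONST = -np.log(4.0) - np.log(2.0)


@dataclass(frozen=True)
class InferenceData:
    """Preprocessed per-SNP observations for architecture inference.

    ``f`` is clamped to [floor, 1-floor] and is what the simple model
    raises to the power S.  ``f_raw`` keeps the unclamped (but
    fixation-free) frequencies for the drift model's Beta likelihood,
    where the floor instead bounds the latent ancestral frequencies.
    """

    f: np.ndarray
    beta: np.ndarray
    fst: float | None = None
    snp_id: np.ndarray | None = None
    kept_idx: np.ndarray | None = None  # indices into the pre-filter input
    f_raw: np.ndarray | None = None
    floor: float = DEFAULT_FREQ_FLOOR

    def __post_init__(self):
        f = np.asarray(self.f, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        if f.shape != beta.shape or f.ndim != 1:
            raise ValueError("f and beta must be equal-length vectors")
        if np.any(f <= 0.0) or np.any(f >= 1.0):
            raise ValueError("preprocessed frequencies must lie strictly in (0, 1)")
        if self.fst is not None and not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie strictly in (0, 1)")
        if not (0.0 < self.floor < 0.5):
            raise ValueError("floor must lie in (0, 0.5)")
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "beta", beta)
        if self.f_raw is None:
            object.__setattr__(self, "f_raw", f)
        else:
            fr = np.asarray(self.f_raw, dtype=float)
            if fr.shape != f.shape or np.any(fr <= 0.0) or np.any(fr >= 1.0):
                raise ValueError("f_raw must match f in length and lie strictly in (0, 1)")
            object.__setattr__(self, "f_raw", fr)

    def __len__(self) -> int:
        return len(self.f)


def preprocess(f, beta, floor: float = DEFAULT_FREQ_FLOOR, fst: float | None = None,
               snp_id=None) -> InferenceData:
    """Drop fixed SNPs and clamp frequencies away from the boundaries.

    SNPs with f in {0, 1} have zero probability under both likelihoods and
    are removed.  Remaining frequencies are clamped to [floor, 1-floor]
    (default floor 1e-4), applied symmetrically at both tails so the
    minor/major allele labelling is irrelevant.  The clamp regularises the
    frequencies entering a [f(1-f)]^S term; the unclamped values are kept
    on ``f_raw`` because the drift model observes f only through the
    Balding–Nichols kernel, which needs no clamping — there the floor
    bounds the latent ancestral frequencies instead.  Original indices of
    the retained SNPs are kept for reporting.
    """
    f = np.asarray(f, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if f.shape != beta.shape or f.ndim != 1:
        raise ValueError("f and beta must be equal-length vectors")
    if not (0.0 < floor < 0.5):
        raise ValueError("floor must lie in (0, 0.5)")
    keep = (f > 0.0) & (f < 1.0)
    if not np.any(keep):
        raise ValueError("all SNPs are fixed; no data left for inference")
    kept_idx = np.flatnonzero(keep)
    f_raw = f[kept_idx]
    f_kept = np.clip(f_raw, floor, 1.0 - floor)
    ids = None if snp_id is None else np.asarray(snp_id, dtype=object)[kept_idx]
    return InferenceData(f=f_kept, beta=beta[kept_idx], fst=fst, snp_id=ids,
                         kept_idx=kept_idx, f_raw=f_raw, floor=floor)


def _in_prior_support(S: float, sigma_beta: float) -> bool:
    return PRIOR_S[0] < S < PRIOR_S[1] and PRIOR_SIGMA_BETA[0] < sigma_beta < PRIOR_SIGMA_BETA[1]


def _effect_loglik(S: float, sigma_beta: float, p: np.ndarray, beta: np.ndarray) -> float:
    logb = np.log(p * (1.0 - p))
    return float(
        np.sum(
            -0.5 * (_LOG2PI + 2.0 * np.log(sigma_beta) + S * logb)
            - beta**2 * np.exp(-S * logb) / (2.0 * sigma_beta**2)
        )
    )


def _bn_loglik(f: np.ndarray, p: np.ndarray, fst: float) -> float:
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    terms = (
        (a - 1.0) * np.log(f)
        + (b - 1.0) * np.log1p(-f)
        - (gammaln(a) + gammaln(b) - gammaln(a + b))
    )
    return float(np.sum(terms))


def simple_model_logpost(S: float, sigma_beta: float, data: InferenceData) -> float:
    """Log posterior density (up to MCMC-irrelevant constants) of the simple model."""
    if not _in_prior_support(S, sigma_beta):
        return -np.inf
    return _LOG_PRIOR_CONST + _effect_loglik(S, sigma_beta, data.f, data.beta)


def drift_model_logpost(S: float, sigma_beta: float, p, data: InferenceData) -> float:
    """Log posterior of the drift model at latent ancestral frequencies ``p``.

    Combines the flat priors on (S, σ_β) and on each p_i, the
    Balding–Nichols drift term for the observed f_i, and the
    ancestral-frequency effect-size likelihood.  The latent frequencies
    carry the floor: p outside [floor, 1-floor] has zero posterior density
    (this is where the frequency floor acts in the drift model, keeping
    the [p(1-p)]^S variance term bounded); the observed frequencies enter
    the Beta kernel unclamped.
    """
    if data.fst is None:
        raise ValueError("drift model requires data.fst")
    if not _in_prior_support(S, sigma_beta):
        return -np.inf
    p = np.asarray(p, dtype=float)
    if p.shape != data.f.shape:
        raise ValueError("p must match the number of SNPs")
    if np.any(p < data.floor) or np.any(p > 1.0 - data.floor):
        return -np.inf
    return (
        _LOG_PRIOR_CONST
        + _bn_loglik(data.f_raw, p, data.fst)
        + _effect_loglik(S, sigma_beta, p, data.beta)
    )


@dataclass
class PosteriorResult:
    """MCMC draws and convergence diagnostics for one fitted model."""

    model: str
    S: np.ndarray  # (n_chains, n_iter) post-warmup draws
    sigma_beta: np.ndarray  # (n_chains, n_iter)
    p: np.ndarray | None  # (n_chains, n_thinned, L) for the drift model
    p_thin: int
    n_chains: int
    rhat_S: float
    retained: bool
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def pooled_S(self) -> np.ndarray:
        return self.S.reshape(-1)

    def median_S(self) -> float:
        return float(np.median(self.pooled_S()))

    def ci_S(self, level: float = 0.9) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.pooled_S(), [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    def median_sigma_beta(self) -> float:
        return float(np.median(self.sigma_beta.reshape(-1)))


def rhat(chains) -> float:
    """Split-Rhat convergence statistic for a scalar parameter.

    Each chain is split in half; the statistic is
    sqrt(((n-1)/n·W + B/n) / W) over the 2m half-chains.  Values near 1
    indicate the chains explore the same distribution; the retention rule
    discards runs with Rhat(S) >= 1.2.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("rhat needs >= 2 chains of >= 4 draws each")
    half = arr.shape[1] // 2
    split = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    W = float(np.mean(np.var(split, axis=1, ddof=1)))
    if W == 0.0:
        warnings.warn("zero within-chain variance; Rhat reported as 1.0", RuntimeWarning)
        return 1.0
    B = half * float(np.var(np.mean(split, axis=1), ddof=1))
    var_hat = (half - 1.0) / half * W + B / half
    return float(np.sqrt(var_hat / W))


def _adapt(step: np.ndarray | float, accepted, window: int, target: float = 0.44):
    rate = np.asarray(accepted, dtype=float) / window
    return np.clip(step * np.exp(rate - target), 1e-4, 20.0)


def _run_chain_simple(data: InferenceData, n_warmup: int, n_iter: int,
                      rng: np.random.Generator):
    beta_sq = data.beta ** 2
    logb = np.log(data.f * (1.0 - data.f))
    L = len(data)

    S = rng.uniform(*PRIOR_S)
    eta = np.log(rng.uniform(0.1, 1.9))  # eta = log sigma_beta
    # Q(S) = sum beta_i^2 [f(1-f)]^{-S}; the sufficient statistic for sigma
    Q = float(np.sum(beta_sq * np.exp(-S * logb)))
    sum_logb = float(np.sum(logb))
    # (S, eta) posterior is a ridge: d eta / d S = -mean(log b)/2; propose along it
    shear = -0.5 * sum_logb / L

    step_S, step_eta = 0.1, 0.1
    acc_S = acc_eta = 0
    window = 50
    out_S = np.empty(n_iter)
    out_sig = np.empty(n_iter)

    for it in range(n_warmup + n_iter):
        # S block: sheared joint proposal (S, eta) -> (S+e, eta+shear*e);
        # unit Jacobian, symmetric, so plain Metropolis acceptance applies
        eps = step_S * rng.standard_normal()
        S_prop = S + eps
        eta_prop = eta + shear * eps
        if PRIOR_S[0] < S_prop < PRIOR_S[1] and np.exp(eta_prop) < PRIOR_SIGMA_BETA[1]:
            Q_prop = float(np.sum(beta_sq * np.exp(-S_prop * logb)))
            delta = (
                -0.5 * (S_prop - S) * sum_logb
                - (L - 1.0) * (eta_prop - eta)
                - Q_prop / (2.0 * np.exp(2 * eta_prop))
                + Q / (2.0 * np.exp(2 * eta))
            )
            if np.log(rng.uniform()) < delta:
                S, eta, Q = S_prop, eta_prop, Q_prop
                acc_S += 1
        # sigma block on log scale (flat prior on sigma => +eta Jacobian)
        eta_prop = eta + step_eta * rng.standard_normal()
        if np.exp(eta_prop) < PRIOR_SIGMA_BETA[1]:
            delta = (
                -L * (eta_prop - eta)
                - 0.5 * Q * (np.exp(-2 * eta_prop) - np.exp(-2 * eta))
                + (eta_prop - eta)
            )
            if np.log(rng.uniform()) < delta:
                eta = eta_prop
                acc_eta += 1
        if it < n_warmup:
            if (it + 1) % window == 0:
                step_S = float(_adapt(step_S, acc_S, window))
                step_eta = float(_adapt(step_eta, acc_eta, window))
                acc_S = acc_eta = 0
        else:
            out_S[it - n_warmup] = S
            out_sig[it - n_warmup] = np.exp(eta)
    return out_S, out_sig, None


def _run_chain_drift(data: InferenceData, n_warmup: int, n_iter: int,
                     rng: np.random.Generator, thin_p: int):
    f, beta_sq, fst = data.f_raw, data.beta ** 2, data.fst
    floor = data.floor
    L = len(data)
    logf, log1mf = np.log(f), np.log1p(-f)
    scale = (1.0 - fst) / fst

    def bn_terms(p):
        a = p * scale
        b = (1.0 - p) * scale
        return (a - 1.0) * logf + (b - 1.0) * log1mf - (
            gammaln(a) + gammaln(b) - gammaln(a + b)
        )

    S = rng.uniform(*PRIOR_S)
    eta = np.log(rng.uniform(0.1, 1.9))
    # latent ancestral frequencies start at the floored observed f with logit jitter
    zp = logit(np.clip(f, floor, 1.0 - floor)) + rng.normal(0.0, 0.05, size=L)
    p = np.clip(expit(zp), floor, 1.0 - floor)
    zp = logit(p)
    logb = np.log(p * (1.0 - p))
    d_cur = bn_terms(p)

    step_p = np.full(L, 0.5)
    step_S, step_eta = 0.05, 0.05
    acc_p = np.zeros(L)
    acc_S = acc_eta = 0
    window = 50

    out_S = np.empty(n_iter)
    out_sig = np.empty(n_iter)
    n_keep_p = (n_iter + thin_p - 1) // thin_p
    out_p = np.empty((n_keep_p, L))

    for it in range(n_warmup + n_iter):
        inv2sig2 = np.exp(-2.0 * eta) / 2.0
        # --- p block: componentwise RWM on logit scale (conditionally independent)
        z_prop = zp + step_p * rng.standard_normal(L)
        p_prop = expit(z_prop)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            # latent frequencies live on [floor, 1-floor]; outside has zero prior mass
            ok = (p_prop >= floor) & (p_prop <= 1.0 - floor)
            logb_prop = np.where(ok, np.log(p_prop * (1.0 - p_prop)), -np.inf)
            d_prop = np.where(ok, bn_terms(np.clip(p_prop, floor, 1.0 - floor)), -np.inf)
            delta = (
                (d_prop - d_cur)
                - 0.5 * S * (logb_prop - logb)
                - beta_sq * inv2sig2 * (np.exp(-S * logb_prop) - np.exp(-S * logb))
                + (logb_prop - logb)  # Jacobian of the logit transform
            )
            accept = np.log(rng.uniform(size=L)) < np.where(np.isfinite(delta), delta, -np.inf)
        zp = np.where(accept, z_prop, zp)
        p = np.where(accept, p_prop, p)
        logb = np.where(accept, logb_prop, logb)
        d_cur = np.where(accept, d_prop, d_cur)
        acc_p += accept

        # --- S block (local proposal: large sheared jumps along the (S, eta)
        # ridge can carry chains into the S > 0 local mode, where the latent
        # frequencies equilibrate and trap them; small steps with the latent
        # p guiding S toward the global mode mix reliably here)
        S_prop = S + step_S * rng.standard_normal()
        if PRIOR_S[0] < S_prop < PRIOR_S[1]:
            dq = np.sum(beta_sq * (np.exp(-S_prop * logb) - np.exp(-S * logb)))
            delta = -0.5 * (S_prop - S) * np.sum(logb) - dq * inv2sig2
            if np.log(rng.uniform()) < delta:
                S = S_prop
                acc_S += 1

        # --- sigma block on log scale
        eta_prop = eta + step_eta * rng.standard_normal()
        if np.exp(eta_prop) < PRIOR_SIGMA_BETA[1]:
            Q = float(np.sum(beta_sq * np.exp(-S * logb)))
            delta = (
                -L * (eta_prop - eta)
                - 0.5 * Q * (np.exp(-2 * eta_prop) - np.exp(-2 * eta))
                + (eta_prop - eta)
            )
            if np.log(rng.uniform()) < delta:
                eta = eta_prop
                acc_eta += 1

        if it < n_warmup:
            if (it + 1) % window == 0:
                step_p = _adapt(step_p, acc_p, window)
                step_S = float(_adapt(step_S, acc_S, window))
                step_eta = float(_adapt(step_eta, acc_eta, window))
                acc_p[:] = 0
                acc_S = acc_eta = 0
        else:
            k = it - n_warmup
            out_S[k] = S
            out_sig[k] = np.exp(eta)
            if k % thin_p == 0:
                out_p[k // thin_p] = p
    return out_S, out_sig, out_p


def fit(model: str, data: InferenceData, n_chains: int = 4, n_iter: int = 1000,
        n_warmup: int | None = None, seed: int = 0, thin_p: int = 10) -> PosteriorResult:
    """Sample the posterior of the chosen model by adaptive Metropolis-within-Gibbs.

    Parameters
    ----------
    model : {"simple", "drift"}
    data : preprocessed observations; the drift model requires ``data.fst``.
    n_chains : independent chains (>= 2, needed for Rhat).
    n_iter : post-warmup draws per chain (>= 200).
    n_warmup : warmup/adaptation iterations per chain (default: ``n_iter``).
    seed : master seed; chains derive independent streams from it.
    thin_p : thinning interval for stored latent-frequency draws.

    The run is flagged ``retained`` when split-Rhat of S is below 1.2.
    Numerical failure in any chain marks the run not retained with a
    diagnostic message rather than raising.
    """
    if model not in ("simple", "drift"):
        raise ValueError("model must be 'simple' or 'drift'")
    if len(data) == 0:
        raise ValueError("data is empty")
    if model == "drift" and data.fst is None:
        raise ValueError("drift model requires data.fst")
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2 for Rhat")
    if n_iter < 200:
        raise ValueError("n_iter must be >= 200 post-warmup draws")
    if n_warmup is None:
        n_warmup = n_iter

    S_draws = np.empty((n_chains, n_iter))
    sig_draws = np.empty((n_chains, n_iter))
    p_draws = [] if model == "drift" else None
    failure = None
    for chain in range(n_chains):
        rng = stage_rng(seed, "mcmc", model, chain)
        try:
            if model == "simple":
                s, sg, _ = _run_chain_simple(data, n_warmup, n_iter, rng)
            else:
                s, sg, pp = _run_chain_drift(data, n_warmup, n_iter, rng, thin_p)
                p_draws.append(pp)
            if not (np.all(np.isfinite(s)) and np.all(np.isfinite(sg))):
                raise FloatingPointError("non-finite draws")
        except FloatingPointError as exc:  # pragma: no cover - defensive
            failure = f"chain {chain}: {exc}"
            logger.warning("sampler failure in %s", failure)
            s = np.full(n_iter, np.nan)
            sg = np.full(n_iter, np.nan)
            if model == "drift":
                p_draws.append(np.full((1, len(data)), np.nan))
        S_draws[chain] = s
        sig_draws[chain] = sg

    diagnostics = {}
    if failure is not None:
        rhat_S = np.inf
        diagnostics["failure"] = failure
    else:
        rhat_S = rhat(S_draws)
    return PosteriorResult(
        model=model,
        S=S_draws,
        sigma_beta=sig_draws,
        p=np.stack(p_draws) if (p_draws and failure is None) else None,
        p_thin=thin_p,
        n_chains=n_chains,
        rhat_S=rhat_S,
        retained=bool(rhat_S < RETENTION_RHAT),
        seed=seed,
        diagnostics=diagnostics,
    )


@dataclass
class RetentionReport:
    """Outcome of replicate fitting with Rhat-based retention."""

    results: list
    retention_cut: float
    n_replicates: int

    @property
    def retained(self) -> list:
        return [r for r in self.results if r.rhat_S < self.retention_cut]

    @property
    def fraction_retained(self) -> float:
        return len(self.retained) / self.n_replicates

    @property
    def fraction_rhat_below_102(self) -> float:
        return sum(r.rhat_S < 1.02 for r in self.results) / self.n_replicates

    @property
    def retained_medians(self) -> np.ndarray:
        return np.array([r.median_S() for r in self.retained])

    @property
    def all_failed(self) -> bool:
        return len(self.retained) == 0


def replicate_runs(model: str, data_generator, n_replicates: int,
                   retention_cut: float = RETENTION_RHAT, seed: int = 0,
                   **fit_kwargs) -> RetentionReport:
    """Fit ``n_replicates`` independently generated datasets and gate on Rhat.

    ``data_generator(replicate_index, seed)`` must return an InferenceData;
    it receives a per-replicate child seed derived from the master seed.
    A ``retention_cut`` of ``inf`` keeps every run regardless of Rhat.
    Zero retained runs produce a report with ``all_failed`` set, never an
    exception.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    results = []
    for i in range(n_replicates):
        data_seed = int(stage_seed_sequence(seed, "replicate-data", i).generate_state(1)[0] % (2**31))
        fit_seed = int(stage_seed_sequence(seed, "replicate-fit", i).generate_state(1)[0] % (2**31))
        data = data_generator(i, data_seed)
        results.append(fit(model, data, seed=fit_seed, **fit_kwargs))
    report = RetentionReport(results=results, retention_cut=retention_cut,
                             n_replicates=n_replicates)
    if report.all_failed:
        logger.warning("no replicate retained at Rhat < %.3g", retention_cut)
    return report
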