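"""Complex-trait simulation under a frequency-dependent architecture.

Per-SNP effect sizes follow

    β_i ~ Normal(0, σ_β² [p_i(1-p_i)]^S),

so the shape parameter S links effect-size variance to allele frequency:
S < 0 gives rare SNPs larger effects (the signature of negative selection),
S = 0 decouples the two, S > 0 favours common SNPs.  Genomes are binary
(x_ki ~ Bernoulli(f_i)) and phenotypes additive with Gaussian noise.

Two SNP-selection regimes control how rare causal variants are treated:
``unbounded`` admits every segregating SNP (p > 0), allowing arbitrarily
large per-SNP variance when S < 0, while ``bounded`` restricts causal SNPs
to p > 0.01, capping the variance multiplier at [0.01·0.99]^-1 ≈ 101 for
S = -1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .panels import AncestralPanel

__all__ = [
    "TraitArchitecture",
    "TraitRealization",
    "CohortData",
    "variance_multiplier",
    "select_causal_snps",
    "draw_effects",
    "genetic_variance",
    "environmental_variance",
    "simulate_cohort",
    "observed_heritability",
]

logger = logging.getLogger(__name__)

BOUNDED_FREQ_THRESHOLD = 0.01


@dataclass(frozen=True)
class TraitArchitecture:
    """Generative parameters of the architecture model."""

    S: float
    sigma_beta_sq: float = 1.0
    h2_target: float = 0.5
    n_causal: int = 1000
    mode: str = "unbounded"

    def __post_init__(self):
        if not np.isfinite(self.S):
            raise ValueError("S must be finite")
        if self.sigma_beta_sq <= 0:
            raise ValueError("sigma_beta_sq must be positive")
        if not (0.0 < self.h2_target < 1.0):
            raise ValueError("h2_target must lie in (0, 1)")
        if self.n_causal < 1:
            raise ValueError("n_causal must be >= 1")
        if self.mode not in ("unbounded", "bounded"):
            raise ValueError("mode must be 'unbounded' or 'bounded'")

    @property
    def selection_threshold(self) -> float:
        return BOUNDED_FREQ_THRESHOLD if self.mode == "bounded" else 0.0


@dataclass(frozen=True)
class TraitRealization:
    """A realised trait: causal SNPs, effects and variance components."""

    causal_idx: np.ndarray
    beta: np.ndarray
    Vg: float
    Ve: float

    def __post_init__(self):
        object.__setattr__(self, "causal_idx", np.asarray(self.causal_idx, dtype=int))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if len(self.causal_idx) != len(self.beta):
            raise ValueError("causal_idx and beta must have equal length")
        if self.Vg < 0 or self.Ve < 0:
            raise ValueError("variance components must be non-negative")

    def to_tsv(self, path, snp_id=None) -> None:
        ids = (
            np.asarray(snp_id, dtype=object)[self.causal_idx]
            if snp_id is not None
            else np.array([f"snp{i}" for i in self.causal_idx], dtype=object)
        )
        pd.DataFrame({"snp_id": ids, "beta": self.beta}).to_csv(
            path, sep="\t", index=False, float_format="%.9g", lineterminator="\n"
        )


@dataclass(frozen=True)
class CohortData:
    """Binary genomes and phenotypes for a simulated cohort."""

    genotypes: np.ndarray  # n_individuals x n_causal, entries in {0, 1}
    phenotypes: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        y = np.asarray(self.phenotypes, dtype=float)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if not np.isin(g, (0, 1)).all():
            raise ValueError("genotype entries must be 0 or 1")
        if len(y) != g.shape[0]:
            raise ValueError("phenotype length must match genotype rows")
        object.__setattr__(self, "genotypes", g.astype(np.int8))
        object.__setattr__(self, "phenotypes", y)

    def to_tsv(self, genotype_path, phenotype_path) -> None:
        np.savetxt(genotype_path, self.genotypes, fmt="%d", delimiter="\t")
        pd.DataFrame(
            {
                "individual_id": [f"ind{k}" for k in range(len(self.phenotypes))],
                "y": self.phenotypes,
            }
        ).to_csv(phenotype_path, sep="\t", index=False, float_format="%.9g", lineterminator="\n")


def variance_multiplier(p, S: float):
    """Per-SNP prior-variance multiplier [p(1-p)]^S of the effect-size model.

    At S = -1 this is 4 for p = 0.5 and grows without bound as p → 0
    (20001 at p = 5e-5); the bounded selection regime caps it near 101.
    """
    p = np.asarray(p, dtype=float)
    if S < 0 and (np.any(p <= 0.0) or np.any(p >= 1.0)):
        raise ValueError("p must lie strictly in (0, 1) when S < 0")
    return (p * (1.0 - p)) ** S


def select_causal_snps(panel: AncestralPanel, arch: TraitArchitecture, seed: int = 0) -> np.ndarray:
    """Sample ``arch.n_causal`` causal SNP indices uniformly without replacement.

    The eligible set depends on the selection regime: p > 0 (unbounded) or
    p > 0.01 (bounded).
    """
    thr = arch.selection_threshold
    eligible = np.flatnonzero(panel.p > thr)
    if len(eligible) < arch.n_causal:
        raise ValueError(
            f"{arch.mode} mode (frequency > {thr}) leaves {len(eligible)} eligible SNPs, "
            f"fewer than n_causal={arch.n_causal}"
        )
    rng = stage_rng(seed, "causal-selection")
    idx = rng.choice(eligible, size=arch.n_causal, replace=False)
    return np.sort(idx)


def draw_effects(p, arch: TraitArchitecture, seed: int = 0) -> np.ndarray:
    """Draw β_i ~ Normal(0, σ_β² [p_i(1-p_i)]^S) independently per SNP."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("p must lie strictly in (0, 1)")
    rng = stage_rng(seed, "effects")
    sd = np.sqrt(arch.sigma_beta_sq * variance_multiplier(p, arch.S))
    return rng.normal(0.0, sd)


def genetic_variance(beta, f) -> float:
    """Additive genetic variance Σ_i β_i² f_i(1-f_i) under Bernoulli genomes."""
    beta = np.asarray(beta, dtype=float)
    f = np.asarray(f, dtype=float)
    if beta.shape != f.shape:
        raise ValueError("beta and f must have equal length")
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    return float(np.sum(beta**2 * f * (1.0 - f)))


def environmental_variance(Vg_evolved: float, h2: float) -> float:
    """Environmental variance fixing h² = Vg/(Vg+Ve) in the evolving population.

    Ve = Vg·(1-h²)/h²; at h² = 0.5 this is simply Ve = Vg(evolved).  Ve is
    held constant across populations thereafter.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie in (0, 1)")
    if Vg_evolved < 0:
        raise ValueError("Vg_evolved must be non-negative")
    return Vg_evolved * (1.0 - h2) / h2


def simulate_cohort(f, beta, Ve: float, n: int, seed: int = 0) -> CohortData:
    """Simulate n binary genomes x_ki ~ Bern(f_i) and phenotypes y_k = Σβx + N(0, Ve)."""
    f = np.asarray(f, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if Ve < 0:
        raise ValueError("Ve must be non-negative")
    rng = stage_rng(seed, "cohort")
    x = (rng.uniform(size=(n, len(f))) < f).astype(np.int8)
    y = x @ beta + (rng.normal(0.0, np.sqrt(Ve), size=n) if Ve > 0 else 0.0)
    return CohortData(genotypes=x, phenotypes=np.asarray(y, dtype=float))


def observed_heritability(beta, f_target, Ve: float, maf_threshold: float = 0.0) -> float:
    """Observed h² in a target population after MAF thresholding.

    Genetic variance is recomputed from SNPs whose minor-allele frequency
    min(f, 1-f) exceeds ``maf_threshold``; the environmental variance is NOT
    rescaled (constant across populations), so drift that inflates or
    removes genetic variation shows up directly in the observed h².
    """
    if Ve <= 0:
        raise ValueError("Ve must be positive")
    if not (0.0 <= maf_threshold < 0.5):
        raise ValueError("maf_threshold must lie in [0, 0.5)")
    beta = np.asarray(beta, dtype=float)
    f = np.asarray(f_target, dtype=float)
    maf = np.minimum(f, 1.0 - f)
    keep = maf > maf_threshold
    if not np.any(keep):
        logger.warning("no SNP passes MAF threshold %.4g; observed h2 is 0", maf_threshold)
        return 0.0
    Vg = genetic_variance(beta[keep], f[keep])
    return Vg / (Vg + Ve)
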