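"""F_st estimation between two populations.

The Weir–Cockerham estimator here operates on per-SNP allele frequencies
and allele sample sizes (the summary a frequency panel provides), using
the standard two-population ANOVA decomposition:

    MSP_l = Σ_i n_il (f_il - f̄_l)²            (between populations, r-1 df)
    MSG_l = Σ_i n_il f_il (1-f_il) / Σ_i (n_il - 1)   (within populations)

combined across SNPs as a ratio of averages (sum of per-SNP numerators
over sum of denominators), matching how plink 1.9 pools SNPs.  A
method-of-moments companion, :func:`bn_moment_fst`, recovers the F_st of a
Balding–Nichols drift episode when the ancestral frequencies are known,
via Var(f_i) = F_st·p_i(1-p_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TwoPopFreqData", "FstEstimate", "weir_cockerham_fst", "bn_moment_fst"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoPopFreqData:
    """Per-SNP allele frequencies and allele counts for two populations."""

    f1: np.ndarray
    f2: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    snp_id: np.ndarray | None = None

    def __post_init__(self):
        f1 = np.asarray(self.f1, dtype=float)
        f2 = np.asarray(self.f2, dtype=float)
        n1 = np.broadcast_to(np.asarray(self.n1, dtype=float), f1.shape).copy()
        n2 = np.broadcast_to(np.asarray(self.n2, dtype=float), f2.shape).copy()
        if not (f1.shape == f2.shape == n1.shape == n2.shape):
            raise ValueError("all fields must have equal length")
        for name, f in (("f1", f1), ("f2", f2)):
            if np.any(f < 0.0) or np.any(f > 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(n1 < 2) or np.any(n2 < 2):
            raise ValueError("sample sizes must be >= 2 alleles")
        object.__setattr__(self, "f1", f1)
        object.__setattr__(self, "f2", f2)
        object.__setattr__(self, "n1", n1)
        object.__setattr__(self, "n2", n2)

    def __len__(self) -> int:
        return len(self.f1)

    @classmethod
    def from_tsv(cls, path) -> "TwoPopFreqData":
        df = pd.read_csv(path, sep="\t")
        return cls(
            f1=df["f1"].to_numpy(), f2=df["f2"].to_numpy(),
            n1=df["n1"].to_numpy(), n2=df["n2"].to_numpy(),
            snp_id=df["snp_id"].astype(str).to_numpy() if "snp_id" in df else None,
        )


@dataclass(frozen=True)
class FstEstimate:
    """Pooled F_st estimate with the raw (unclipped) value retained."""

    value: float  # clipped to [0, 1] for reporting
    raw: float
    n_snps_used: int
    n_monomorphic_skipped: int
    per_snp: pd.DataFrame | None = None


def weir_cockerham_fst(data: TwoPopFreqData, return_per_snp: bool = False) -> FstEstimate:
    """Weir–Cockerham F_st between two populations, ratio of averages across SNPs.

    SNPs monomorphic in the pooled sample carry no information about
    differentiation (zero denominator) and are skipped, with a count
    recorded on the estimate.
    """
    f1, f2, n1, n2 = data.f1, data.f2, data.n1, data.n2
    n_tot = n1 + n2
    p_bar = (n1 * f1 + n2 * f2) / n_tot
    poly = (p_bar > 0.0) & (p_bar < 1.0)
    n_skip = int(np.sum(~poly))
    if not np.any(poly):
        raise ValueError("no polymorphic SNPs in the pooled sample; F_st undefined")
    if n_skip:
        logger.info("skipping %d SNPs monomorphic in the pooled sample", n_skip)

    f1, f2, n1, n2, n_tot, p_bar = (x[poly] for x in (f1, f2, n1, n2, n_tot, p_bar))
    r = 2.0
    n_bar = n_tot / r
    n_c = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1.0)
    msp = (n1 * (f1 - p_bar) ** 2 + n2 * (f2 - p_bar) ** 2) / (r - 1.0)
    msg = (n1 * f1 * (1.0 - f1) + n2 * f2 * (1.0 - f2)) / (n_tot - r)
    num = msp - msg
    den = msp + (n_c - 1.0) * msg
    raw = float(np.sum(num) / np.sum(den))
    per_snp = None
    if return_per_snp:
        ids = data.snp_id[poly] if data.snp_id is not None else np.arange(len(f1))
        per_snp = pd.DataFrame({"snp_id": ids, "numerator": num, "denominator": den})
    return FstEstimate(
        value=float(np.clip(raw, 0.0, 1.0)),
        raw=raw,
        n_snps_used=int(np.sum(poly)),
        n_monomorphic_skipped=n_skip,
        per_snp=per_snp,
    )


def bn_moment_fst(p, f) -> float:
    """Method-of-moments F_st of one Balding–Nichols drift episode.

    With known ancestral frequencies p_i and drifted frequencies f_i,
    Var(f_i) = F_st·p_i(1-p_i) gives the pooled estimator
    Σ(f_i-p_i)² / Σ p_i(1-p_i).  Useful for simulation QC.
    """
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    if p.shape != f.shape:
        raise ValueError("p and f must have equal length")
    seg = (p > 0.0) & (p < 1.0)
    if not np.any(seg):
        raise ValueError("all ancestral frequencies are fixed; F_st undefined")
    denom = float(np.sum(p[seg] * (1.0 - p[seg])))
    return float(np.sum((f[seg] - p[seg]) ** 2) / denom)
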