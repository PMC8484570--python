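"""Allele-frequency panels and the Balding–Nichols drift kernel.

An :class:`AncestralPanel` holds per-SNP allele frequencies ``p_i`` in the
evolving population (the population in which a trait's architecture arose).
:func:`drift_panel` pushes those frequencies through one episode of genetic
drift, parameterised by the fixation index ``F_st``, using the
Balding–Nichols Beta kernel

    f_i | p_i, F_st  ~  Beta(p_i (1-F_st)/F_st, (1-p_i) (1-F_st)/F_st),

which has E(f_i) = p_i and Var(f_i) = F_st · p_i (1-p_i).  The same kernel's
log density, :func:`bn_log_density`, is the drift term of the drift-aware
inference model.

SNPs already fixed (p in {0, 1}) pass through drift unchanged: a fixed
allele cannot drift, and the Beta kernel is degenerate there.  Downstream
inference removes fixed SNPs explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import betaln

from ._rng import stage_rng

__all__ = [
    "AncestralPanel",
    "DriftedPanel",
    "FrequencyDistribution",
    "uniform_dist",
    "beta_dist",
    "neutral_sfs_dist",
    "sample_ancestral_panel",
    "drift_panel",
    "bn_log_density",
    "bn_shapes",
]

# canonical float format for TSV round-trips (>= 6 significant digits)
_FLOAT_FMT = "%.9g"


def _as_freq_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class AncestralPanel:
    """Per-SNP allele frequencies p_i in the evolving population."""

    snp_id: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))
        object.__setattr__(self, "p", _as_freq_array(self.p, "p"))
        if len(self.snp_id) != len(self.p):
            raise ValueError("snp_id and p must have equal length")
        if len(set(self.snp_id)) != len(self.snp_id):
            raise ValueError("snp_id entries must be unique")

    def __len__(self) -> int:
        return len(self.p)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"snp_id": self.snp_id, "p": self.p})
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "AncestralPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(snp_id=df["snp_id"].astype(str).to_numpy(), p=df["p"].to_numpy())


@dataclass(frozen=True)
class DriftedPanel:
    """Per-SNP target-population frequencies f_i plus the generating F_st."""

    snp_id: np.ndarray
    f: np.ndarray
    fst: float
    source: AncestralPanel | str = "observed"

    def __post_init__(self):
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))
        object.__setattr__(self, "f", _as_freq_array(self.f, "f"))
        if len(self.snp_id) != len(self.f):
            raise ValueError("snp_id and f must have equal length")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie strictly in (0, 1)")
        if isinstance(self.source, AncestralPanel) and not np.array_equal(
            self.source.snp_id, self.snp_id
        ):
            raise ValueError("drifted panel must preserve the source snp_id order")

    def __len__(self) -> int:
        return len(self.f)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"snp_id": self.snp_id, "f": self.f, "fst": self.fst})
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "DriftedPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(
            snp_id=df["snp_id"].astype(str).to_numpy(),
            f=df["f"].to_numpy(),
            fst=float(df["fst"].iloc[0]),
            source="observed",
        )


@dataclass(frozen=True)
class FrequencyDistribution:
    """Specification of the i.i.d. source distribution of ancestral frequencies.

    ``kind`` is one of ``uniform`` (params a, b), ``beta`` (shape params a, b)
    or ``neutral-sfs`` (density ∝ 1/p truncated to [p_min, 1-p_min]).
    """

    kind: str
    params: tuple = field(default=())

    def __post_init__(self):
        if self.kind == "uniform":
            a, b = self.params
            if not (0.0 <= a <= b <= 1.0):
                raise ValueError("uniform bounds require 0 <= a <= b <= 1")
        elif self.kind == "beta":
            a, b = self.params
            if a <= 0 or b <= 0:
                raise ValueError("beta shapes must be positive")
        elif self.kind == "neutral-sfs":
            (p_min,) = self.params
            if not (0.0 < p_min < 0.5):
                raise ValueError("neutral-sfs requires 0 < p_min < 0.5")
        else:
            raise ValueError(f"unknown frequency distribution kind: {self.kind!r}")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            a, b = self.params
            return rng.uniform(a, b, size=size) if a < b else np.full(size, a)
        if self.kind == "beta":
            a, b = self.params
            return rng.beta(a, b, size=size)
        # neutral-sfs: inverse-CDF of 1/p on [p_min, 1-p_min]
        (p_min,) = self.params
        u = rng.uniform(size=size)
        return p_min * np.exp(u * np.log((1.0 - p_min) / p_min))

    @classmethod
    def parse(cls, text: str) -> "FrequencyDistribution":
        """Parse strings like ``uniform:0.001,0.999`` or ``neutral-sfs:0.001``."""
        kind, _, rest = text.partition(":")
        params = tuple(float(x) for x in rest.split(",")) if rest else ()
        return cls(kind=kind.strip(), params=params)


def uniform_dist(a: float, b: float) -> FrequencyDistribution:
    return FrequencyDistribution("uniform", (a, b))


def beta_dist(a: float, b: float) -> FrequencyDistribution:
    return FrequencyDistribution("beta", (a, b))


def neutral_sfs_dist(p_min: float) -> FrequencyDistribution:
    return FrequencyDistribution("neutral-sfs", (p_min,))


def sample_ancestral_panel(
    L: int,
    freq_dist: FrequencyDistribution | str = "uniform:0.001,0.999",
    seed: int = 0,
) -> AncestralPanel:
    """Draw ``L`` i.i.d. ancestral allele frequencies from ``freq_dist``.

    The default uniform(0.001, 0.999) covers the frequency axis without
    producing fixed alleles; inference conditions on frequencies, so the
    source distribution only affects that coverage.
    """
    if L < 1:
        raise ValueError("L must be a positive integer")
    if isinstance(freq_dist, str):
        freq_dist = FrequencyDistribution.parse(freq_dist)
    rng = stage_rng(seed, "ancestral-panel")
    p = freq_dist.sample(L, rng)
    snp_id = np.array([f"snp{i}" for i in range(L)], dtype=object)
    return AncestralPanel(snp_id=snp_id, p=p)


def bn_shapes(p, fst: float):
    """Beta shape parameters (α, β) of the Balding–Nichols kernel."""
    scale = (1.0 - fst) / fst
    p = np.asarray(p, dtype=float)
    return p * scale, (1.0 - p) * scale


def drift_panel(panel: AncestralPanel, fst: float, seed: int = 0) -> DriftedPanel:
    """Drift a panel through the Balding–Nichols kernel at fixation index ``fst``.

    Each f_i is drawn independently from Beta(p_i(1-F)/F, (1-p_i)(1-F)/F),
    so E(f_i) = p_i and Var(f_i) = fst·p_i(1-p_i).  SNPs with p in {0, 1}
    pass through unchanged.
    """
    if not (0.0 < fst < 1.0):
        raise ValueError("fst must lie strictly in (0, 1)")
    rng = stage_rng(seed, "drift")
    p = panel.p
    f = p.copy()
    seg = (p > 0.0) & (p < 1.0)
    if np.any(seg):
        a, b = bn_shapes(p[seg], fst)
        f[seg] = rng.beta(a, b)
    return DriftedPanel(snp_id=panel.snp_id, f=f, fst=fst, source=panel)


def bn_log_density(f, p, fst: float):
    """Log density of the Balding–Nichols Beta kernel at drifted frequency ``f``.

    Vectorised over ``f`` and ``p``.  Both must lie strictly in (0, 1): the
    kernel puts zero mass at fixation, so fixed SNPs must be excluded by the
    caller before evaluating it.
    """
    f = np.asarray(f, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValueError("f must lie strictly in (0, 1); exclude fixed SNPs")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("p must lie strictly in (0, 1)")
    if not (0.0 < fst < 1.0):
        raise ValueError("fst must lie strictly in (0, 1)")
    a, b = bn_shapes(p, fst)
    return (a - 1.0) * np.log(f) + (b - 1.0) * np.log1p(-f) - betaln(a, b)
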