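"""Seeded end-to-end fixture generation.

``make_fixture`` composes the simulation pipeline (ancestral panel →
effects → drift → inference preprocessing) into a small set of TSV files
plus a manifest recording the spec and SHA-256 checksums of every file.
Serialization uses a fixed float format so an identical spec always
yields identical checksums, which tests and docs rely on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import drift_panel, sample_ancestral_panel
from .trait import TraitArchitecture, draw_effects, select_causal_snps
from .infer import preprocess

__all__ = ["FixtureSpec", "make_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture set."""

    L: int = 500
    S_true: float = -1.0
    sigma_beta_sq: float = 1.0
    fst: float = 0.1
    mode: str = "unbounded"
    seed: int = 0
    freq_dist: str = "uniform:0.001,0.999"
    floor: float = 1e-4


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write ancestral.tsv, effects.tsv, drifted.tsv, inference_input.tsv + manifest.

    Returns the manifest dict.  The causal set covers the whole panel in
    unbounded mode; in bounded mode only SNPs with ancestral p > 0.01 are
    eligible, so the effects table may be shorter than the panel.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = sample_ancestral_panel(spec.L, spec.freq_dist, seed=spec.seed)
    n_eligible = int(np.sum(panel.p > (0.01 if spec.mode == "bounded" else 0.0)))
    arch = TraitArchitecture(S=spec.S_true, sigma_beta_sq=spec.sigma_beta_sq,
                             n_causal=n_eligible, mode=spec.mode)
    causal = select_causal_snps(panel, arch, seed=spec.seed)
    beta = draw_effects(panel.p[causal], arch, seed=spec.seed)
    drifted = drift_panel(panel, spec.fst, seed=spec.seed)
    data = preprocess(drifted.f[causal], beta, floor=spec.floor, fst=spec.fst,
                      snp_id=panel.snp_id[causal])

    panel.to_tsv(out / "ancestral.tsv")
    pd.DataFrame({"snp_id": panel.snp_id[causal], "beta": beta}).to_csv(
        out / "effects.tsv", sep="\t", index=False, float_format="%.9g", lineterminator="\n")
    drifted.to_tsv(out / "drifted.tsv")
    pd.DataFrame({"snp_id": data.snp_id, "f": data.f, "beta": data.beta}).to_csv(
        out / "inference_input.tsv", sep="\t", index=False, float_format="%.9g",
        lineterminator="\n")

    files = ["ancestral.tsv", "effects.tsv", "drifted.tsv", "inference_input.tsv"]
    manifest = {
        "spec": asdict(spec),
        "checksums": {name: _sha256(out / name) for name in files},
        "n_causal": int(len(causal)),
        "n_inference_snps": int(len(data)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
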