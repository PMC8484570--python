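import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import driftarch as da

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel() -> da.AncestralPanel:
    """500-SNP ancestral panel covering the frequency axis."""
    return da.sample_ancestral_panel(500, "uniform:0.001,0.999", seed=11)


@pytest.fixture(scope="session")
def arch_s_minus1() -> da.TraitArchitecture:
    return da.TraitArchitecture(S=-1.0, sigma_beta_sq=1.0, h2_target=0.5, n_causal=500)


@pytest.fixture(scope="session")
def drifted_dataset(small_panel, arch_s_minus1):
    """Effects in the evolving population + drifted observations (fst=0.1)."""
    beta = da.draw_effects(small_panel.p, arch_s_minus1, seed=21)
    drifted = da.drift_panel(small_panel, 0.1, seed=22)
    return small_panel, beta, drifted


@pytest.fixture(scope="session")
def tiny_inference_data() -> da.InferenceData:
    """20 SNPs simulated in the evolving population at S = -1."""
    rng = np.random.default_rng(5)
    f = rng.uniform(0.02, 0.98, size=20)
    beta = rng.normal(0.0, np.sqrt((f * (1 - f)) ** -1.0))
    return da.preprocess(f, beta)
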