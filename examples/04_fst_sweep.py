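"""How the drift-naive bias in S grows with F_st, and how the drift model fixes it.

Runs a small F_st sweep (two replicates per cell) fitting both models to
Balding-Nichols data simulated at S = -1, then prints the per-cell
summary: the naive model's attenuation toward 0 grows with drift
distance, while the drift model stays centred on the truth.
"""

from driftarch.sweep import SweepConfig, run_fst_sweep, summarize

config = SweepConfig(
    S_true=(-1.0,),
    fst_grid=(0.02, 0.1, 0.2),
    L=1000,
    n_replicates=2,
    models=("simple", "drift"),
    n_chains=4,
    n_iter=1000,
)
result = run_fst_sweep(config, seed=3)
summary = summarize(result)
cols = ["fst", "model", "median_of_medians_S", "mean_bias", "retention_fraction"]
print(summary[cols].to_string(index=False, float_format=lambda x: f"{x:+.3f}"))
print("\nmean_bias is posterior-median minus the simulated S = -1; the simple")
print("model's bias rises with fst, the drift model's stays near zero.")
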