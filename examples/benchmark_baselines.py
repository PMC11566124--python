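"""FDR/power comparison of the CRT against regression baselines.

A small version of the semi-synthetic benchmark: the response is a linear
combination of SQUARED centered log-CPM values, so linear-model baselines
are misspecified. The marginal t-test picks up indirect correlations and
overshoots the FDR target; the CRT stays calibrated.
"""

import sccrt

cfg = sccrt.SimulationConfig(n_cells=1000, n_genes=40, latent_dim=4,
                             n_causal=8, seed=2)
table = sccrt.run_benchmark(cfg,
                            methods=("crt_mlp", "ols", "marginal"),
                            alphas=(0.1,), n_replicates=3, seed=2, n_mc=100,
                            gen_config={"latent_dim": 4})

summary = sccrt.summarize_benchmark(table)
print(summary.to_string(index=False))
print("\nfdr_mean is the realized false discovery proportion at target 0.1;"
      "\ntpr_mean the fraction of truly causal genes recovered. The marginal"
      "\ntest trades calibration for raw discoveries; the CRT does not.")
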