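"""Gene-level conditional independence testing on simulated data.

Simulates a small single-cell count matrix with a known causal gene set,
runs the full CRT pipeline (split, NB-VAE null model, MLP importance
score, BH correction), and compares the discoveries with the truth.
"""

import numpy as np

import sccrt

cfg = sccrt.SimulationConfig(n_cells=1000, n_genes=30, latent_dim=4,
                             n_causal=6, seed=1)
sim = sccrt.simulate_dataset(cfg)
print(f"simulated {cfg.n_cells} cells x {cfg.n_genes} genes, "
      f"causal genes: {sim.causal_set.tolist()}")

out = sccrt.run_pipeline(sim.dataset, sim.response,
                         predictor_family="mlp_gaussian",
                         n_mc=200, alpha=0.1, seed=1,
                         gen_config={"latent_dim": 4})
res = out.results["genes"]
disc = res.discovery_indices()
metrics = sccrt.evaluate(disc, sim.causal_set)

print(f"discoveries at FDR 0.1: {sorted(disc.tolist())}")
print(f"FDR {metrics.fdr:.2f}  TPR {metrics.tpr:.2f}  "
      f"({metrics.n_discoveries} discoveries)")
print("\nper-gene results (smallest p first):")
print(res.to_frame().nsmallest(8, "p_value")[
    ["genes", "p_value", "q_value", "rejected"]].to_string(index=False))

# cell scores localize an association: positive values mark cells where
# randomizing the gene degrades the prediction of the response
if len(disc):
    g = disc[0]
    cs = res.cell_scores[g]
    print(f"\ncell scores for gene {res.gene_names[g]}: "
          f"mean {cs.mean():.3f}, top-decile mean {np.quantile(cs, 0.9):.3f}")
    print("a positive mean says the observed values of this gene carry "
          "information about the response that synthetic nulls do not")
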