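"""Node-level permutation regression and Geary's C sampling-effort check.

First regresses strong-bond out-degree on the in-/out-degrees of each
gesture modality network plus individual controls (10,000 outcome
permutations), then asks whether observation effort is confounded with any
gesture network via Geary's C (null expectation 1.0; < 1 means tied
individuals have similar values).
"""
import pandas as pd

import gestnet as g
from gestnet.pipeline import build_matrices

ds = g.simulate_dataset(n=12, seed=1)
cfg = g.AnalysisConfig(master_seed=1, n_perm_node=10000)
mats = build_matrices(ds)

cent = g.run_centrality_analysis(ds, cfg, mats)
print("predictors of strong-bond out-degree (node-label permutation test):")
print(cent[["predictor", "beta", "p"]].round(3).to_string(index=False))
print(f"(r^2 = {cent.r_squared.iloc[0]:.3f}: with 12 predictors on 12 "
      "individuals the fit is saturated; inference rests on the permutations)")

print()
effort = g.run_sampling_effort_check(ds, cfg, mats)
print("observation hours vs gesture networks (Geary's C, null = 1.0):")
print(effort[["network", "geary_c", "p"]].round(3).to_string(index=False))
print("non-significant p-values indicate sampling effort does not drive "
      "the gesture networks.")
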