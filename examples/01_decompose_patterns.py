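"""Factor a multi-line differentiation study into transcriptomic patterns.

Simulates a study shaped like a six-line hPSC differentiation experiment
(3 conditions x 3 days), runs multi-restart consensus NMF at the planted
rank, and compares the recovered gene-amplitude matrix with the planted
modules.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from stempatterns import SimulationConfig, consensus_decompose, \
    simulate_study

study, truth = simulate_study(SimulationConfig(seed=1))
print(f"study: {study.n_genes} genes x {study.n_samples} samples, "
      f"{truth.k_true} planted modules "
      f"({truth.module_class.count('dynamic')} dynamic, "
      f"{truth.k_true - truth.module_class.count('dynamic')} line/donor)")

decomp = consensus_decompose(study, K=truth.k_true, n_restarts=30, seed=1)
print(f"consensus NMF: K={decomp.K}, per-pattern restart stability "
      f"{np.round(decomp.restart_stability, 2)}")

# match estimated patterns to planted modules by cosine similarity
A_est = decomp.A * decomp.row_scaling[:, None]
C = (truth.A_true.T @ A_est) / np.outer(
    np.linalg.norm(truth.A_true, axis=0), np.linalg.norm(A_est, axis=0))
rows, cols = linear_sum_assignment(-C)
print("matched cosine per module:", np.round(C[rows, cols], 3))
print(f"mean {C[rows, cols].mean():.3f} -- values near 1 mean the planted "
      "gene programs were recovered almost exactly.")
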