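"""How sampling structure flips the synergy/redundancy balance.

Draws from one mixture of 72 tight clusters on a constraint manifold in two
ways: 'unique' (one model per cluster, spanning the manifold) and
'oversampled' (36 models from each of two clusters). The same generative
process reads as synergy in one case and strong redundancy in the other.
"""

import numpy as np

from hoinfo.recipes import sampling_structure_experiment

result = sampling_structure_experiment(seed=0, n_replicates=20)

print("dominance = synergy AUC - redundancy AUC (positive -> synergy)")
print(f"unique draws     : median {np.median(result.unique_dominance):+.2f} "
      f"(range {result.unique_dominance.min():+.2f} "
      f"to {result.unique_dominance.max():+.2f})")
print(f"oversampled draws: median "
      f"{np.median(result.oversampled_dominance):+.2f} "
      f"(range {result.oversampled_dominance.min():+.2f} "
      f"to {result.oversampled_dominance.max():+.2f})")
print(f"rank-sum p-value : {result.p_value:.2e}")
print()
print("Equal sample sizes, same clusters: only the way models are drawn "
      "differs. Oversampling two tight clusters manufactures a shared "
      "discrete factor that reads as redundancy; spanning clusters "
      "preserves the manifold's synergy.")
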