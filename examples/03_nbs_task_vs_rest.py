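"""Network-based statistic on paired task/rest interaction matrices.

Plants a +3 sigma metastability increase on a triangle of network
connections in 40 paired subjects and shows the NBS recovering it as a
single family-wise-significant connected component, while a null
cohort yields nothing.
"""

import numpy as np

from metanet.cohort import synthetic_paired_stacks
from metanet.nbs import nbs_permutation

noise = 0.02
triangle = [(0, 1), (1, 2), (0, 2)]  # edges among networks 0, 1, 2
task, rest = synthetic_paired_stacks(
    n_subjects=40, effect_edges=triangle,
    effect_size=3 * np.sqrt(2) * noise, noise_sd=noise, seed=1,
)
res = nbs_permutation(task, rest, thr=3.0, n_perm=2000, seed=2, tail="increase")
print(f"planted effect: largest component {res.observed_size} edges "
      f"(triangle planted on {triangle}), FWER p = {res.p_value:.4f}")
print(f"  component edges: {res.components[0].edges}")

task0, rest0 = synthetic_paired_stacks(n_subjects=40, seed=3)
null = nbs_permutation(task0, rest0, thr=3.0, n_perm=2000, seed=4)
print(f"null cohort: largest component {null.observed_size} edges, "
      f"p = {null.p_value:.4f} (no family-wise significant increase)")
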