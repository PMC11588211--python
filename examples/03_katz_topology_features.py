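"""Katz-index spatial topology features.

The Katz matrix scores every spot pair by the attenuated count of all
connecting paths; compressing it by SVD gives each spot a fixed-width
topology feature used as the Es block of the fused input.
"""

import numpy as np

import sducl
from sducl.features import katz_matrix

# path of four spots: 0 - 1 - 2 - 3
A = np.diag(np.ones(3), 1)
A = A + A.T

km = katz_matrix(A, beta=0.1)
print("Katz index matrix (beta=0.1, closed form):")
print(np.array_str(km.K, precision=5, suppress_small=True))
# adjacent pairs score highest; the 0-3 pair is reached only through
# length-3 paths, so its score is beta^3-sized.

km_tr = katz_matrix(A, beta=0.1, l_max=8)
print("max |closed-form - truncated(l_max=8)|:",
      f"{np.abs(km.K - km_tr.K).max():.2e}")

g = sducl.build_knn_graph(np.random.default_rng(0).random((30, 2)), k=4)
_, Es = sducl.katz_features(g, beta=0.1, d_s=8)
print(f"topology features for 30 spots: shape {Es.shape}")
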