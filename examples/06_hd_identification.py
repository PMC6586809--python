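"""Hausdorff-distance model identification: can each synthetic tree be
matched to its own (perturbed) counterpart from another 'modality'?

Builds n trees and mildly perturbed copies, computes the full symmetric
Hausdorff distance matrix, and checks diagonal dominance — every row's
minimum should sit on the diagonal when the geometry carries enough
identity.
"""

import numpy as np

from coroflow.pipeline import run_hd_matrix

result = run_hd_matrix(n_trees=4, perturb_sd_mm=0.4, seed=0,
                       tree_scale=0.3, n_samples=2000)
hd = result["hd_matrix_mm"]
print("symmetric Hausdorff matrix (mm); rows = trees, cols = perturbed copies")
for row in hd:
    print("  " + "  ".join(f"{x:6.2f}" for x in row))
print(f"diagonal dominance: {result['diagonal_dominance']:.2f} "
      f"(1.0 = every tree matched to its own copy)")
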