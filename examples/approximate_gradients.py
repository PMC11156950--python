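"""Approximate connectivity gradients from landmarks and compare to the
full-matrix reference.

Builds a synthetic 600-vertex cortex with planted low-rank connectivity
structure, computes gradients from increasing landmark subsets and from the
full vertex-by-vertex matrix, and prints their per-gradient spatial
similarity.
"""

import numpy as np

import fcga

cortex = fcga.make_toy_cortex(20, 30)
gt = fcga.make_ground_truth(cortex, m=5, seed=0)
ts = fcga.simulate_timeseries(gt, T=400, seed=1)

full = fcga.full_gradients(ts, n_components=5, zero_variance="zero")

print("landmarks  storage   mean |spearman rho| vs full (5 gradients)")
for k in (30, 60, 120):
    landmarks = fcga.select_uniform_vertices(cortex.coords, k, seed=2)
    approx = fcga.fcga(ts, landmarks, n_components=5, zero_variance="zero")
    report = fcga.spearman_similarity(approx, full)
    ratio = fcga.cost_summary(cortex.n_vertices, k)["ratio"]
    print(f"  k={k:4d}    {ratio:5.0%}    {report.mean_rho:.3f}   "
          f"per-gradient {np.round(report.per_gradient_rho, 3)}")
# similarity to the full-matrix gradients rises with the landmark count
# while the affinity storage stays a small fraction of the n-by-n matrix
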