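"""Build multi-view morphological brain networks for one subject.

Generates a small synthetic cohort, constructs the per-view dissimilarity
networks for the first subject, and shows the lower-triangle feature vector
with its edge index map.
"""

import numpy as np

import morphnet as mn

cohort, _ = mn.generate(mn.default_recovery_scenario(seed=0))
atlas = mn.desikan_killiany()

tensor = mn.build_tensor(cohort, 0)
print(f"subject {tensor.subject_id}: {tensor.matrices.shape[0]} views, "
      f"each {tensor.matrices.shape[1]}x{tensor.matrices.shape[2]}")

# The thickness network: entry (i, j) = |mean thickness ROI i - ROI j|
thickness = tensor.matrices[1]
i, j = 34, 32  # 0-based insula (region 35) and temporal pole (region 33)
print(f"|thickness({atlas.name_of(35)}) - thickness({atlas.name_of(33)})| = "
      f"{thickness[i, j]:.3f} mm")

vec, index_map = mn.vectorize(thickness, view=2)
print(f"feature vector length {len(vec)} (= R(R-1)/2 for R=35)")
print(f"first entries map to (view, roi_i, roi_j): {index_map.entries[:3]}")

# Fusing the four views: concatenation keeps view provenance, averaging
# collapses to one vector of the same length as a single view.
vecs = [mn.vectorize(tensor.matrices[m])[0] for m in range(4)]
con, _ = mn.fuse_con(vecs, 35)
avg, _ = mn.fuse_avg(vecs, 35)
print(f"CON length {len(con)}, AVG length {len(avg)}")
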