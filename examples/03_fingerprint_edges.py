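"""Fingerprint edges: which connections encode brain age?

Averages each feature's RFE rank across the five cross-validation folds
into a relevance score, extracts the top-K edges, and writes a ranked edge
list with atlas-resolved ROI names (the input for circular-graph figures).
"""

import morphnet as mn

cohort, truth = mn.generate(mn.default_recovery_scenario(seed=0))
features = mn.cohort_features(cohort, "view2")
config = mn.PipelineConfig(
    rfe=mn.RFEConfig(scorer="rf", scorer_forest=mn.RFConfig(n_trees=50)),
    n_features=50,
    forest=mn.RFConfig(),
    seed=0,
)
result = mn.evaluate_cv(features, cohort.ages, config)
relevance = result.relevance()

atlas = mn.desikan_killiany()
top5 = mn.top_k_edges(relevance, 5)
print("top 5 fingerprint edges (lower relevance score = more predictive):")
for view, roi_i, roi_j, score, rank in top5:
    print(f"  #{rank}: view {view}  {atlas.name_of(roi_i)} ({roi_i}) -- "
          f"{atlas.name_of(roi_j)} ({roi_j})  score {score:.1f}")

planted = {(v, i, j) for v, i, j, _ in truth.planted_edges}
hits = sum((v, i, j) in planted for v, i, j, _, _ in top5)
print(f"{hits}/5 of these edges were actually planted with age signal.")

mn.write_edge_list(
    [(v, i, j, s) for v, i, j, s, _ in mn.top_k_edges(relevance, 15)],
    atlas,
    "edges_top15.csv",
    view_names=cohort.view_names,
)
print("wrote edges_top15.csv (view, ROI indices and names, score, rank)")
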