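"""Discover disease subtypes in the contrastive representation.

Hierarchical (Ward) clustering of the projected subjects with the cluster
count chosen by mean silhouette, compared against the planted subtype
assignment, plus pooled vs within-cluster progression prediction.
"""

from sklearn.metrics import adjusted_rand_score

import tcpca

pair, truth = tcpca.generate(tcpca.SyntheticSpec(seed=1))
basis = tcpca.fit_tcpca(pair, alpha_feature=2.0, alpha_time=2.0)
rep = tcpca.transform(basis, pair.target)

model = tcpca.fit_subtypes(rep, k_range=range(2, 11))
print("mean silhouette by cluster count:")
for k, s in model.silhouette_by_k.items():
    marker = "  <- selected" if k == model.n_clusters else ""
    print(f"  K={k:2d}: {s:.3f}{marker}")
print(f"adjusted Rand index vs planted subtypes: "
      f"{adjusted_rand_score(truth.subtypes, model.assignments):.3f}")

labels = tcpca.ProgressionLabelSet(truth.labels, horizon_years=1)
comp = tcpca.per_cluster_evaluation(rep, labels, model, "knn", n_runs=3, seed=0)
print(f"\npooled CV accuracy:         {comp['before']['accuracy']:.4f}")
print(f"within-cluster CV accuracy: {comp['after']['accuracy']:.4f}  (size-weighted)")
print("an ARI of 1.0 means the silhouette-selected clusters match the planted")
print("subtypes exactly; the pooled/within comparison mirrors the protocol of")
print("training identical classifiers before and after clustering")
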