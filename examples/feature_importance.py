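"""Gini importance profiling: which features drive the labels, and when.

Plants a label signal in one (visit, feature) cell of a generated cohort,
fits a random forest per visit, and accumulates per-split impurity changes
(GI_parent - GI_left - GI_right) into normalized per-feature scores. The
profile should concentrate on the planted cell, and the representative-
feature rule (score strictly above 0.02) should put the planted feature first.
"""

import numpy as np
from sklearn.ensemble import RandomForestClassifier

import tcpca

pair, _ = tcpca.generate(tcpca.SyntheticSpec(seed=3))
visit, feature = 3, 7
labels = (pair.target.values[:, visit, feature] > 0).astype(int)

profile = tcpca.longitudinal_importance(
    pair.target, labels, {"n_estimators": 150}, seed=0
)
print("per-visit importance of the planted feature (row-normalized):")
for t, row in enumerate(profile.matrix):
    flag = "  <- planted visit" if t == visit else ""
    print(f"  visit {t}: score {row[feature]:+.3f}, argmax feature "
          f"{int(np.argmax(row)):2d}{flag}")

forest = RandomForestClassifier(n_estimators=300, random_state=0).fit(
    pair.target.values[:, visit, :], labels
)
imp = tcpca.forest_gini_importance(forest, pair.target.n_features)
top = tcpca.representative_features(imp)  # strictly above 0.02
print(f"\nrepresentative features at visit {visit} (threshold 0.02):")
for name, score in top[:5]:
    print(f"  feature {name}: {score:.3f}")
print("the planted feature should dominate its visit's row and lead the")
print("representative list; other visits spread importance over noise")
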