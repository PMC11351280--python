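"""Fit a tensorized contrastive basis and inspect what it isolates.

Generates a target (disease) and background (never-diseased) cohort that
share a dominant "natural aging" variance structure, then fits the bilinear
contrastive decomposition at alpha = 0 (plain two-sided PCA) and at a strong
contrast. The cosines show that plain PCA locks onto the shared aging axis
while the contrastive fit recovers the disease-specific axis instead.
"""

import numpy as np

import tcpca

pair, truth = tcpca.generate(tcpca.SyntheticSpec(seed=1))

plain = tcpca.fit_tcpca(pair, alpha_feature=0.0, alpha_time=0.0, m_feature=1, m_time=1)
contrast = tcpca.fit_tcpca(pair, alpha_feature=50.0, alpha_time=50.0, m_feature=1, m_time=1)

cos = lambda a, b: abs(float(a @ b))
print("top feature direction at alpha=0:")
print(f"  |cos| with planted aging axis:   {cos(plain.feature_basis[:, 0], truth.aging_feature_axes[:, 0]):.3f}")
print(f"  |cos| with planted disease axis: {cos(plain.feature_basis[:, 0], truth.disease_feature_axes[:, 0]):.3f}")
print("top feature direction at alpha=50:")
print(f"  |cos| with planted aging axis:   {cos(contrast.feature_basis[:, 0], truth.aging_feature_axes[:, 0]):.3f}")
print(f"  |cos| with planted disease axis: {cos(contrast.feature_basis[:, 0], truth.disease_feature_axes[:, 0]):.3f}")

rep = tcpca.transform(contrast, pair.target)
print(f"\nprojected representation: {rep.matrices.shape[0]} subjects x "
      f"{rep.matrices.shape[1]} time x {rep.matrices.shape[2]} feature components")
print("a cosine near 1 means the fitted direction coincides with the planted axis;")
print("raising alpha moves the top direction from aging onto disease structure")
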