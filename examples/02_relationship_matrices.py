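"""Pedigree relationship machinery: A, A^-1, inbreeding, A*, A(Gamma).

Builds the classical matrices on a toy pedigree: two unrelated founders
with unknown parents assigned to one unknown-parent group, their offspring,
and a metafounder version with a self-relationship of 0.2.
"""

import numpy as np

from mfblup import (GammaMatrix, Pedigree, build_A, build_Agamma,
                    build_A_inverse, build_Q, build_QP_Astar,
                    compute_inbreeding)

# trio: founders 0 and 1, offspring 2
ped = Pedigree(np.array([-1, -1, 0]), np.array([-1, -1, 1]))

print("A (tabular):")
print(build_A(ped))
print("\nA^-1 (Henderson rules)  — the classical trio matrix:")
print(build_A_inverse(ped).toarray())
print("\ninbreeding:", compute_inbreeding(ped))

# QP transformation: founders' unknown parents all in group 1
sg = np.array([0, 0, -1])
dg = np.array([0, 0, -1])
print("\nQ (expected group contribution per animal):")
print(build_Q(ped, sg, dg, 1).values)
print("\nA* (QP-transformed, group column appended):")
print(build_QP_Astar(ped, sg, dg, 1).toarray())

# metafounders: the same group as a pseudo-animal with gamma = 0.2
gamma = GammaMatrix(np.array([[0.2]]), labels=["base"])
mf = build_Agamma(ped, gamma, sg, dg)
print("\nA(Gamma) with gamma = 0.2 (metafounder last):")
print(np.round(mf.A, 3))
print("\nFounder diagonal is 1 + gamma/2 = 1.1 and the founders are now "
      "related by gamma = 0.2; with gamma = 0 this is exactly the "
      "unrelated-founder A.")
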