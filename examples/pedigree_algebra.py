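"""Relationship-matrix algebra on a toy pedigree.

Builds a five-animal pedigree with a full-sib mating, prints the dense
numerator relationship matrix A, the inbreeding coefficients, and the
sparse inverse assembled by Henderson's rules.
"""

import numpy as np

from tdgibbs import PedigreeEntry, a_inverse, inbreeding_coefficients, relationship_matrix

ped = [
    PedigreeEntry("sire"),
    PedigreeEntry("dam"),
    PedigreeEntry("son", "sire", "dam"),
    PedigreeEntry("daughter", "sire", "dam"),
    PedigreeEntry("inbred", "son", "daughter"),  # full-sib mating
]

A = relationship_matrix(ped)
F = inbreeding_coefficients(ped)
rel = a_inverse(ped)

np.set_printoptions(precision=3, suppress=True)
print("A =\n", A)
print("inbreeding:", dict(zip([e.animal for e in ped], F)))
print("A^-1 nonzeros:", rel.a_inv.nnz, "of", len(ped) ** 2)
print("A^-1 @ A ~ I:", np.allclose(rel.a_inv.toarray() @ A[np.ix_(
    [[e.animal for e in ped].index(a) for a in rel.ids],
    [[e.animal for e in ped].index(a) for a in rel.ids])], np.eye(5)))
# The full-sib offspring has F = 0.25: its parents share both parents, so a
# quarter of its genome is expected to be identical by descent.
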