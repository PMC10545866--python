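"""Weighted k-nearest-neighbour densification of a toy association matrix.

Three drugs, two diseases: r1 treats d1, r2 treats d2, and r3 is a novel
drug with no known indication.  WKNN gives r3 a soft profile from its
similar known neighbours, so the downstream tensor solver has something
to work with.
"""

import numpy as np

from tensordr import AssociationMatrix, SimilarityMatrix, wknn_update

a = AssociationMatrix(
    np.array([[1.0, 0.0, 0.0],
              [0.0, 1.0, 0.0]]),
    disease_ids=("d1", "d2"),
    drug_ids=("r1", "r2", "r3"),
)
sim = SimilarityMatrix(
    np.array([[1.0, 0.5, 0.8],
              [0.5, 1.0, 0.4],
              [0.8, 0.4, 1.0]]),
    ids=("r1", "r2", "r3"),
)

out = wknn_update(a, sim, k=2, alpha=0.95, axis="drugs")
print("original profile of r3 :", a.values[:, 2])
print("densified profile of r3:", np.round(out.values[:, 2], 4))
# r3 inherits (0.8*[1,0] + 0.95*0.4*[0,1]) / (0.8+0.4) = [0.6667, 0.3167]:
# mostly d1 (via its strong 0.8 neighbour r1), a little d2 (via r2, whose
# contribution is discounted both by lower similarity and the 0.95 decay).
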