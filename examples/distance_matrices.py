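"""Kullback-Leibler class-separation matrices, full and simplified.

Shows, for one DINA item, how the KL divergence between class-conditional
response distributions measures the item's power to separate latent
classes, and how the simplified pair set keeps only nearest-neighbour
(Hamming-distance-1) pattern pairs.
"""

import numpy as np

from cdta import (
    ItemParameters,
    QMatrix,
    class_probability_table,
    enumerate_latent_classes,
    full_pairs,
    item_distance_matrix,
    kl_distance,
    minimal_pairs,
)

space = enumerate_latent_classes(3)
q = QMatrix([[1, 1, 0]])  # one item measuring attributes 1 and 2
params = ItemParameters(model="DINA", slip=[0.1], guess=[0.2])
table = class_probability_table(q, params, space)

print("class probabilities for item q=(1,1,0), s=0.1, g=0.2:")
for bits, p in zip(space.bitstrings(), table.probs[:, 0]):
    print(f"  alpha={bits}  P(correct)={p:.1f}")

print(f"\nKL is asymmetric: D(0.9||0.2)={kl_distance(0.9, 0.2):.6f}, "
      f"D(0.2||0.9)={kl_distance(0.2, 0.9):.6f}")

D = item_distance_matrix(table.probs[:, 0])
print(f"\n8x8 distance matrix: {np.count_nonzero(D)} nonzero entries "
      "(pairs this item can separate), zero diagonal")

print(f"full pair set: {full_pairs(space).R} ordered pairs; "
      f"simplified (Hamming distance 1): {minimal_pairs(space).R} pairs")
print("The simplified set keeps the hardest pairs - patterns differing in "
      "one attribute - shrinking the assembly program 2.3-fold at K=3 and "
      "32-fold at K=8.")
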