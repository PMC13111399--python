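"""Rough-neutrosophic six-component encoding of selected features.

Encodes a tiny scaled table: each value x in [0, 1] becomes a
truth/indeterminacy/falsity triple, then granule-wise pessimistic (lower)
and optimistic (upper) summaries give six columns per feature.
"""

import numpy as np

from roughns import TabularDataset, rns_transform_table

X = np.array([[0.0], [0.1], [0.9], [1.0]])
data = TabularDataset(["bp"], X, np.array([0, 0, 1, 1]))

rns = rns_transform_table(data, ["bp"], bins=2)
print("columns:", rns.column_names)
for i, row in enumerate(rns.matrix):
    print(f"object {i} (x={X[i,0]:.1f}):", np.round(row, 3))

# With two quantile granules {0, 0.1} and {0.9, 1.0}: T_low is the most
# cautious membership in the granule (min), F_low the most cautious
# non-membership (max); the upper row is the optimistic counterpart.
# Width is 6 x number of encoded features by construction.
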