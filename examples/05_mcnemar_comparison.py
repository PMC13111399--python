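"""Paired comparison of two classifiers with McNemar's test.

Only the discordant predictions matter: b counts samples A gets right and
B wrong, c the reverse.  Small discordant totals switch to the exact
binomial branch automatically.
"""

import numpy as np

from roughns import mcnemar_test

rng = np.random.default_rng(0)
n = 300
y = rng.integers(0, 2, n)

# classifier A is right 92% of the time, B 85%, errors partly overlapping
a_pred = np.where(rng.uniform(size=n) < 0.92, y, 1 - y)
b_pred = np.where(rng.uniform(size=n) < 0.85, y, 1 - y)

res = mcnemar_test(y, a_pred, b_pred, correction=True)
print(f"b (A right, B wrong) = {res.b},  c (A wrong, B right) = {res.c}")
print(f"chi2 = {res.chi2:.4f}  p = {res.p_value:.4g}  exact branch: {res.exact}")

# p below the chosen level means the two classifiers' error patterns
# differ beyond what random disagreement on the same test set explains.
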