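"""Ranking candidate models over several metrics with MEREC + TOPSIS.

Weights come from MEREC (the effect of removing each metric on a
logarithmic performance score); TOPSIS then ranks models by closeness to
the per-metric ideal profile.
"""

import numpy as np

from roughns import DecisionMatrixMCDM, merec_weights, topsis_rank

models = ["forest", "boosting", "knn", "naive_bayes"]
metrics = ["accuracy", "precision", "recall", "f1", "auc"]
performance = np.array([
    [0.985, 1.000, 0.971, 0.985, 0.998],
    [0.979, 0.990, 0.968, 0.979, 0.997],
    [0.862, 0.870, 0.850, 0.860, 0.910],
    [0.823, 0.830, 0.815, 0.822, 0.885],
])

dm = DecisionMatrixMCDM(models, metrics, performance)
dm.weights = merec_weights(dm)
print("MEREC weights:", dict(zip(metrics, np.round(dm.weights, 4))))

closeness, order = topsis_rank(dm)
for pos, idx in enumerate(order, start=1):
    print(f"{pos}. {models[idx]:12s} closeness = {closeness[idx]:.4f}")

# Closeness 1 would mean the model sits at the ideal on every weighted
# metric, 0 at the anti-ideal; the ranking is the final model choice.
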