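# Methods

This note records the model assumptions, the parameter choices that
matter, the numerical conventions, and what the synthetic benchmarks do
and do not demonstrate.

## Decision tables and attribute reduction

A decision table holds discretized predictor symbols plus a class label
per object.  Continuous columns are binned with train-derived cut points
(quantile by default, equal-width optionally; a column with no more
distinct values than bins passes through as codes).  The dependency
degree γ(S) is the fraction of objects lying in blocks of the
S-indiscernibility partition that are pure in the label; γ = 1 means S
determines the label.

Selection is a greedy cover of the discernibility matrix: for every
object pair with different labels the matrix stores the attributes
separating them, and each step takes the attribute present in the most
still-uncovered entries (ties broken by lowest column index, which makes
the output a pure function of the table).  Two classes of pairs are
excluded from the cover's targets because separating them cannot change
γ: pairs with identical attribute rows (no attribute set can separate
them) and, more generally, pairs whose two objects both lie outside the
positive region of the full attribute set.  Both kinds are still recorded
on the matrix object.  With this restriction, hitting every remaining
("effective") entry is provably equivalent to preserving γ.

An optional backward pass (on by default in the pipeline) re-tests each
selected attribute in reverse selection order and drops it if γ is
unchanged.  Because γ is monotone in the attribute set, the surviving
selection is irreducible — it is itself an inclusion-minimal reduct, a
fact the tests check against a brute-force enumerator of all
inclusion-minimal γ-preserving subsets (guarded to ≤ 12 attributes).

**Known limitation.**  Greedy cover carries no minimum-cardinality
guarantee: on small random tables the selection is an inclusion-minimal
reduct in every observed instance, but in roughly 2–5% of instances a
*smaller* reduct exists that is disjoint from the greedy pick, so no
pruning of the greedy output can reach it.  Applications that need the
global minimum at small attribute counts should use the exhaustive
enumerator directly.

## Scaling conventions

Two scalers are provided, both fitted on training rows only.  Z-score
uses the population standard deviation (divide by n); constant features
are an error under z-score because their deviation is zero.  Min-max
maps to [0, 1] and clips out-of-range test values, keeping the
neutrosophic components well defined; a feature that was constant during
fitting maps to 0.5, the point of maximal indeterminacy, since its value
carries no ordering information.  The neutrosophic stage requires [0, 1],
so the pipeline uses min-max; z-score remains available for raw-feature
baselines.

## Rough-neutrosophic encoding

The membership mapping T = x, I = 1 − |2x − 1|, F = 1 − x is the package
default: it honours the boundary semantics (full membership at 1, full
non-membership at 0, peak indeterminacy mid-range) and is a pluggable
injection point — any map [0, 1] → [0, 1]³ can be substituted.  No
T + I + F = 1 constraint is imposed; the three degrees are independent.

Granulation defaults to the indiscernibility partition of the discretized
selected attributes jointly, matching the selection stage; per-feature
quantile granules are available.  The lower summary takes min T / max I /
max F over the granule, the upper max T / min I / min F, which yields the
ordering invariants T_low ≤ T_up, I_low ≥ I_up, F_low ≥ F_up and the
refinement property that both summaries converge to the point triple as
the partition refines.  Columns are feature-major in the fixed order
(T_low, I_low, F_low, T_up, I_up, F_up), so the network can reshape the
6k matrix into (k channels × 6 positions) without bookkeeping.

At prediction time a new object joins the granule matching its
discretized signature; its own triple is folded into the stored summary
(min/max as appropriate), and an unseen signature falls back to a
singleton granule (lower = upper = point triple).

## The dual-attention extractor

Input layout: channels = selected features (C = k), positions = the six
encoding components (L = 6).  This gives the average pooling a meaningful
axis and lets the soft-attention block relate the uncertainty components
of different features.

* Channel attention: per-channel mean over L, a bottleneck gate
  W₂·relu(W₁·s) with reduction ratio 2 (floor width 1), sigmoid output
  g ∈ (0,1)^C, and output x·g + x.  The residual makes the zero-parameter
  block exactly x ↦ 1.5x, which the tests pin down.
* Soft attention: single head, shared projections of each position's
  C-vector into Q, K, V; scores QKᵀ/√C; row-softmax; output A·V.  No
  positional encoding, so the block is permutation-equivariant over
  positions — also pinned by tests.
* Composition order is channel-then-soft attention: the gate stabilises
  channel scales before position mixing; the ablation switch
  (`attention_variant`) exposes none / cam / sam / cam_sam.
* Head: dense layer of width `hidden_expansion × 6k` with ReLU, a linear
  embedding layer (default 16 dimensions), and a softmax classification
  head.  After training, the embeddings (head bypassed) feed a random
  forest; a forest on learned embeddings is more robust at small n than
  the softmax head alone.

Training uses Adam (β = 0.9/0.999, ε = 1e-8), mean cross-entropy plus L2
weight decay on the weight matrices, default learning rate 1e-3, batch
size 32, 50 epochs, and a stratified 20% validation split for the
learning curves.  Everything — initialisation (Glorot uniform), batch
shuffling, the validation split — derives from one seed, and all kernels
are plain NumPy, so training is bit-reproducible and single-threaded.
Gradients for every block are hand-derived and verified against central
finite differences in the test suite.  Non-finite loss aborts with a
diagnostic rather than continuing.

Hyperparameter search is a seeded random search sampling jointly from
the network ranges (learning rate log-uniform 1e-5–1e-1, batch 16–128,
weight decay log-uniform 1e-6–1e-2, hidden expansion {2, 4}) and the
forest ranges (trees 50–300, depth 5–30, min split 2–10).  The objective
is inner-validation accuracy of the full extractor → forest pipeline
computed only on the data handed to the tuner, which in the pipeline is
always the training partition — the tuner never sees test indices.

## Evaluation

Binary metrics use the plain confusion-count formulas; multiclass uses a
support-weighted one-vs-rest average (cross-checked against
scikit-learn).  Zero denominators resolve to 0 with a warning so reports
stay total.  McNemar's statistic is (|b−c|−1)²/(b+c) with continuity
correction (default) or (b−c)²/(b+c) without; the p-value switches to
the exact two-sided binomial when b + c < 25, and b + c = 0 returns
χ² = 0, p = 1 with an `undefined` flag.  MEREC keeps the original
criterion count in the removal score's denominator so that a criterion
with h ≡ 1 has exactly zero effect; identical alternatives fall back to
uniform weights.  TOPSIS vector-normalises columns, weights them, and
ranks by closeness D⁻/(D⁺+D⁻); ties keep input order with a warning, and
an alternative equal to both ideal and anti-ideal is assigned 0.5.
Cross-validation fits every component — scaler, cut points, reduct,
granules, network, forest — inside each fold and rejects pre-fitted
pipelines.

## Synthetic benchmarks: what they show

The generator plants informative features whose bin codes determine the
label through a parity rule, so the informative set is the unique
minimal reduct up to exchange with its exact monotone copies; noise
features are label-independent; label flips are optional.  Bin
occupancies are balanced and values keep an 8% margin from bin edges,
creating a genuine density gap at every bin boundary.  Equal-width cuts
land in that gap for any subset of rows, so discretization recovers the
planted symbols exactly even when refitted inside folds; quantile cuts
are rank-based and recover the symbols only when fitted and applied on
the same balanced rows — a single mis-binned object contaminates its
whole granule, which is why the recovery harnesses use equal-width.
Quantile remains the default for real data, where skewed marginals are
the more common hazard, and the bin count/strategy pair is the main
reproducibility lever for selection results on real tables.

Study conditions used by the tests and the acceptance script: n = 500,
two informative features, five noise features, no label noise for the
recovery pincer (held-out accuracy ≥ 0.95 on planted signal, within
±0.1 of chance on label-shuffled controls); 100–120 random tables of at
most 8 attributes and 30 objects for the oracle comparisons; 1,000
random partitions for the approximation and ordering invariants; and a
5-trial search for the tuning checks.  These sizes complete in seconds
while leaving the statistical conclusions unambiguous.

What passing these benchmarks does **not** show: robustness to skewed or
heavy-tailed marginals (the generator's bins are uniform), to correlated
noise features, to class imbalance, or to label noise interacting with
granule contamination; and real clinical tables may be inconsistent
(identical records with different outcomes), where γ < 1 and selection
quality depends on the discretization choice far more than on the cover
heuristic.
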