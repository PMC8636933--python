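# Methods

This note documents the modeling choices behind `carcstack`: the stacked
architecture, its tunable parameters, the synthetic data the tests rely on,
and the numerical conventions adopted where the design was genuinely open.

## Model

The classifier is a two-level stack. Level one trains populations of five
classical learners (KNN, logistic regression, SVM with RBF kernel, random
forest, XGBoost) on random 80% subsamples (without replacement by default;
`replace=True` gives classic bootstrap sampling) of the training set. Each
member records its Matthews correlation coefficient (MCC) on the **full**
training set and on the development set; out-of-bag scoring is deliberately
not the default, because the selection rules below are defined against
full-set performance. KNN, LR and SVM see standardized inputs (fitted on
each member's subsample); tree ensembles use raw descriptors. SVM
probabilities come from cross-validated Platt scaling; all other algorithms
expose native probabilities. The probability source is recorded per member.

Hyperparameters are chosen per algorithm by bagging: every grid combination
trains `n_search_models` members (default 100) and the combination with the
highest mean development-set MCC wins, first-in-grid-order on ties. The
shipped grids are compact sweeps around each algorithm's usual operating
range and can be replaced wholesale via `HyperparameterGrid`.

Two selection rules thin the final population (default 1,000 members per
algorithm):

* **original** — keep members whose dev MCC lies inside the inclusive
  [P5, P95] band. Percentiles use linear interpolation between order
  statistics (numpy's default), under which 100 distinct values keep
  exactly 90 members and 10 distinct values keep 8. The convention is
  recorded in the selection metadata.
* **supervised** — keep members strictly above the population mean MCC on
  both the training and the development set. Strict inequality means a
  population of identical members selects nothing — the degenerate case
  raises rather than silently passing everything through.

The survivors' positive-class probabilities on the development set form the
meta-classifier's training matrix: one row per compound, one column per
selected member.

The meta-classifier is a three-layer network: dense (10 units, no bias) →
batch normalization → ReLU → inverted dropout (rate 0.5) → dense → sigmoid,
trained with mini-batch SGD (momentum 0.9) on binary cross-entropy. It is
implemented directly in NumPy — at 10 hidden units the network is small
enough that owning the forward/backward pass buys exact, bit-reproducible
training under a single seed, and keeps inference trivially deterministic
(running batch-norm moments, no dropout sampling at predict time). The
layer order (dense → BN → ReLU → dropout) is the conventional one; training
hyperparameters (epochs 200, batch 32, learning rate 0.01, momentum 0.9,
early stopping on training loss with patience 20 and best-weight restore)
are defaults recorded in `MetaNetworkConfig`, not canonical values. Batches
of a single sample are skipped when batch norm is active, since batch
statistics are undefined there.

Training the meta network on the development set and also reporting its
development-set MCC means that number is partly in-sample — this mirrors
the stack's design (the meta-classifier exists to recombine dev-set
behavior) and is why an independent test set is carved out for the honest
generalization estimate.

## Descriptors and preprocessing

MACCS fingerprints use RDKit's 167-bit layout with the dummy bit 0 dropped,
giving exactly the 166 structural keys; the convention is stored in the
matrix metadata. SMILES are parsed (hence canonicalized) before
fingerprinting, so kekulized and aromatic spellings agree. Mol2vec-style
embedding assigns each molecule the sum of its Morgan substructure
identifiers' vectors (radii 0–1, occurrences counted with multiplicity);
out-of-vocabulary identifiers fall back to a reserved `UNK` vector when the
table provides one, else the zero vector. Mold2 and pretrained Mol2vec
tables are ingested as CSV, never recomputed.

Preprocessing drops zero-variance columns, then scans columns left to
right and drops any column whose Pearson correlation with an earlier
*retained* column exceeds 0.9. Absolute correlation is the default —
anti-correlated descriptors are equally redundant — with signed comparison
available via `absolute=False`. Strictly-greater comparison at the
threshold, deterministic keep-first order, and both choices are recorded in
the output metadata alongside the dropped-feature report. The two-step
pipeline is idempotent.

## Similarity analysis

Within-class discrimination power is quantified by the Tanimoto coefficient
over all unordered within-class pairs: the bit-count form `c/(a+b−c)` for
fingerprints, the continuous generalization `x·y/(‖x‖²+‖y‖²−x·y)` (range
[−1/3, 1]) for embeddings and physicochemical descriptors. The two forms
coincide on 0/1 vectors, which the tests verify exhaustively on all 4-bit
pairs. Pairs of all-zero vectors are 0/0 in both forms; the package defines
them as 0.0 with a warning — "no evidence of similarity" is the
conservative reading. Summaries default to preprocessed descriptors
(similarity should reflect the feature space the models see); raw matrices
can be passed just as well.

## Kennard–Stone split

Euclidean distance on the preprocessed descriptor matrix; the first two
picks are the maximally distant pair (lower original index emitted first),
each later pick maximizes its minimum distance to the selected set, ties
broken by lowest original index. The three-way split is sequential: KS
selects the training set from the full pool, a second KS pass over the
remainder selects the development set, the residue is the test set. The
procedure contains no randomness. Continuous-embedding space is the natural
default for splitting; any `DescriptorMatrix` is accepted.

## Evaluation conventions

All six metrics derive from confusion counts with `prob ≥ threshold`
called positive (consistent with the average-probability ensemble rule
that `< 0.5` means non-carcinogen). Degenerate MCC denominators return 0.0
with a warning; an undefined PPV/NPV side returns NaN with a warning. AUC
is the rank statistic (ties at 1/2), delegated to scikit-learn and
cross-checked in the tests against exhaustive concordant-pair counting.
The threshold-prioritization table uses Pearson's chi-square without
continuity correction (df = 1) on the predicted-vs-actual 2×2 table; the
Yates-corrected variant is a flag. Chi-square p-values are reported for
ranking, not inference — with margins this small the exact test flavor
matters, so downstream decisions should rest on PPV/NPV. Report output is
rounded to 3 decimals; full precision is kept on the objects.

Two conventional ensemble baselines are provided for comparison: majority
vote (exact tie → positive) and average probability (mean ≥ 0.5 →
positive).

## Screening

"Organometallic" means any atom outside {H, B, C, N, O, F, Si, P, S, Cl,
Se, Br, I}; "heavy" means molecular weight above 1000 Da. Both criteria
are configurable — the admissibility notion they encode (inside the
descriptor sets' applicability domain) has no single canonical definition.
Overlap with the modeling set is detected by InChIKey. Probability bins are
[0, 0.1), …, [0.9, 1.0] (last bin closed); risk and high-concern tallies
use inclusive cutoffs at 0.5 and 0.9.

## Synthetic data

The generator emulates the shape of a curated rodent-bioassay dataset —
863 compounds, 65% carcinogens (so exactly 561/302 at the default
fraction) — with two blocks: MACCS-like Bernoulli bits (base rate 0.3) and
Mol2vec-like standard-normal features. `effect_size` is the informative-bit
probability gap and, simultaneously, the informative continuous features'
class mean shift in sd units; `effect_size=0` is an exact null. What the
generator does **not** emulate: real chemical correlation structure,
scaffold clustering, activity cliffs, or any structure–label causality.
Passing tests therefore demonstrate that the machinery is correct and that
stacking adds skill when complementary signal exists — not that any
particular real-world accuracy will be reached.

## Problem sizes in the test and acceptance runs

The stacking property is exercised at the full 863-compound scale with 50
continuous features (20 informative, effect 0.5), 5 algorithms × 20
members per population, fixed mid-grid hyperparameters, over 10 seeds —
about 10 s per seed on one CPU. Population sizes of 100/1,000 and the full
bagged grid search remain the defaults for real use; the smaller
populations in the automated runs exercise identical code paths, and the
selection rules are additionally verified against brute-force oracles on
populations up to 1,000.

## Known limitations

* The meta network's development-set performance is partly in-sample (see
  above); use the test split for generalization claims.
* KS splitting is O(n²) in memory (full distance matrix) — fine to ~10⁴
  compounds, not designed for full-library scale.
* Probability calibration of the meta output is not addressed; binned
  screening reports ordinal concern, not calibrated risk.
* The supervised selection rule can legitimately select zero members of an
  algorithm whose population is homogeneous; only an empty selection across
  **all** algorithms is an error.
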