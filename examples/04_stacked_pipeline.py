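"""The full stacked ensemble on synthetic data, at a small scale.

Trains base-classifier populations for each algorithm, applies the
supervised (dual above-mean MCC) selection, trains the neural
meta-classifier on the development-set probability vectors, and evaluates.
Takes ~10 s on one CPU.
"""

import numpy as np

import carcstack as cs

spec = cs.SyntheticSpec(n_compounds=300, n_continuous_features=30,
                        n_informative=15, effect_size=0.8, seed=5)
_, cmat, labels = cs.generate_synthetic(spec)
pre = cs.preprocess(cmat)
split = cs.three_way_split(pre, (180, 60, 60))
lab = dict(zip(pre.compound_ids, labels))
sub = {name: (pre.subset_rows(ids), np.array([lab[c] for c in ids], int))
       for name, ids in (("train", split.train_ids), ("dev", split.dev_ids),
                         ("test", split.test_ids))}

result = cs.run_stack(
    sub["train"][0], sub["train"][1], sub["dev"][0], sub["dev"][1],
    sub["test"][0], sub["test"][1],
    n_population_models=15, search_hyperparameters=False, seed=5,
)

print("selected members per algorithm:", result.ensemble.per_algorithm_counts)
print(f"mean base dev MCC:  {result.base_mcc_dev_mean:.3f}")
print(f"meta dev MCC:       {result.meta_dev_mcc:.3f}")
print(f"meta test MCC:      {result.metrics['test']['mcc']:.3f}")
print(f"meta test AUC:      {result.metrics['test']['auc']:.3f}")
# The meta-classifier combines complementary base members, so its dev MCC
# should exceed the mean dev MCC of the members it was built from.
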