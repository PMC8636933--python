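"""Kennard-Stone three-way split on a synthetic descriptor matrix.

KS picks maximally spread compounds first, so each subset covers descriptor
space instead of sampling it at random; the split is fully deterministic.
"""

import carcstack as cs

spec = cs.SyntheticSpec(n_compounds=100, n_continuous_features=10,
                        n_informative=5, seed=0)
_, cmat, labels = cs.generate_synthetic(spec)

split = cs.three_way_split(cmat, (60, 20, 20))
print(f"train {len(split.train_ids)}, dev {len(split.dev_ids)}, "
      f"test {len(split.test_ids)}")
print("first training picks:", split.train_ids[:5])
# The first two picks are the most distant compound pair; every later pick
# maximizes its minimum distance to everything already selected.
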