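import numpy as np
import pytest

import carcstack as cs


@pytest.fixture(scope="session")
def small_split():
    """Small preprocessed synthetic dataset split train/dev, reused session-wide."""
    spec = cs.SyntheticSpec(
        n_compounds=240, positive_fraction=0.6, n_binary_features=40,
        n_continuous_features=30, n_informative=10, effect_size=1.0, seed=42,
    )
    _, cmat, labels = cs.generate_synthetic(spec)
    pre = cs.preprocess(cmat)
    split = cs.three_way_split(pre, (150, 50, 40))
    lab = dict(zip(pre.compound_ids, labels))

    def subset(ids):
        return pre.subset_rows(ids), np.array([lab[c] for c in ids], dtype=int)

    return {
        "train": subset(split.train_ids),
        "dev": subset(split.dev_ids),
        "test": subset(split.test_ids),
    }


@pytest.fixture(scope="session")
def tiny_populations(small_split):
    """Per-algorithm base populations at small n_models, shared by selection
    and representation tests."""
    (tr, trl), (dv, dvl) = small_split["train"], small_split["dev"]
    pops = {}
    for algo, combo in (("KNN", {"n_neighbors": 5}), ("LR", {"C": 1.0})):
        pops[algo] = cs.train_base_population(
            algo, combo, tr, trl, dv, dvl, n_models=12, seed=7,
        )
    return pops
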