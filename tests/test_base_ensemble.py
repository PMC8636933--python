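import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import carcstack as cs
from carcstack.base_ensemble import TrainedBaseClassifier


def _fake_population(algo, mcc_train, mcc_dev):
    return [
        TrainedBaseClassifier(algo, {}, i, [], None, float(t), float(d))
        for i, (t, d) in enumerate(zip(mcc_train, mcc_dev))
    ]


class TestGrid:
    def test_combinations_are_crossed(self):
        g = cs.HyperparameterGrid("KNN", {"n_neighbors": [1, 3], "weights": ["uniform"]})
        assert g.combinations() == [
            {"n_neighbors": 1, "weights": "uniform"},
            {"n_neighbors": 3, "weights": "uniform"},
        ]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            cs.HyperparameterGrid("LR", {"C": []})

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            cs.HyperparameterGrid("MLP", {"x": [1]})


class TestTrainPopulation:
    def test_single_model_fields_populated(self, small_split):
        (tr, trl), (dv, dvl) = small_split["train"], small_split["dev"]
        pop = cs.train_base_population("LR", {"C": 1.0}, tr, trl, dv, dvl,
                                       n_models=1, seed=0)
        assert len(pop) == 1
        m = pop[0]
        assert -1 <= m.mcc_train <= 1 and -1 <= m.mcc_dev <= 1
        assert len(m.subsample_ids) == round(0.8 * tr.n_compounds)

    def test_seeded_rerun_is_identical(self, small_split):
        (tr, trl), (dv, dvl) = small_split["train"], small_split["dev"]
        kw = dict(n_models=4, seed=11)
        a = cs.train_base_population("RF", {"n_estimators": 20}, tr, trl, dv, dvl, **kw)
        b = cs.train_base_population("RF", {"n_estimators": 20}, tr, trl, dv, dvl, **kw)
        assert [m.mcc_dev for m in a] == [m.mcc_dev for m in b]
        assert [m.subsample_ids for m in a] == [m.subsample_ids for m in b]

    def test_subsample_sizes(self, tiny_populations):
        for pop in tiny_populations.values():
            for m in pop:
                assert len(m.subsample_ids) == round(0.8 * 150)

    def test_overlapping_sets_rejected(self, small_split):
        (tr, trl), _ = small_split["train"], small_split["dev"]
        with pytest.raises(ValueError, match="overlap"):
            cs.train_base_population("LR", {}, tr, trl, tr, trl, n_models=1)


class TestHyperparameterSearch:
    def test_single_combination_returned(self, small_split):
        (tr, trl), (dv, dvl) = small_split["train"], small_split["dev"]
        grid = cs.HyperparameterGrid("KNN", {"n_neighbors": [5]})
        best, table = cs.bootstrap_hyperparameter_search(
            "KNN", grid, tr, trl, dv, dvl, n_models=3, seed=0)
        assert best == {"n_neighbors": 5}
        assert len(table) == 1

    def test_underfit_arm_loses_on_separable_data(self):
        """On strongly separable data k=1 is perfect, while k spanning nearly
        the whole 120-row subsample degenerates to a majority vote."""
        spec = cs.SyntheticSpec(n_compounds=250, positive_fraction=0.5,
                                n_continuous_features=10, n_informative=10,
                                effect_size=3.0, seed=2)
        _, cmat, labels = cs.generate_synthetic(spec)
        split = cs.three_way_split(cmat, (150, 60, 40))
        lab = dict(zip(cmat.compound_ids, labels))
        tr = cmat.subset_rows(split.train_ids)
        trl = np.array([lab[c] for c in split.train_ids])
        dv = cmat.subset_rows(split.dev_ids)
        dvl = np.array([lab[c] for c in split.dev_ids])
        grid = cs.HyperparameterGrid("KNN", {"n_neighbors": [1, 119]})
        best, table = cs.bootstrap_hyperparameter_search(
            "KNN", grid, tr, trl, dv, dvl, n_models=10, seed=0)
        assert best == {"n_neighbors": 1}
        assert table["mean_mcc_dev"].iloc[0] > table["mean_mcc_dev"].iloc[1]

    def test_same_seed_same_score_table(self, small_split):
        (tr, trl), (dv, dvl) = small_split["train"], small_split["dev"]
        grid = cs.HyperparameterGrid("LR", {"C": [0.1, 1.0]})
        _, t1 = cs.bootstrap_hyperparameter_search("LR", grid, tr, trl, dv, dvl,
                                                   n_models=4, seed=5)
        _, t2 = cs.bootstrap_hyperparameter_search("LR", grid, tr, trl, dv, dvl,
                                                   n_models=4, seed=5)
        assert t1["mean_mcc_dev"].tolist() == t2["mean_mcc_dev"].tolist()


class TestSelectOriginal:
    def test_hundred_distinct_keeps_ninety(self):
        pop = _fake_population("KNN", np.zeros(100), np.linspace(0, 1, 100))
        assert len(cs.select_original({"KNN": pop}).members) == 90

    def test_ten_distinct_keeps_eight(self):
        pop = _fake_population("KNN", np.zeros(10), np.linspace(0, 1, 10))
        assert len(cs.select_original({"KNN": pop}).members) == 8

    def test_all_equal_keeps_all(self):
        pop = _fake_population("LR", np.zeros(30), np.full(30, 0.4))
        assert len(cs.select_original({"LR": pop}).members) == 30

    def test_band_matches_rank_filter(self):
        rng = np.random.default_rng(8)
        devs = rng.uniform(-1, 1, 100)
        pop = _fake_population("RF", np.zeros(100), devs)
        sel = cs.select_original({"RF": pop})
        lo, hi = np.percentile(devs, [5, 95])
        expected = {m.seed for m in pop if lo <= m.mcc_dev <= hi}  # brute filter
        assert {m.seed for m in sel.members} == expected


class TestSelectSupervised:
    def test_worked_example(self):
        pop = _fake_population("LR", [0.1, 0.3, 0.5, 0.7], [0.2, 0.4, 0.6, 0.8])
        sel = cs.select_supervised({"LR": pop})
        assert [m.seed for m in sel.members] == [2, 3]

    def test_identical_members_select_nothing(self):
        pop = _fake_population("LR", np.full(5, 0.3), np.full(5, 0.3))
        with pytest.raises(ValueError, match="no members"):
            cs.select_supervised({"LR": pop})

    def test_dominating_member_always_kept(self):
        rng = np.random.default_rng(0)
        trains = np.append(rng.uniform(0, 0.5, 20), 0.99)
        devs = np.append(rng.uniform(0, 0.5, 20), 0.99)
        pop = _fake_population("SVM", trains, devs)
        sel = cs.select_supervised({"SVM": pop})
        assert 20 in [m.seed for m in sel.members]

    @given(st.integers(0, 2**31 - 1), st.integers(5, 1000))
    @settings(max_examples=50, deadline=None)
    def test_matches_dual_predicate_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        trains, devs = rng.uniform(-1, 1, n), rng.uniform(-1, 1, n)
        pop = _fake_population("XGBoost", trains, devs)
        expected = {m.seed for m in pop
                    if m.mcc_train > trains.mean() and m.mcc_dev > devs.mean()}
        if not expected:
            with pytest.raises(ValueError):
                cs.select_supervised({"XGBoost": pop})
            return
        sel = cs.select_supervised({"XGBoost": pop})
        assert {m.seed for m in sel.members} == expected
        # selection keeps above-average members, never grows the population
        assert len(sel.members) < n
        kept_devs = [m.mcc_dev for m in sel.members]
        assert np.mean(kept_devs) >= devs.mean()


class TestModelLevelRepresentation:
    def test_columns_match_member_by_member_calls(self, tiny_populations, small_split):
        dv = small_split["dev"][0]
        ensemble = cs.select_supervised(tiny_populations)
        mlr = cs.predict_probabilities(ensemble, dv)
        assert mlr.probabilities.shape == (dv.n_compounds, len(ensemble.members))
        assert 0 <= mlr.probabilities.min() and mlr.probabilities.max() <= 1
        for j, mem in enumerate(ensemble.members):  # loop oracle
            np.testing.assert_allclose(
                mlr.probabilities[:, j], mem.predict_proba_positive(dv))

    def test_feature_mismatch_rejected(self, tiny_populations, small_split):
        dv = small_split["dev"][0]
        wrong = cs.DescriptorMatrix(dv.compound_ids, dv.values[:, :3],
                                    dv.feature_names[:3], dv.kind)
        ensemble = cs.select_supervised(tiny_populations)
        with pytest.raises(ValueError, match="feature mismatch"):
            cs.predict_probabilities(ensemble, wrong)

    def test_per_algorithm_counts(self, tiny_populations):
        ensemble = cs.select_supervised(tiny_populations)
        counts = ensemble.per_algorithm_counts
        assert set(counts) <= {"KNN", "LR"}
        assert sum(counts.values()) == len(ensemble.members)
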