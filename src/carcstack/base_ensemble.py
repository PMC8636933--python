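"""Base-classifier populations and the two MCC-driven selection strategies.

Five classical learners (KNN, LR, SVM, RF, XGBoost) are each trained many
times on random 80% subsamples of the training set. Hyperparameters are
chosen by bagging: for every combination in a grid, a population of
classifiers is fitted and the combination with the highest mean
development-set MCC wins. A large population trained at the winning
combination is then thinned by one of two rules:

* **original** — keep members whose development-set MCC lies within the
  5th-95th percentile band of the population (trims both tails);
* **supervised** — keep members whose MCC is strictly above the population
  mean on *both* the training set and the development set.

The survivors' positive-class probabilities, stacked per compound, form the
model-level representation that the meta-classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .descriptors import DescriptorMatrix

ALGORITHMS = ("KNN", "LR", "SVM", "RF", "XGBoost")

# Compact default grids around each algorithm's usual sweet spots; any grid
# can be swapped in via HyperparameterGrid.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "KNN": {"n_neighbors": [3, 5, 9], "weights": ["uniform", "distance"]},
    "LR": {"C": [0.1, 1.0, 10.0]},
    "SVM": {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
    "RF": {"n_estimators": [100], "max_depth": [None, 8], "max_features": ["sqrt"]},
    "XGBoost": {"n_estimators": [100], "max_depth": [3, 6], "learning_rate": [0.1]},
}


@dataclass
class HyperparameterGrid:
    """Named parameter lists to be crossed for one algorithm."""

    algorithm: str
    params: Mapping[str, list]

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if not self.params or any(len(v) == 0 for v in self.params.values()):
            raise ValueError("grid must be non-empty")

    def combinations(self) -> list[dict]:
        combos = [{}]
        for name, values in self.params.items():
            combos = [{**c, name: v} for c in combos for v in values]
        return combos

    @classmethod
    def default(cls, algorithm: str) -> "HyperparameterGrid":
        return cls(algorithm, DEFAULT_GRIDS[algorithm])


def make_estimator(algorithm: str, hyperparameters: Mapping[str, Any], seed: int):
    """Instantiate one learner; SVM gets Platt-scaled probabilities and, like
    KNN/LR, standardized inputs."""
    hp = dict(hyperparameters)
    if algorithm == "KNN":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**hp))
    if algorithm == "LR":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed, **hp)
        )
    if algorithm == "SVM":
        # Platt-scaled probabilities via internal cross-validated calibration
        return make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(SVC(random_state=seed, **hp), ensemble=False),
        )
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if algorithm == "XGBoost":
        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss", **hp)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class TrainedBaseClassifier:
    """One fitted learner plus the bookkeeping needed to audit and replay it."""

    algorithm: str
    hyperparameters: dict
    seed: int
    subsample_ids: list[str]
    model: Any
    mcc_train: float
    mcc_dev: float
    probability_source: str = "predict_proba"

    def predict_proba_positive(self, m: DescriptorMatrix) -> np.ndarray:
        proba = self.model.predict_proba(m.values)
        pos_col = list(self.model.classes_).index(1)
        return proba[:, pos_col]


@dataclass
class SelectedEnsemble:
    """Members surviving one selection strategy, concatenated across algorithms."""

    strategy: str
    members: list[TrainedBaseClassifier]
    selection_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("selected ensemble has no members")

    @property
    def per_algorithm_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for mem in self.members:
            counts[mem.algorithm] = counts.get(mem.algorithm, 0) + 1
        return counts

    @property
    def classifier_ids(self) -> list[str]:
        return [f"{m.algorithm}_{m.seed}" for m in self.members]


@dataclass
class ModelLevelRepresentation:
    """Compounds x selected-classifiers matrix of positive-class probabilities."""

    compound_ids: list[str]
    classifier_ids: list[str]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (len(self.compound_ids), len(self.classifier_ids)):
            raise ValueError("probability matrix shape does not match ids")
        if self.probabilities.min() < 0 or self.probabilities.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probabilities,
            index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.classifier_ids,
        )


def _subsample(
    rng: np.random.Generator,
    train: DescriptorMatrix,
    labels: np.ndarray,
    frac: float,
    replace: bool,
    max_retries: int = 20,
) -> tuple[np.ndarray, list[str]]:
    """Random row subsample containing both classes (bounded retries)."""
    n = train.n_compounds
    size = int(round(frac * n))
    for _ in range(max_retries):
        idx = rng.choice(n, size=size, replace=replace)
        if not replace:
            idx = np.sort(idx)
        if len(np.unique(labels[idx])) == 2:
            return idx, [train.compound_ids[i] for i in idx]
    raise RuntimeError(
        f"could not draw a subsample containing both classes in {max_retries} tries"
    )


def _fit_one(
    algorithm: str,
    combo: Mapping[str, Any],
    train: DescriptorMatrix,
    train_labels: np.ndarray,
    dev: DescriptorMatrix,
    dev_labels: np.ndarray,
    seed: int,
    subsample_frac: float,
    replace: bool,
) -> TrainedBaseClassifier:
    rng = np.random.default_rng(seed)
    idx, sub_ids = _subsample(rng, train, train_labels, subsample_frac, replace)
    est = make_estimator(algorithm, combo, seed)
    est.fit(train.values[idx], train_labels[idx])
    pos_col_of = list(est.classes_).index(1)
    p_train = est.predict_proba(train.values)[:, pos_col_of]
    p_dev = est.predict_proba(dev.values)[:, pos_col_of]
    return TrainedBaseClassifier(
        algorithm=algorithm,
        hyperparameters=dict(combo),
        seed=seed,
        subsample_ids=sub_ids,
        model=est,
        # mcc_train is scored on the FULL training set, not the subsample
        mcc_train=float(matthews_corrcoef(train_labels, p_train >= 0.5)),
        mcc_dev=float(matthews_corrcoef(dev_labels, p_dev >= 0.5)),
        probability_source="platt" if algorithm == "SVM" else "predict_proba",
    )


def train_base_population(
    algorithm: str,
    hyperparameters: Mapping[str, Any],
    train: DescriptorMatrix,
    train_labels: Sequence[int],
    dev: DescriptorMatrix,
    dev_labels: Sequence[int],
    n_models: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    replace: bool = False,
) -> list[TrainedBaseClassifier]:
    """Fit ``n_models`` classifiers on independent random 80% subsamples.

    Each member records its subsample, its MCC on the full training set and
    its MCC on the development set. ``replace=True`` switches to bootstrap
    sampling with replacement. Deterministic given ``seed``.
    """
    train_labels = np.asarray(train_labels, dtype=int)
    dev_labels = np.asarray(dev_labels, dtype=int)
    _check_sets(train, train_labels, dev, dev_labels)
    member_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_models)
    return [
        _fit_one(algorithm, hyperparameters, train, train_labels, dev, dev_labels,
                 int(s), subsample_frac, replace)
        for s in member_seeds
    ]


def _check_sets(train, train_labels, dev, dev_labels):
    if train.n_compounds != len(train_labels) or dev.n_compounds != len(dev_labels):
        raise ValueError("labels must align with matrices")
    if len(np.unique(train_labels)) < 2 or len(np.unique(dev_labels)) < 2:
        raise ValueError("train and dev must each contain both classes")
    if set(train.compound_ids) & set(dev.compound_ids):
        raise ValueError("train and dev sets overlap")
    if train.feature_names != dev.feature_names:
        raise ValueError("train and dev feature spaces differ")


def bootstrap_hyperparameter_search(
    algorithm: str,
    grid: HyperparameterGrid,
    train: DescriptorMatrix,
    train_labels: Sequence[int],
    dev: DescriptorMatrix,
    dev_labels: Sequence[int],
    n_models: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    replace: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """Bagged grid search: best combination by mean development-set MCC.

    For every combination, ``n_models`` classifiers are fitted on independent
    random subsamples and scored on the development set; the combination with
    the highest mean dev MCC wins (first in grid order on ties). Returns the
    winning combination and the full per-combination score table.
    """
    if grid.algorithm != algorithm:
        raise ValueError("grid/algorithm mismatch")
    records = []
    for combo in grid.combinations():
        population = train_base_population(
            algorithm, combo, train, train_labels, dev, dev_labels,
            n_models=n_models, subsample_frac=subsample_frac, seed=seed,
            replace=replace,
        )
        devs = np.array([m.mcc_dev for m in population])
        records.append({
            **{f"param_{k}": v for k, v in combo.items()},
            "combo": combo, "mean_mcc_dev": devs.mean(), "sd_mcc_dev": devs.std(),
        })
    table = pd.DataFrame(records)
    best = table.loc[table["mean_mcc_dev"].idxmax(), "combo"]
    return dict(best), table


def _percentile_band(values: np.ndarray, lo: float = 5.0, hi: float = 95.0) -> np.ndarray:
    """Boolean mask of values inside the inclusive [P_lo, P_hi] band.

    Percentiles use linear interpolation between order statistics (numpy's
    default), under which 100 distinct values keep exactly 90 members and 10
    distinct values keep 8.
    """
    p_lo, p_hi = np.percentile(values, [lo, hi])
    return (values >= p_lo) & (values <= p_hi)


def select_original(
    populations: Mapping[str, Sequence[TrainedBaseClassifier]],
    lo: float = 5.0,
    hi: float = 95.0,
) -> SelectedEnsemble:
    """Percentile-band selection: keep members with dev MCC in [P5, P95].

    Applied per algorithm; survivors are concatenated in algorithm order.
    """
    members: list[TrainedBaseClassifier] = []
    meta: dict[str, dict] = {}
    for algo, pop in populations.items():
        devs = np.array([m.mcc_dev for m in pop])
        mask = _percentile_band(devs, lo, hi)
        kept = [m for m, k in zip(pop, mask) if k]
        members.extend(kept)
        p_lo, p_hi = np.percentile(devs, [lo, hi])
        meta[algo] = {
            "n_population": len(pop), "n_selected": len(kept),
            "band": [float(p_lo), float(p_hi)],
            "percentile_convention": "linear-interpolation, inclusive bounds",
        }
    return SelectedEnsemble("original", members, meta)


def select_supervised(
    populations: Mapping[str, Sequence[TrainedBaseClassifier]],
) -> SelectedEnsemble:
    """Dual above-mean selection: keep members strictly above the population
    mean MCC on both the training and the development set (per algorithm)."""
    members: list[TrainedBaseClassifier] = []
    meta: dict[str, dict] = {}
    for algo, pop in populations.items():
        if len(pop) < 2:
            raise ValueError(f"{algo}: need >= 2 classifiers for supervised selection")
        trains = np.array([m.mcc_train for m in pop])
        devs = np.array([m.mcc_dev for m in pop])
        kept = [
            m for m in pop
            if m.mcc_train > trains.mean() and m.mcc_dev > devs.mean()
        ]
        members.extend(kept)
        meta[algo] = {
            "n_population": len(pop), "n_selected": len(kept),
            "mean_mcc_train": float(trains.mean()), "mean_mcc_dev": float(devs.mean()),
        }
    return SelectedEnsemble("supervised", members, meta)


def predict_probabilities(
    ensemble: SelectedEnsemble, m: DescriptorMatrix
) -> ModelLevelRepresentation:
    """Stack every member's positive-class probability into the model-level
    representation (columns follow ensemble member order)."""
    n_expected = ensemble.members[0].model.n_features_in_
    if m.n_features != n_expected:
        raise ValueError(
            f"feature mismatch: ensemble was trained on {n_expected} features, "
            f"matrix has {m.n_features}"
        )
    cols = [mem.predict_proba_positive(m) for mem in ensemble.members]
    return ModelLevelRepresentation(
        compound_ids=list(m.compound_ids),
        classifier_ids=ensemble.classifier_ids,
        probabilities=np.column_stack(cols),
    )
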