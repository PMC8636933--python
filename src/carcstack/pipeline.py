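"""End-to-end stacked-ensemble workflow and its on-disk run directory.

``run_stack`` is the in-memory core: given preprocessed train/dev/test
matrices it trains per-algorithm base populations, applies a selection
strategy, builds model-level representations, trains the meta network on
the development set, and evaluates everywhere. ``run_pipeline`` wraps it
with featurization, preprocessing, Kennard-Stone splitting, artifact
persistence and logging, driven by a single plain-text ``RunConfig``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

from . import base_ensemble as be
from .datasplit import SplitAssignment, three_way_split
from .descriptors import DescriptorMatrix, preprocess, write_drop_report
from .evaluation import (
    compute_metrics, confusion_at_threshold, roc_auc, threshold_prioritization,
)
from .meta import MetaClassifier, MetaNetworkConfig, train_meta
from .synthetic import SyntheticSpec, generate_synthetic

log = logging.getLogger("carcstack")


@dataclass
class RunConfig:
    """One run = one config: sizes, grids, seeds, strategy, output paths.

    Every stochastic stage draws its own seed from ``seed`` so a rerun with
    the same config reproduces every artifact bit for bit.
    """

    out_dir: str
    split_sizes: tuple[int, int, int] = (554, 138, 171)
    algorithms: tuple[str, ...] = be.ALGORITHMS
    grids: Mapping[str, Mapping[str, list]] | None = None
    n_search_models: int = 100
    n_population_models: int = 1000
    subsample_frac: float = 0.8
    strategy: str = "supervised"
    meta: dict = field(default_factory=dict)  # MetaNetworkConfig overrides
    seed: int | None = 0
    search_hyperparameters: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed before any compute")
        if self.strategy not in ("original", "supervised"):
            raise ValueError(f"unknown selection strategy {self.strategy!r}")


@dataclass
class StackResult:
    """Everything the stacked run produced, in memory."""

    populations: dict[str, list[be.TrainedBaseClassifier]]
    best_combos: dict[str, dict]
    ensemble: be.SelectedEnsemble
    meta_model: MetaClassifier
    mlr: dict[str, be.ModelLevelRepresentation]
    meta_probs: dict[str, np.ndarray]
    metrics: dict[str, dict]
    base_mcc_dev_mean: float

    @property
    def meta_dev_mcc(self) -> float:
        return self.metrics["dev"]["mcc"]


def _evaluate(probs: np.ndarray, labels: np.ndarray) -> dict:
    counts = confusion_at_threshold(probs, labels)
    auc = roc_auc(probs, labels) if len(np.unique(labels)) == 2 else None
    bundle = compute_metrics(counts, auc=auc)
    out = vars(bundle).copy()
    out["counts"] = {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn}
    return out


def run_stack(
    train: DescriptorMatrix, train_labels: Sequence[int],
    dev: DescriptorMatrix, dev_labels: Sequence[int],
    test: DescriptorMatrix | None = None, test_labels: Sequence[int] | None = None,
    algorithms: Sequence[str] = be.ALGORITHMS,
    grids: Mapping[str, Mapping[str, list]] | None = None,
    n_search_models: int = 100,
    n_population_models: int = 1000,
    subsample_frac: float = 0.8,
    strategy: str = "supervised",
    meta_overrides: Mapping | None = None,
    seed: int = 0,
    search_hyperparameters: bool = True,
) -> StackResult:
    """Train and evaluate the full stack on already-split descriptor matrices.

    When ``search_hyperparameters`` is false, the first combination of each
    algorithm's grid is used as-is (useful for small smoke runs).
    """
    train_labels = np.asarray(train_labels, dtype=int)
    dev_labels = np.asarray(dev_labels, dtype=int)
    rng = np.random.default_rng(seed)
    stage_seeds = {a: int(s) for a, s in
                   zip(algorithms, rng.integers(0, 2**31 - 1, size=len(algorithms)))}
    meta_seed = int(rng.integers(0, 2**31 - 1))

    populations: dict[str, list[be.TrainedBaseClassifier]] = {}
    best_combos: dict[str, dict] = {}
    for algo in algorithms:
        grid = be.HyperparameterGrid(algo, grids[algo]) if grids and algo in grids \
            else be.HyperparameterGrid.default(algo)
        t0 = time.perf_counter()
        if search_hyperparameters:
            best, _ = be.bootstrap_hyperparameter_search(
                algo, grid, train, train_labels, dev, dev_labels,
                n_models=n_search_models, subsample_frac=subsample_frac,
                seed=stage_seeds[algo],
            )
        else:
            best = grid.combinations()[0]
        best_combos[algo] = best
        populations[algo] = be.train_base_population(
            algo, best, train, train_labels, dev, dev_labels,
            n_models=n_population_models, subsample_frac=subsample_frac,
            seed=stage_seeds[algo] + 1,
        )
        log.info("base stage %s: combo=%s, %d models, %.1fs",
                 algo, best, n_population_models, time.perf_counter() - t0)

    select = be.select_supervised if strategy == "supervised" else be.select_original
    ensemble = select(populations)
    base_mcc_dev_mean = float(np.mean([m.mcc_dev for m in ensemble.members]))

    mlr = {"dev": be.predict_probabilities(ensemble, dev)}
    cfg = MetaNetworkConfig(
        input_dim=len(ensemble.members), seed=meta_seed, **(meta_overrides or {})
    )
    meta_model = train_meta(cfg, mlr["dev"], dev_labels)

    meta_probs = {"dev": meta_model.predict_proba(mlr["dev"])}
    metrics = {"dev": _evaluate(meta_probs["dev"], dev_labels)}
    mlr["train"] = be.predict_probabilities(ensemble, train)
    meta_probs["train"] = meta_model.predict_proba(mlr["train"])
    metrics["train"] = _evaluate(meta_probs["train"], train_labels)
    if test is not None:
        mlr["test"] = be.predict_probabilities(ensemble, test)
        meta_probs["test"] = meta_model.predict_proba(mlr["test"])
        if test_labels is not None:
            metrics["test"] = _evaluate(meta_probs["test"], np.asarray(test_labels, int))

    return StackResult(
        populations=populations, best_combos=best_combos, ensemble=ensemble,
        meta_model=meta_model, mlr=mlr, meta_probs=meta_probs, metrics=metrics,
        base_mcc_dev_mean=base_mcc_dev_mean,
    )


def save_ensemble(ensemble: be.SelectedEnsemble, out_dir: str | Path) -> None:
    """Persist members per algorithm (joblib) with a JSON manifest each."""
    out_dir = Path(out_dir)
    for i, mem in enumerate(ensemble.members):
        algo_dir = out_dir / mem.algorithm
        algo_dir.mkdir(parents=True, exist_ok=True)
        joblib.dump(mem.model, algo_dir / f"member_{i:04d}.joblib")
        (algo_dir / f"member_{i:04d}.json").write_text(json.dumps({
            "algorithm": mem.algorithm, "hyperparameters": mem.hyperparameters,
            "seed": mem.seed, "subsample_ids": mem.subsample_ids,
            "mcc_train": mem.mcc_train, "mcc_dev": mem.mcc_dev,
            "probability_source": mem.probability_source,
            "selection_strategy": ensemble.strategy,
        }, indent=2))
    (out_dir / "manifest.json").write_text(json.dumps({
        "strategy": ensemble.strategy,
        "classifier_ids": ensemble.classifier_ids,
        "per_algorithm_counts": ensemble.per_algorithm_counts,
        "selection_metadata": ensemble.selection_metadata,
    }, indent=2))


def load_ensemble(out_dir: str | Path) -> be.SelectedEnsemble:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    members = []
    paths = sorted(out_dir.glob("*/member_*.json"))
    # restore original member order from classifier ids
    by_key: dict[str, be.TrainedBaseClassifier] = {}
    for meta_path in paths:
        meta = json.loads(meta_path.read_text())
        model = joblib.load(meta_path.with_suffix(".joblib"))
        mem = be.TrainedBaseClassifier(
            algorithm=meta["algorithm"], hyperparameters=meta["hyperparameters"],
            seed=meta["seed"], subsample_ids=meta["subsample_ids"], model=model,
            mcc_train=meta["mcc_train"], mcc_dev=meta["mcc_dev"],
            probability_source=meta["probability_source"],
        )
        by_key.setdefault(f"{mem.algorithm}_{mem.seed}", mem)
        members.append(mem)
    ordered = [by_key[k] for k in manifest["classifier_ids"]] \
        if set(manifest["classifier_ids"]) == set(by_key) else members
    return be.SelectedEnsemble(manifest["strategy"], ordered,
                               manifest.get("selection_metadata", {}))


def run_pipeline(
    config: RunConfig,
    matrix: DescriptorMatrix | None = None,
    labels: Sequence[int] | None = None,
    synthetic_spec: SyntheticSpec | None = None,
) -> Path:
    """Execute the whole workflow and write every intermediate artifact.

    Input is either a labeled descriptor matrix or a synthetic-data spec
    (in which case the continuous block is modeled). Artifacts written:
    preprocessed descriptor CSV + drop report, split assignment CSV,
    ensemble bundle + manifest, meta model, per-split prediction CSVs,
    metrics JSON, threshold-prioritization CSV, and the config itself.
    """
    out = Path(config.out_dir)
    stage = "setup"
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(config).items()}, indent=2, default=str))

        if matrix is None:
            stage = "synthesize"
            if synthetic_spec is None:
                synthetic_spec = SyntheticSpec(seed=config.seed)
            _, matrix, labels = generate_synthetic(synthetic_spec)
        labels = np.asarray(labels, dtype=int)

        stage = "preprocess"
        pre = preprocess(matrix)
        pre.to_csv(out / "descriptors_preprocessed.csv")
        write_drop_report(pre, out / "dropped_features.json")

        stage = "split"
        split = three_way_split(pre, config.split_sizes)
        assign = pd.DataFrame(
            [(c, "train") for c in split.train_ids]
            + [(c, "dev") for c in split.dev_ids]
            + [(c, "test") for c in split.test_ids],
            columns=["compound_id", "subset"],
        )
        assign.to_csv(out / "split_assignment.csv", index=False)

        label_of = dict(zip(matrix.compound_ids, labels))
        subsets = {}
        for name, ids in (("train", split.train_ids), ("dev", split.dev_ids),
                          ("test", split.test_ids)):
            subsets[name] = (pre.subset_rows(ids),
                             np.array([label_of[c] for c in ids], dtype=int))

        stage = "train_stack"
        result = run_stack(
            subsets["train"][0], subsets["train"][1],
            subsets["dev"][0], subsets["dev"][1],
            subsets["test"][0], subsets["test"][1],
            algorithms=config.algorithms, grids=config.grids,
            n_search_models=config.n_search_models,
            n_population_models=config.n_population_models,
            subsample_frac=config.subsample_frac, strategy=config.strategy,
            meta_overrides=config.meta, seed=config.seed,
            search_hyperparameters=config.search_hyperparameters,
        )

        stage = "persist"
        save_ensemble(result.ensemble, out / "ensemble")
        result.meta_model.save(out / "meta_model")
        for name, probs in result.meta_probs.items():
            ids = subsets[name][0].compound_ids
            pd.DataFrame({
                "compound_id": ids, "probability": probs, "label": subsets[name][1],
            }).to_csv(out / f"predictions_{name}.csv", index=False)
        (out / "metrics.json").write_text(json.dumps({
            "best_hyperparameters": result.best_combos,
            "per_algorithm_counts": result.ensemble.per_algorithm_counts,
            "base_mcc_dev_mean": result.base_mcc_dev_mean,
            "metrics": result.metrics,
        }, indent=2, default=float))

        stage = "prioritize"
        eval_name = "test" if "test" in result.meta_probs else "dev"
        rows = threshold_prioritization(result.meta_probs[eval_name],
                                        subsets[eval_name][1])
        pd.DataFrame([{
            "threshold": r.threshold, "tp": r.counts.tp, "fp": r.counts.fp,
            "tn": r.counts.tn, "fn": r.counts.fn, "p_value": r.p_value,
            "ppv": r.ppv, "npv": r.npv,
        } for r in rows]).to_csv(out / "threshold_prioritization.csv", index=False)

        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
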