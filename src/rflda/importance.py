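"""Random-forest permutation importance and importance-based feature selection.

Importance follows Breiman's out-of-bag (OOB) scheme: each regression tree
is grown on a bootstrap sample; its OOB rows are predicted before and after
permuting one feature column, and the feature's score is the mean error
increase over trees.  Features a tree never splits on are skipped, which
makes their contribution exactly zero.  For the 0/1 regression targets
used here the default error is mean squared error; the ``classification``
option instead thresholds OOB predictions at 0.5 and measures the accuracy
decrement, the description usually attached to importance scores even when
the forest is a regression.

Scores are averaged over several independently seeded runs and features
ranked by mean score (ties broken by feature id ascending, so the total
order is deterministic).  The operating size k is picked by sweeping the
top-k prefix of the ranking through stratified cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeRegressor

from .features import SampleMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ForestParams",
    "ImportanceRanking",
    "AccuracyCurve",
    "default_mtry",
    "oob_permutation_importance",
    "average_importance",
    "rank_features",
    "select_top_k",
    "sweep_k_accuracy",
]


def default_mtry(n_features: int) -> int:
    """Features tried per split: one third of the feature count, at least 1."""
    return max(1, n_features // 3)


@dataclass(frozen=True)
class ForestParams:
    """Random-forest hyper-parameters.

    ``mtry=None`` applies the p/3 rule at whatever feature count the forest
    is grown on (so the rule follows the selection stage through every k).
    """

    n_trees: int = 500
    mtry: int | None = None
    seed: int = 0
    task: str = "regression"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1 when given")
        if self.task != "regression":
            raise ValueError("only the regression task is supported")

    def resolve_mtry(self, n_features: int) -> int:
        mtry = self.mtry if self.mtry is not None else default_mtry(n_features)
        return min(mtry, n_features)

    def make_forest(self, n_features: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.resolve_mtry(n_features),
            random_state=self.seed,
            n_jobs=1,
        )


def oob_permutation_importance(
    samples: SampleMatrix,
    params: ForestParams,
    classification: bool = False,
) -> np.ndarray:
    """Per-feature OOB permutation importance from one seeded forest.

    Returns one score per feature of ``samples`` (larger = more important):
    the mean over trees of the OOB mean-squared-error increase after
    permuting the feature, or of the accuracy decrement at a 0.5 score
    threshold when ``classification`` is set.
    """
    if samples.labels is None:
        raise ValueError("importance needs labelled samples")
    y = samples.labels
    if np.unique(y).size < 2:
        raise ValueError("importance needs at least two label classes")
    X = samples.values
    n, p = X.shape
    rng = np.random.default_rng(params.seed)
    mtry = params.resolve_mtry(p)

    scores = np.zeros(p)
    trees_with_oob = 0
    for _ in range(params.n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = DecisionTreeRegressor(max_features=mtry, random_state=tree_seed)
        tree.fit(X[boot], y[boot])
        if oob.size == 0:
            continue
        trees_with_oob += 1
        X_oob = X[oob]
        y_oob = y[oob]
        base_pred = tree.predict(X_oob)
        if classification:
            base = np.mean((base_pred >= 0.5) == (y_oob >= 0.5))
        else:
            base = np.mean((base_pred - y_oob) ** 2)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]  # drop the leaf marker
        for f in used:
            X_perm = X_oob.copy()
            X_perm[:, f] = X_perm[rng.permutation(oob.size), f]
            pred = tree.predict(X_perm)
            if classification:
                scores[f] += base - np.mean((pred >= 0.5) == (y_oob >= 0.5))
            else:
                scores[f] += np.mean((pred - y_oob) ** 2) - base
    if trees_with_oob == 0:
        raise ValueError("no tree had out-of-bag samples; increase sample count")
    return scores / trees_with_oob


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ordered by mean importance, with per-run provenance."""

    feature_ids: tuple[str, ...]  # ranked: mean score desc, id asc on ties
    mean_scores: np.ndarray  # aligned with feature_ids
    per_run: np.ndarray  # shape (n_runs, n_features), same alignment
    seeds: tuple[int, ...] = ()

    @property
    def n_runs(self) -> int:
        return self.per_run.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.feature_ids) + 1),
                "feature": list(self.feature_ids),
                "mean_importance": self.mean_scores,
            }
        )
        for r in range(self.n_runs):
            frame[f"run_{r + 1}"] = self.per_run[r]
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def average_importance(
    runs: Sequence[np.ndarray],
    feature_ids: Sequence[str],
    seeds: Sequence[int] = (),
) -> ImportanceRanking:
    """Average per-run scores and impose the deterministic total order."""
    if len(runs) == 0:
        raise ValueError("need at least one importance run")
    per_run = np.asarray(runs, dtype=float)
    if per_run.shape[1] != len(feature_ids):
        raise ValueError("importance runs cover different feature sets")
    mean = per_run.mean(axis=0)
    order = sorted(range(len(feature_ids)), key=lambda i: (-mean[i], feature_ids[i]))
    return ImportanceRanking(
        feature_ids=tuple(feature_ids[i] for i in order),
        mean_scores=mean[order],
        per_run=per_run[:, order],
        seeds=tuple(seeds),
    )


def rank_features(
    samples: SampleMatrix,
    params: ForestParams,
    n_runs: int = 10,
    classification: bool = False,
) -> ImportanceRanking:
    """Run OOB permutation importance ``n_runs`` times and average.

    Run r uses seed ``params.seed + r`` so the full ranking is reproducible
    from the base seed alone.
    """
    seeds = [params.seed + r for r in range(n_runs)]
    runs = [
        oob_permutation_importance(
            samples, replace(params, seed=s), classification=classification
        )
        for s in seeds
    ]
    return average_importance(runs, samples.feature_ids, seeds=seeds)


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered prefix of an importance ranking."""

    kept: tuple[str, ...]
    provenance: str = ""


def select_top_k(ranking: ImportanceRanking, k: int) -> FeatureSubset:
    if not 1 <= k <= len(ranking.feature_ids):
        raise ValueError(
            f"k must be in [1, {len(ranking.feature_ids)}], got {k}"
        )
    return FeatureSubset(
        kept=ranking.feature_ids[:k],
        provenance=f"top-{k} of {ranking.n_runs}-run mean importance",
    )


@dataclass(frozen=True)
class AccuracyCurve:
    """Cross-validated accuracy as a function of the number of kept features."""

    ks: tuple[int, ...]
    accuracy: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.ks, self.ks[1:])):
            raise ValueError("ks must be strictly increasing")

    @property
    def best_k(self) -> int:
        return self.ks[int(np.argmax(self.accuracy))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "accuracy": self.accuracy})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def sweep_k_accuracy(
    samples: SampleMatrix,
    ranking: ImportanceRanking,
    ks: Sequence[int],
    folds: int = 10,
    threshold: float = 0.5,
    params: ForestParams = ForestParams(),
) -> AccuracyCurve:
    """Mean stratified CV accuracy of forests trained on top-k feature sets.

    Accuracy counts a held-out sample as correct when its regression score,
    thresholded at ``threshold``, matches the 0/1 label.  ``mtry`` follows
    the p/3 rule at each k unless pinned in ``params``.
    """
    if samples.labels is None:
        raise ValueError("the accuracy sweep needs labelled samples")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    index = {f: i for i, f in enumerate(samples.feature_ids)}
    y = samples.labels
    y_cls = (y >= threshold).astype(int)
    accuracies = []
    for k in ks:
        cols = [index[f] for f in ranking.feature_ids[:k]]
        X = samples.values[:, cols]
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=params.seed
        )
        correct = 0
        for fold, (train, test) in enumerate(splitter.split(X, y_cls)):
            forest = RandomForestRegressor(
                n_estimators=params.n_trees,
                max_features=params.resolve_mtry(k),
                random_state=params.seed + fold,
                n_jobs=1,
            )
            forest.fit(X[train], y[train])
            pred = forest.predict(X[test]) >= threshold
            correct += int(np.sum(pred == (y_cls[test] == 1)))
        accuracies.append(correct / len(y))
        logger.info("sweep k=%d accuracy=%.4f", k, accuracies[-1])
    return AccuracyCurve(ks=tuple(ks), accuracy=tuple(accuracies))
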