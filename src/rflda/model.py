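"""The random-forest association model, its CV protocol and case studies.

The model scores every lncRNA-disease pair with a random-forest regression
trained on experiment-supported associations (label 1) against an equal
number of unconfirmed pairs sampled uniformly at random (label 0).  Feature
vectors concatenate lncRNA functional similarity, lncRNA-disease and
lncRNA-miRNA association profiles, disease semantic similarity and
miRNA-disease association profiles; features are min-max normalized,
all-zero columns dropped, and optionally reduced to the top-k features of
an out-of-bag permutation-importance ranking before training.

:class:`RFLDA` is the user-facing model object: build it from the three
association matrices plus an ontology (or from files), call :meth:`RFLDA.fit`
to run the pipeline, and use the returned :class:`RFLDAResults` to rank
candidate lncRNAs, run the cross-validation protocol, or produce
case-study tables in which every known association of the investigated
disease is removed before feature building and training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics
from .features import (
    FeatureMatrices,
    FeatureScaler,
    SampleMatrix,
    build_sample_matrix,
    drop_allzero_features,
    normalize_features,
)
from .importance import (
    AccuracyCurve,
    FeatureSubset,
    ForestParams,
    ImportanceRanking,
    rank_features,
    select_top_k,
    sweep_k_accuracy,
)
from .io import AssociationMatrix, OntologyGraph, read_association_matrix, read_ontology
from .similarity import (
    SimilarityMatrix,
    disease_similarity_matrix,
    lncrna_similarity_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RFLDA",
    "RFLDAResults",
    "CVResult",
    "sample_negatives",
    "partition_folds",
    "train_score",
    "cross_validate",
    "case_study",
]

Pair = tuple[str, str]


def sample_negatives(
    positives: Sequence[Pair],
    universe: Sequence[Pair],
    n: int,
    seed: int,
) -> list[Pair]:
    """Sample ``n`` unconfirmed pairs uniformly without replacement.

    The sample is disjoint from ``positives`` and reproducible from
    ``seed`` alone (candidates are put in sorted order before drawing).
    """
    pos = set(positives)
    candidates = sorted(set(universe) - pos)
    if n > len(candidates):
        raise ValueError(
            f"cannot sample {n} negatives from {len(candidates)} unconfirmed pairs"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in picked]


def partition_folds(
    n_items: int, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shuffle indices and split them into ``folds`` near-equal parts.

    Part sizes differ by at most one (2697 items over 5 folds gives parts
    of 540, 540, 539, 539 and 539).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    order = rng.permutation(n_items)
    return np.array_split(order, folds)


def train_score(
    train: SampleMatrix, test: SampleMatrix, params: ForestParams
) -> np.ndarray:
    """Fit a regression forest on ``train`` and score ``test`` pairs.

    Scores are means of 500 (by default) tree outputs over 0/1 targets,
    hence already in [0, 1]; identical seeds give identical scores.
    """
    if train.feature_ids != test.feature_ids:
        raise ValueError("train and test sample matrices disagree on features")
    if train.labels is None:
        raise ValueError("training samples must be labelled")
    forest = params.make_forest(train.n_features)
    forest.fit(train.values, train.labels)
    return np.clip(forest.predict(test.values), 0.0, 1.0)


def _prepare_fold(
    train: SampleMatrix,
    test: SampleMatrix,
    feature_subset: FeatureSubset | None,
    normalization: str,
) -> tuple[SampleMatrix, SampleMatrix]:
    """Normalize, drop training-dead columns and apply the feature subset."""
    if normalization == "paper_exact":
        # statistics over train and test jointly, as stated for the
        # original protocol; "train" fits them on the training rows only
        joint = SampleMatrix(
            train.pair_ids + test.pair_ids,
            train.feature_ids,
            np.vstack([train.values, test.values]),
        )
        scaler = FeatureScaler.fit(joint)
        train = scaler.transform(train)
    elif normalization == "train":
        train, scaler = normalize_features(train)
    else:
        raise ValueError(f"unknown normalization mode {normalization!r}")
    test = scaler.transform(test)
    train, removed = drop_allzero_features(train)
    kept = train.feature_ids
    if feature_subset is not None:
        kept = tuple(f for f in feature_subset.kept if f not in set(removed))
        train = train.subset_features(kept)
    return train, test.subset_features(kept)


@dataclass(frozen=True)
class CVResult:
    """Fold-level AUC/AUPR with the protocol metadata that produced them."""

    auc: np.ndarray  # shape (repetitions, folds)
    aupr: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(self.auc.mean())

    @property
    def mean_aupr(self) -> float:
        return float(self.aupr.mean())

    @property
    def sd_auc_folds(self) -> float:
        """Mean over repetitions of the fold-to-fold standard deviation."""
        return float(self.auc.std(axis=1, ddof=1).mean()) if self.auc.shape[1] > 1 else 0.0

    @property
    def sd_auc_reps(self) -> float:
        """Standard deviation over repetition means."""
        reps = self.auc.mean(axis=1)
        return float(reps.std(ddof=1)) if reps.size > 1 else 0.0

    @property
    def sd_aupr_folds(self) -> float:
        return float(self.aupr.std(axis=1, ddof=1).mean()) if self.aupr.shape[1] > 1 else 0.0

    @property
    def sd_aupr_reps(self) -> float:
        reps = self.aupr.mean(axis=1)
        return float(reps.std(ddof=1)) if reps.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        reps, folds = self.auc.shape
        rows = [
            (r + 1, f + 1, self.auc[r, f], self.aupr[r, f])
            for r in range(reps)
            for f in range(folds)
        ]
        return pd.DataFrame(rows, columns=["repetition", "fold", "auc", "aupr"])


def cross_validate(
    matrices: FeatureMatrices,
    folds: int = 5,
    repetitions: int = 10,
    params: ForestParams = ForestParams(),
    n_negatives: int | None = None,
    mask_self: bool = True,
    feature_subset: FeatureSubset | None = None,
    include_trained_negatives: bool = False,
    normalization: str = "train",
    truth_pairs: Sequence[Pair] | None = None,
    recovery_pool: Sequence[Pair] | None = None,
    shuffle_labels: bool = False,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold evaluation of the association scorer.

    Per repetition, negatives are freshly sampled (seed + repetition) and
    positives/negatives are each split into ``folds`` near-equal parts.
    Each fold trains on the other parts and scores a test set of the
    held-out positives (class 1) against every unconfirmed pair (class 0);
    the repetition's sampled training negatives are excluded from that
    pool unless ``include_trained_negatives`` re-admits them (the literal
    protocol).  AUC and AUPR are recorded per fold.

    ``truth_pairs`` switches to planted-signal recovery: the test set is
    the unconfirmed pool alone and a pair's class is membership in
    ``truth_pairs`` (used with synthetic benchmarks whose held-out true
    associations were zeroed in LD).  ``recovery_pool`` restricts the
    class-0 side of that test set to an explicit pair list (e.g. the
    benchmark's background pairs; see
    :func:`rflda.synthetic.background_pairs` for why).  ``shuffle_labels``
    permutes training labels, giving the matching no-signal null.
    """
    positives = matrices.ld.pairs()
    universe = matrices.all_pairs()
    n_neg = len(positives) if n_negatives is None else n_negatives
    truth = set(truth_pairs) if truth_pairs is not None else None

    aucs = np.zeros((repetitions, folds))
    auprs = np.zeros((repetitions, folds))
    for rep in range(repetitions):
        rep_seed = seed + rep
        negatives = sample_negatives(positives, universe, n_neg, seed=rep_seed)
        rng = np.random.default_rng(rep_seed)
        pos_folds = partition_folds(len(positives), folds, rng)
        neg_folds = partition_folds(len(negatives), folds, rng)

        excluded = set(negatives) if not include_trained_negatives else set()
        if truth is not None and recovery_pool is not None:
            pool = sorted((set(recovery_pool) | truth) - excluded)
        else:
            pool = sorted(set(universe) - set(positives) - excluded)
        all_pairs = positives + negatives + pool
        samples = build_sample_matrix(all_pairs, matrices, mask_self=mask_self)
        n_pos, n_negs = len(positives), len(negatives)
        pool_rows = np.arange(n_pos + n_negs, len(all_pairs))
        pool_labels = (
            np.array([p in truth for p in pool], dtype=int)
            if truth is not None
            else np.zeros(len(pool), dtype=int)
        )

        for fold in range(folds):
            test_pos = pos_folds[fold]
            train_pos = np.concatenate(
                [pos_folds[i] for i in range(folds) if i != fold]
            )
            train_neg = n_pos + np.concatenate(
                [neg_folds[i] for i in range(folds) if i != fold]
            )
            train_rows = np.concatenate([train_pos, train_neg])
            y_train = np.r_[np.ones(train_pos.size), np.zeros(train_neg.size)]
            if shuffle_labels:
                y_train = np.random.default_rng(rep_seed + 7919 * (fold + 1)).permutation(
                    y_train
                )
            if truth is None:
                test_rows = np.concatenate([test_pos, pool_rows])
                y_test = np.r_[np.ones(test_pos.size), pool_labels]
            else:
                test_rows = pool_rows
                y_test = pool_labels
            train = SampleMatrix(
                tuple(all_pairs[i] for i in train_rows),
                samples.feature_ids,
                samples.values[train_rows],
                y_train,
            )
            test = SampleMatrix(
                tuple(all_pairs[i] for i in test_rows),
                samples.feature_ids,
                samples.values[test_rows],
            )
            train, test = _prepare_fold(train, test, feature_subset, normalization)
            scores = train_score(train, test, replace(params, seed=params.seed + rep))
            aucs[rep, fold] = metrics.auc(y_test, scores)
            auprs[rep, fold] = metrics.aupr(y_test, scores)
            logger.info(
                "rep %d fold %d: AUC=%.4f AUPR=%.4f",
                rep + 1,
                fold + 1,
                aucs[rep, fold],
                auprs[rep, fold],
            )
    return CVResult(
        auc=aucs,
        aupr=auprs,
        metadata={
            "folds": folds,
            "repetitions": repetitions,
            "seed": seed,
            "n_negatives": n_neg,
            "mask_self": mask_self,
            "normalization": normalization,
            "include_trained_negatives": include_trained_negatives,
            "mode": "recovery" if truth is not None else "heldout_positives",
            "shuffle_labels": shuffle_labels,
            "forest": {"n_trees": params.n_trees, "mtry": params.mtry},
        },
    )


def case_study(
    disease: str,
    matrices: FeatureMatrices,
    params: ForestParams = ForestParams(),
    top_k: int = 15,
    mask_self: bool = True,
    feature_subset: FeatureSubset | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank candidate lncRNAs for one disease under full hold-out.

    Every known association of ``disease`` is removed from LD before the
    lncRNA similarity matrix is recomputed and features are built, so no
    trace of the investigated disease's associations can reach the model.
    Training negatives are sampled from unconfirmed pairs of the *other*
    diseases; every lncRNA is then scored against ``disease`` and the
    ``top_k`` highest-scoring candidates returned.
    """
    if disease not in matrices.diseases:
        raise KeyError(f"unknown disease {disease!r}")
    d_idx = matrices.ld.col_index(disease)
    masked_values = matrices.ld.values.copy()
    masked_values[:, d_idx] = 0
    ld_masked = AssociationMatrix(
        matrices.ld.row_ids, matrices.ld.col_ids, masked_values
    )
    ll_masked = lncrna_similarity_matrix(ld_masked, matrices.dd)
    masked = FeatureMatrices(
        ll=ll_masked, ld=ld_masked, lm=matrices.lm, dd=matrices.dd, md=matrices.md
    )

    positives = ld_masked.pairs()
    universe = [p for p in masked.all_pairs() if p[1] != disease]
    negatives = sample_negatives(positives, universe, len(positives), seed=seed)
    train = build_sample_matrix(
        positives + negatives,
        masked,
        labels=np.r_[np.ones(len(positives)), np.zeros(len(negatives))],
        mask_self=mask_self,
    )
    candidates = [(l, disease) for l in masked.lncrnas]
    test = build_sample_matrix(candidates, masked, mask_self=mask_self)
    train, test = _prepare_fold(train, test, feature_subset, "train")
    scores = train_score(train, test, params)
    frame = pd.DataFrame(
        {
            "disease": disease,
            "lncRNA": [l for l, _ in candidates],
            "score": scores,
        }
    ).sort_values(["score", "lncRNA"], ascending=[False, True])
    return frame.head(top_k).reset_index(drop=True)


class RFLDA:
    """Random-forest lncRNA-disease association model.

    Parameters
    ----------
    ld, md, lm
        Binary association matrices: lncRNA x disease, miRNA x disease and
        lncRNA x miRNA, over shared entity axes.
    ontology
        IS_A hierarchy covering (ideally) the disease axis; diseases
        missing from it fall back to single-node DAGs.
    delta
        Semantic-contribution attenuation for disease similarity (0.5
        by default).
    mask_self
        Zero each sample's own association cell in both LD-derived blocks
        (on by default; turn off to reproduce the literal feature map,
        which leaks the label).
    params
        Forest hyper-parameters; ``mtry=None`` applies the p/3 rule.

    Examples
    --------
    >>> model = RFLDA(ld, md, lm, ontology)
    >>> results = model.fit(n_importance_runs=10, k=300)
    >>> print(results.summary())
    >>> results.predict(disease="colon cancer", top_k=15)
    """

    def __init__(
        self,
        ld: AssociationMatrix,
        md: AssociationMatrix,
        lm: AssociationMatrix,
        ontology: OntologyGraph,
        delta: float = 0.5,
        mask_self: bool = True,
        params: ForestParams = ForestParams(),
    ) -> None:
        self.ld = ld
        self.md = md
        self.lm = lm
        self.ontology = ontology
        self.delta = delta
        self.mask_self = mask_self
        self.params = params
        self._matrices: FeatureMatrices | None = None

    @classmethod
    def from_files(
        cls,
        ld_path: str | Path,
        md_path: str | Path,
        lm_path: str | Path,
        ontology_path: str | Path,
        dialect: str = "obo",
        **kwargs,
    ) -> "RFLDA":
        ld = read_association_matrix(ld_path)
        md = read_association_matrix(md_path)
        lm = read_association_matrix(lm_path)
        if lm.col_ids != md.row_ids and lm.shape[1] != md.shape[0]:
            logger.warning(
                "lncRNA-miRNA matrix has %d miRNA columns but the "
                "miRNA-disease matrix has %d miRNA rows",
                lm.shape[1],
                md.shape[0],
            )
        ontology = read_ontology(ontology_path, dialect=dialect)
        return cls(ld, md, lm, ontology, **kwargs)

    @property
    def matrices(self) -> FeatureMatrices:
        """The five feature matrices; similarities computed on first access."""
        if self._matrices is None:
            missing = [d for d in self.ld.col_ids if d not in self.ontology]
            if missing:
                logger.warning(
                    "%d disease(s) absent from the ontology (self DAGs used)",
                    len(missing),
                )
            dd = disease_similarity_matrix(
                list(self.ld.col_ids), self.ontology, self.delta
            )
            ll = lncrna_similarity_matrix(self.ld, dd)
            self._matrices = FeatureMatrices(
                ll=ll, ld=self.ld, lm=self.lm, dd=dd, md=self.md
            )
        return self._matrices

    def fit(
        self,
        n_importance_runs: int = 10,
        k: int | None = 300,
        sweep_ks: Sequence[int] | None = None,
        sweep_folds: int = 10,
        seed: int | None = None,
    ) -> "RFLDAResults":
        """Run the full pipeline and return fitted results.

        Steps: sample negatives, assemble and normalize the training
        matrix, drop all-zero features, rank the remainder by averaged
        OOB permutation importance, pick k (fixed ``k``, or the best of
        ``sweep_ks`` by stratified CV accuracy), and train the final
        regression forest on the selected features.
        """
        params = self.params if seed is None else replace(self.params, seed=seed)
        matrices = self.matrices
        positives = self.ld.pairs()
        negatives = sample_negatives(
            positives, matrices.all_pairs(), len(positives), seed=params.seed
        )
        raw = build_sample_matrix(
            positives + negatives,
            matrices,
            labels=np.r_[np.ones(len(positives)), np.zeros(len(negatives))],
            mask_self=self.mask_self,
        )
        normalized, scaler = normalize_features(raw)
        pruned, removed = drop_allzero_features(normalized)
        logger.info(
            "assembled %d samples x %d features; %d all-zero features removed",
            pruned.n_samples,
            raw.n_features,
            len(removed),
        )
        ranking = rank_features(pruned, params, n_runs=n_importance_runs)
        curve = None
        if sweep_ks is not None:
            curve = sweep_k_accuracy(
                pruned, ranking, sweep_ks, folds=sweep_folds, params=params
            )
            k = curve.best_k
        k = min(k if k is not None else pruned.n_features, pruned.n_features)
        subset = select_top_k(ranking, k)
        selected = pruned.subset_features(subset.kept)
        forest = params.make_forest(selected.n_features)
        forest.fit(selected.values, selected.labels)
        return RFLDAResults(
            model=self,
            params=params,
            negatives=negatives,
            scaler=scaler,
            removed_features=removed,
            ranking=ranking,
            accuracy_curve=curve,
            subset=subset,
            forest=forest,
        )


@dataclass
class RFLDAResults:
    """Fitted pipeline state: ranking, selection, scaler and final forest."""

    model: RFLDA
    params: ForestParams
    negatives: list[Pair]
    scaler: FeatureScaler
    removed_features: tuple[str, ...]
    ranking: ImportanceRanking
    accuracy_curve: AccuracyCurve | None
    subset: FeatureSubset
    forest: object

    def score_pairs(self, pairs: Sequence[Pair]) -> np.ndarray:
        """Association scores in [0, 1] for arbitrary pairs."""
        raw = build_sample_matrix(
            pairs, self.model.matrices, mask_self=self.model.mask_self
        )
        scaled = self.scaler.transform(raw)
        selected = scaled.subset_features(self.subset.kept)
        return np.clip(self.forest.predict(selected.values), 0.0, 1.0)

    def predict(
        self, disease: str | None = None, top_k: int = 50
    ) -> pd.DataFrame:
        """Ranked unconfirmed candidates, per disease (or one disease).

        Returns at most ``top_k`` rows per disease, score descending with
        name tie-break — the layout of the published top-50 table.
        """
        matrices = self.model.matrices
        diseases = [disease] if disease is not None else list(matrices.diseases)
        if disease is not None and disease not in matrices.diseases:
            raise KeyError(f"unknown disease {disease!r}")
        known = set(self.model.ld.pairs())
        pairs = [
            (l, d)
            for d in diseases
            for l in matrices.lncrnas
            if (l, d) not in known
        ]
        scores = self.score_pairs(pairs)
        frame = pd.DataFrame(
            {
                "disease": [d for _, d in pairs],
                "lncRNA": [l for l, _ in pairs],
                "score": scores,
            }
        )
        return (
            frame.sort_values(
                ["disease", "score", "lncRNA"], ascending=[True, False, True]
            )
            .groupby("disease", sort=True)
            .head(top_k)
            .reset_index(drop=True)
        )

    def cross_validate(self, folds: int = 5, repetitions: int = 10, **kwargs) -> CVResult:
        """Run the repeated k-fold protocol with this fit's selected features."""
        kwargs.setdefault("feature_subset", self.subset)
        kwargs.setdefault("mask_self", self.model.mask_self)
        kwargs.setdefault("params", self.params)
        kwargs.setdefault("seed", self.params.seed)
        return cross_validate(
            self.model.matrices, folds=folds, repetitions=repetitions, **kwargs
        )

    def case_study(self, disease: str, top_k: int = 15) -> pd.DataFrame:
        """Hold-out ranking for one disease (all its associations removed)."""
        return case_study(
            disease,
            self.model.matrices,
            params=self.params,
            top_k=top_k,
            mask_self=self.model.mask_self,
            feature_subset=self.subset,
            seed=self.params.seed,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        matrices = self.model.matrices
        n_l, n_d, n_m = (
            len(matrices.lncrnas),
            len(matrices.diseases),
            len(matrices.mirnas),
        )
        lines = [
            "Random-forest lncRNA-disease association model",
            "=" * 54,
            f"lncRNAs: {n_l}   diseases: {n_d}   miRNAs: {n_m}",
            f"known associations (positives): {len(self.model.ld.pairs())}",
            f"sampled negatives:              {len(self.negatives)}",
            f"feature vector width:           {2 * (n_l + n_d + n_m)}",
            f"all-zero features removed:      {len(self.removed_features)}",
            f"importance runs averaged:       {self.ranking.n_runs}",
            f"features selected (k):          {len(self.subset.kept)}",
            f"trees: {self.params.n_trees}   mtry: "
            f"{self.params.resolve_mtry(len(self.subset.kept))}   "
            f"seed: {self.params.seed}",
            f"self-association masking:       {'on' if self.model.mask_self else 'off'}",
        ]
        if self.accuracy_curve is not None:
            lines.append(
                f"accuracy sweep best k:          {self.accuracy_curve.best_k} "
                f"(accuracy {max(self.accuracy_curve.accuracy):.4f})"
            )
        lines.append("-" * 54)
        lines.append("top features by mean importance:")
        for rank, (fid, score) in enumerate(
            zip(self.ranking.feature_ids[:10], self.ranking.mean_scores[:10]), 1
        ):
            lines.append(f"  {rank:>2}. {fid:<30} {score:.6f}")
        return "\n".join(lines)

    def plot_importance(self, top: int = 20, ax=None):
        """Horizontal bar plot of the top mean importance scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * top + 1))
        names = self.ranking.feature_ids[:top][::-1]
        vals = self.ranking.mean_scores[:top][::-1]
        ax.barh(range(len(names)), vals)
        ax.set_yticks(range(len(names)), names, fontsize=7)
        ax.set_xlabel("mean OOB permutation importance")
        return ax

    def plot_accuracy_curve(self, ax=None):
        """Accuracy vs number of selected features (requires a sweep)."""
        import matplotlib.pyplot as plt

        if self.accuracy_curve is None:
            raise ValueError("fit was run without a k sweep")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.accuracy_curve.ks, self.accuracy_curve.accuracy, marker="o")
        ax.axvline(self.accuracy_curve.best_k, ls="--", color="grey")
        ax.set_xlabel("number of selected features")
        ax.set_ylabel("cross-validated accuracy")
        return ax
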