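"""Feature assembly for lncRNA-disease pair samples.

Each sample is an (lncRNA, disease) pair described by the concatenation of
six blocks, in fixed order:

    LL row      - the lncRNA's similarity to every lncRNA        (n_L wide)
    LD-row      - the lncRNA's association with every disease    (n_D wide)
    LM          - the lncRNA's interaction with every miRNA      (n_M wide)
    LD-col      - the disease's association with every lncRNA    (n_L wide)
    DD          - the disease's similarity to every disease      (n_D wide)
    MD          - the disease's association with every miRNA     (n_M wide)

so the full vector has width 2*(n_L + n_D + n_M) -- 2294 at the reference
scale of 240 lncRNAs, 412 diseases and 495 miRNAs, 1147 per entity.
Feature names carry their block and source entity (``LD-row:<disease>``)
so any selected feature can be audited.

Note the LD-row block contains the pair's own association cell LD(l, d),
and the LD-col block contains it again: with labels defined from LD this
is label leakage.  The faithful mode keeps both cells; ``mask_self=True``
zeroes the two occurrences per row for honest evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AssociationMatrix
from .similarity import SimilarityMatrix

__all__ = [
    "FeatureMatrices",
    "SampleMatrix",
    "FeatureScaler",
    "feature_names",
    "assemble_feature_vector",
    "build_sample_matrix",
    "normalize_features",
    "drop_allzero_features",
]


@dataclass(frozen=True)
class FeatureMatrices:
    """The five input matrices sharing consistent entity axes."""

    ll: SimilarityMatrix  # lncRNA x lncRNA
    ld: AssociationMatrix  # lncRNA x disease
    lm: AssociationMatrix  # lncRNA x miRNA
    dd: SimilarityMatrix  # disease x disease
    md: AssociationMatrix  # miRNA x disease

    def __post_init__(self) -> None:
        if self.ll.ids != self.ld.row_ids or self.ld.row_ids != self.lm.row_ids:
            raise ValueError("lncRNA axes of LL, LD and LM disagree")
        if self.dd.ids != self.ld.col_ids or self.ld.col_ids != self.md.col_ids:
            raise ValueError("disease axes of DD, LD and MD disagree")
        if self.lm.col_ids != self.md.row_ids:
            raise ValueError("miRNA axes of LM and MD disagree")

    @property
    def lncrnas(self) -> tuple[str, ...]:
        return self.ld.row_ids

    @property
    def diseases(self) -> tuple[str, ...]:
        return self.ld.col_ids

    @property
    def mirnas(self) -> tuple[str, ...]:
        return self.lm.col_ids

    @property
    def n_features(self) -> int:
        return 2 * (len(self.lncrnas) + len(self.diseases) + len(self.mirnas))

    def all_pairs(self) -> list[tuple[str, str]]:
        return [(l, d) for l in self.lncrnas for d in self.diseases]


def feature_names(matrices: FeatureMatrices) -> tuple[str, ...]:
    """Ordered feature identifiers, ``<block>:<entity>`` per column."""
    return tuple(
        [f"LL:{l}" for l in matrices.lncrnas]
        + [f"LD-row:{d}" for d in matrices.diseases]
        + [f"LM:{m}" for m in matrices.mirnas]
        + [f"LD-col:{l}" for l in matrices.lncrnas]
        + [f"DD:{d}" for d in matrices.diseases]
        + [f"MD:{m}" for m in matrices.mirnas]
    )


@dataclass(frozen=True)
class SampleMatrix:
    """Rows = lncRNA-disease pairs, columns = named features, optional labels."""

    pair_ids: tuple[tuple[str, str], ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.pair_ids), len(self.feature_ids)):
            raise ValueError(
                f"value shape {values.shape} does not match "
                f"({len(self.pair_ids)} pairs, {len(self.feature_ids)} features)"
            )
        object.__setattr__(self, "values", values)
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=float)
            if labels.shape != (len(self.pair_ids),):
                raise ValueError("labels must be one value per pair")
            object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return len(self.pair_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def with_values(self, values: np.ndarray) -> "SampleMatrix":
        return SampleMatrix(self.pair_ids, self.feature_ids, values, self.labels)

    def subset_features(self, kept: Sequence[str]) -> "SampleMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in kept if f not in index]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        cols = [index[f] for f in kept]
        return SampleMatrix(
            self.pair_ids, tuple(kept), self.values[:, cols], self.labels
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.feature_ids))
        frame.insert(0, "lncRNA", [p[0] for p in self.pair_ids])
        frame.insert(1, "disease", [p[1] for p in self.pair_ids])
        if self.labels is not None:
            frame["label"] = self.labels
        return frame


def assemble_feature_vector(
    l_idx: int,
    d_idx: int,
    matrices: FeatureMatrices,
    mask_self: bool = False,
) -> np.ndarray:
    """The feature vector of the pair (lncRNA ``l_idx``, disease ``d_idx``)."""
    n_l, n_d = len(matrices.lncrnas), len(matrices.diseases)
    if not 0 <= l_idx < n_l:
        raise IndexError(f"lncRNA index {l_idx} out of range")
    if not 0 <= d_idx < n_d:
        raise IndexError(f"disease index {d_idx} out of range")
    vector = np.concatenate(
        [
            matrices.ll.values[l_idx],
            matrices.ld.values[l_idx].astype(float),
            matrices.lm.values[l_idx].astype(float),
            matrices.ld.values[:, d_idx].astype(float),
            matrices.dd.values[d_idx],
            matrices.md.values[:, d_idx].astype(float),
        ]
    )
    if mask_self:
        n_m = len(matrices.mirnas)
        vector[n_l + d_idx] = 0.0  # LD-row block, own disease
        vector[n_l + n_d + n_m + l_idx] = 0.0  # LD-col block, own lncRNA
    return vector


def build_sample_matrix(
    pairs: Sequence[tuple[str, str]],
    matrices: FeatureMatrices,
    labels: Sequence[float] | None = None,
    mask_self: bool = False,
) -> SampleMatrix:
    """Assemble the sample matrix for the given pairs, in input order."""
    if len(pairs) == 0:
        raise ValueError("pair list is empty")
    l_index = {l: i for i, l in enumerate(matrices.lncrnas)}
    d_index = {d: i for i, d in enumerate(matrices.diseases)}
    try:
        l_idx = np.array([l_index[l] for l, _ in pairs])
        d_idx = np.array([d_index[d] for _, d in pairs])
    except KeyError as exc:
        raise KeyError(f"unknown entity in pair list: {exc.args[0]!r}") from None

    ld = matrices.ld.values.astype(float)
    values = np.hstack(
        [
            matrices.ll.values[l_idx],
            ld[l_idx],
            matrices.lm.values.astype(float)[l_idx],
            ld.T[d_idx],
            matrices.dd.values[d_idx],
            matrices.md.values.astype(float).T[d_idx],
        ]
    )
    if mask_self:
        n_l, n_d, n_m = (
            len(matrices.lncrnas),
            len(matrices.diseases),
            len(matrices.mirnas),
        )
        rows = np.arange(len(pairs))
        values[rows, n_l + d_idx] = 0.0
        values[rows, n_l + n_d + n_m + l_idx] = 0.0
    return SampleMatrix(
        pair_ids=tuple((l, d) for l, d in pairs),
        feature_ids=feature_names(matrices),
        values=values,
        labels=None if labels is None else np.asarray(labels, dtype=float),
    )


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature min/max statistics, fitted on training samples.

    Held-out samples are scaled with the *training* minima and maxima;
    constant training features map to 0.
    """

    feature_ids: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, samples: SampleMatrix) -> "FeatureScaler":
        if samples.n_samples < 1:
            raise ValueError("need at least one sample to fit normalization")
        return cls(
            feature_ids=samples.feature_ids,
            mins=samples.values.min(axis=0),
            maxs=samples.values.max(axis=0),
        )

    def transform(self, samples: SampleMatrix) -> SampleMatrix:
        if samples.feature_ids != self.feature_ids:
            raise ValueError("feature ids do not match normalization statistics")
        span = self.maxs - self.mins
        scaled = np.zeros_like(samples.values)
        varying = span > 0
        scaled[:, varying] = (
            samples.values[:, varying] - self.mins[varying]
        ) / span[varying]
        return samples.with_values(np.clip(scaled, 0.0, 1.0))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_ids": list(self.feature_ids),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureScaler":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_ids=tuple(payload["feature_ids"]),
            mins=np.asarray(payload["mins"], dtype=float),
            maxs=np.asarray(payload["maxs"], dtype=float),
        )


def normalize_features(
    samples: SampleMatrix, scaler: FeatureScaler | None = None
) -> tuple[SampleMatrix, FeatureScaler]:
    """Min-max scale each feature to [0, 1].

    With no ``scaler`` the statistics are fitted on ``samples`` itself
    (training mode); passing a fitted scaler applies training statistics to
    held-out samples.  Scaling an already-scaled matrix with its own
    statistics is the identity.
    """
    if scaler is None:
        scaler = FeatureScaler.fit(samples)
    return scaler.transform(samples), scaler


def drop_allzero_features(
    samples: SampleMatrix,
) -> tuple[SampleMatrix, tuple[str, ...]]:
    """Remove features that are 0 in every row; returns (matrix, removed ids).

    The removed-id tuple doubles as a persistent mask: re-apply it to later
    sample matrices with :meth:`SampleMatrix.subset_features` on the kept set.
    """
    dead = ~samples.values.any(axis=0)
    removed = tuple(f for f, d in zip(samples.feature_ids, dead) if d)
    if not removed:
        return samples, ()
    kept = [f for f, d in zip(samples.feature_ids, dead) if not d]
    return samples.subset_features(kept), removed
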