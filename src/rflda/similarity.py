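"""Disease semantic similarity and lncRNA functional similarity.

Disease similarity follows Wang's DAG-based method: a disease ``D`` is
represented by the directed acyclic graph of itself plus its IS_A ancestors,
each ancestor ``d`` contributing a semantic score

    DC_D(D) = 1,
    DC_D(d) = max{ delta * DC_D(d') : d' a child of d within the DAG },

with attenuation ``delta`` (0.5 by default).  The semantic value
``DV(D)`` is the sum of contributions, and the similarity of two diseases is
the contribution mass of their shared DAG nodes relative to their combined
semantic values.

lncRNA functional similarity is the best-match average of disease semantic
similarities between the two lncRNAs' associated-disease sets: each disease
in either set is matched to its most similar disease in the other set and
the matches are averaged over both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AssociationMatrix, OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseDAG",
    "SimilarityMatrix",
    "build_dag",
    "semantic_similarity",
    "disease_similarity_matrix",
    "functional_similarity",
    "lncrna_similarity_matrix",
]


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease term, its ancestor closure and per-node semantic contributions."""

    root: str
    contributions: dict[str, float]  # node -> DC_root(node), in (0, 1]
    in_ontology: bool = True

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.contributions)

    @property
    def semantic_value(self) -> float:
        """DV(root): the summed contribution of every node in the DAG."""
        return float(sum(self.contributions.values()))


def build_dag(term: str, ontology: OntologyGraph, delta: float = 0.5) -> DiseaseDAG:
    """Build the semantic DAG of ``term`` with attenuation ``delta``.

    A disease absent from the ontology yields the single-node self DAG and
    is flagged via ``in_ontology=False`` (its cross-similarity to every
    other disease is 0, its self-similarity 1).
    """
    if not 0 < delta <= 1:
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    if term not in ontology:
        logger.warning("disease %r missing from ontology; using self DAG", term)
        return DiseaseDAG(root=term, contributions={term: 1.0}, in_ontology=False)

    nodes = ontology.ancestors(term)
    # children restricted to the DAG: reverse of the IS_A edges within `nodes`
    children: dict[str, list[str]] = {n: [] for n in nodes}
    for child in nodes:
        for parent in ontology.parents[child]:
            if parent in nodes:
                children[parent].append(child)

    contributions: dict[str, float] = {}

    def contribution(node: str) -> float:
        if node in contributions:
            return contributions[node]
        if node == term:
            value = 1.0
        else:
            # every non-root node of the closure has at least one child in it
            value = max(delta * contribution(c) for c in children[node])
        contributions[node] = value
        return value

    for node in nodes:
        contribution(node)
    return DiseaseDAG(root=term, contributions=contributions)


def semantic_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG) -> float:
    """Shared-contribution similarity of two disease DAGs, in [0, 1]."""
    shared = dag_i.nodes & dag_j.nodes
    if not shared:
        return 0.0
    numerator = sum(
        dag_i.contributions[d] + dag_j.contributions[d] for d in shared
    )
    value = numerator / (dag_i.semantic_value + dag_j.semantic_value)
    return float(min(1.0, max(0.0, value)))


@dataclass(frozen=True)
class SimilarityMatrix:
    """A symmetric similarity matrix over one named entity axis."""

    ids: tuple[str, ...]
    values: np.ndarray  # float64, square, symmetric, entries in [0, 1]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in similarity matrix")
        if values.shape != (n, n):
            raise ValueError(f"expected square shape ({n}, {n}), got {values.shape}")
        if not np.allclose(values, values.T):
            raise ValueError("similarity matrix must be symmetric")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(values, 0.0, 1.0))

    def index(self, name: str) -> int:
        try:
            return self.ids.index(name)
        except ValueError:
            raise KeyError(f"unknown entity {name!r}") from None

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=tuple(str(i) for i in df.index), values=df.to_numpy(dtype=float))


def disease_similarity_matrix(
    diseases: Sequence[str], ontology: OntologyGraph, delta: float = 0.5
) -> SimilarityMatrix:
    """Pairwise semantic similarity over an ordered disease list."""
    if len(diseases) == 0:
        raise ValueError("disease list is empty")
    dags = [build_dag(d, ontology, delta) for d in diseases]
    n = len(dags)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = semantic_similarity(dags[i], dags[j])
    return SimilarityMatrix(ids=tuple(diseases), values=values)


def functional_similarity(
    dg_a: frozenset[str] | set[str],
    dg_b: frozenset[str] | set[str],
    dd: SimilarityMatrix,
) -> float:
    """Best-match-average similarity of two associated-disease sets.

    An lncRNA with no known disease associations has an undefined
    functional profile; its similarity is defined as 0 (logged, not an
    error) so the full lncRNA similarity matrix stays dense.
    """
    if not dg_a or not dg_b:
        logger.warning("empty associated-disease set; functional similarity set to 0")
        return 0.0
    ia = [dd.index(d) for d in sorted(dg_a)]
    ib = [dd.index(d) for d in sorted(dg_b)]
    block = dd.values[np.ix_(ia, ib)]
    value = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
        len(ia) + len(ib)
    )
    return float(min(1.0, max(0.0, value)))


def lncrna_similarity_matrix(
    ld: AssociationMatrix, dd: SimilarityMatrix
) -> SimilarityMatrix:
    """Functional similarity over all lncRNAs of an lncRNA-disease matrix.

    Requires every disease of ``ld``'s column axis to be present in ``dd``.
    Diagonal entries are 1 for lncRNAs with at least one known association
    and 0 for the (flagged) degenerate ones.
    """
    missing = set(ld.col_ids) - set(dd.ids)
    if missing:
        raise KeyError(f"diseases missing from similarity matrix: {sorted(missing)}")
    col_idx = [dd.index(d) for d in ld.col_ids]
    dd_vals = dd.values[np.ix_(col_idx, col_idx)]
    supports = [np.nonzero(row)[0] for row in ld.values]

    n = len(ld.row_ids)
    values = np.zeros((n, n))
    for a in range(n):
        sa = supports[a]
        if sa.size == 0:
            continue
        values[a, a] = 1.0
        for b in range(a + 1, n):
            sb = supports[b]
            if sb.size == 0:
                continue
            block = dd_vals[np.ix_(sa, sb)]
            values[a, b] = values[b, a] = (
                block.max(axis=1).sum() + block.max(axis=0).sum()
            ) / (sa.size + sb.size)
    return SimilarityMatrix(ids=ld.row_ids, values=np.clip(values, 0.0, 1.0))
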