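"""Readers and writers for association tables, ontologies and prediction output.

All tabular formats are labelled TSV (UTF-8, tab separator, ``.`` decimal):
association matrices carry a header row of column ids and a first column of
row ids; prediction tables have the three columns ``disease``, ``lncRNA``,
``score``.  Ontologies are accepted either as OBO 1.2 files (only ``id``,
``name``, ``is_a`` and ``is_obsolete`` are consumed) or as two-column
``child<TAB>parent`` edge lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "OntologyGraph",
    "FormatError",
    "DimensionError",
    "OntologyError",
    "read_association_matrix",
    "write_association_matrix",
    "read_ontology",
    "write_prediction_table",
]


class FormatError(ValueError):
    """A file violates the binary-matrix TSV contract."""


class DimensionError(ValueError):
    """A matrix does not have the dimensions the caller demanded."""


class OntologyError(ValueError):
    """The parent relation is not a DAG or references unknown terms."""


@dataclass(frozen=True)
class AssociationMatrix:
    """A labelled binary matrix over two named entity axes.

    Rows and columns are identified by entity names (lncRNAs, miRNAs or
    diseases depending on the role the matrix plays); every cell is 0 or 1.
    """

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray  # int8, shape (len(row_ids), len(col_ids))

    def __post_init__(self) -> None:
        if len(self.row_ids) == 0 or len(self.col_ids) == 0:
            raise FormatError("association matrix must have at least one row and column")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise FormatError("duplicate row ids in association matrix")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise FormatError("duplicate column ids in association matrix")
        values = np.asarray(self.values)
        if values.shape != (len(self.row_ids), len(self.col_ids)):
            raise DimensionError(
                f"value shape {values.shape} does not match id axes "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )
        if not np.isin(values, (0, 1)).all():
            raise FormatError("association matrix cells must be 0 or 1")
        object.__setattr__(self, "values", values.astype(np.int8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, name: str) -> int:
        try:
            return self.row_ids.index(name)
        except ValueError:
            raise KeyError(f"unknown row entity {name!r}") from None

    def col_index(self, name: str) -> int:
        try:
            return self.col_ids.index(name)
        except ValueError:
            raise KeyError(f"unknown column entity {name!r}") from None

    def row_support(self, name: str) -> frozenset[str]:
        """Column entities associated with ``name`` (the 1-cells of its row)."""
        row = self.values[self.row_index(name)]
        return frozenset(c for c, v in zip(self.col_ids, row) if v)

    def pairs(self) -> list[tuple[str, str]]:
        """All (row entity, column entity) pairs whose cell is 1."""
        r, c = np.nonzero(self.values)
        return [(self.row_ids[i], self.col_ids[j]) for i, j in zip(r, c)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.col_ids)
        )


@dataclass(frozen=True)
class OntologyGraph:
    """Disease terms and their ``IS_A`` parents, guaranteed acyclic."""

    parents: Mapping[str, frozenset[str]]
    names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parents = {t: frozenset(p) for t, p in self.parents.items()}
        for term, ps in parents.items():
            missing = ps - parents.keys()
            if missing:
                raise OntologyError(
                    f"term {term!r} references unknown parent(s) {sorted(missing)}"
                )
        graph = nx.DiGraph(
            (child, parent) for child, ps in parents.items() for parent in ps
        )
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"IS_A relation contains a cycle: {cycle}")
        object.__setattr__(self, "parents", parents)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """``term`` plus its transitive IS_A closure (the node set S(term))."""
        if term not in self.parents:
            raise KeyError(f"unknown ontology term {term!r}")
        seen: set[str] = set()
        stack = [term]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(self.parents[node])
        return frozenset(seen)


def read_association_matrix(
    path: str | Path,
    expected_rows: int | None = None,
    expected_cols: int | None = None,
) -> AssociationMatrix:
    """Read a labelled binary TSV matrix, failing loudly on malformed input.

    ``expected_rows`` / ``expected_cols`` assert the axis lengths (e.g. 240
    lncRNAs x 412 diseases for the reference lncRNA-disease table); a
    mismatch raises :class:`DimensionError` rather than silently reshaping.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    col_ids = tuple(c.strip() for c in header)
    if len(set(col_ids)) != len(col_ids):
        raise FormatError(f"{path}: duplicate column ids in header")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    row_ids = tuple(str(r).strip() for r in df.index)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    if not np.isin(values, (0.0, 1.0)).all():
        bad = values[~np.isin(values, (0.0, 1.0))][0]
        raise FormatError(f"{path}: non-binary cell value {bad!r}")
    if expected_rows is not None and len(row_ids) != expected_rows:
        raise DimensionError(
            f"{path}: expected {expected_rows} rows, found {len(row_ids)}"
        )
    if expected_cols is not None and len(col_ids) != expected_cols:
        raise DimensionError(
            f"{path}: expected {expected_cols} columns, found {len(col_ids)}"
        )
    return AssociationMatrix(row_ids=row_ids, col_ids=col_ids, values=values)


def write_association_matrix(matrix: AssociationMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def _read_obo(path: Path) -> OntologyGraph:
    graph = obonet.read_obo(path)  # obsolete terms dropped by default
    parents: dict[str, set[str]] = {term: set() for term in graph.nodes}
    names = {
        term: data.get("name", term) for term, data in graph.nodes(data=True)
    }
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
    return OntologyGraph(parents=parents, names=names)


def _read_edge_list(path: Path) -> OntologyGraph:
    parents: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'child<TAB>parent', got {line!r}"
                )
            child, parent = (f.strip() for f in fields)
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
    return OntologyGraph(parents=parents)


def read_ontology(path: str | Path, dialect: str = "obo") -> OntologyGraph:
    """Read an IS_A hierarchy from an OBO file or a child/parent edge list.

    Raises :class:`OntologyError` if the relation contains a cycle and
    ``ValueError`` for an unknown dialect.
    """
    path = Path(path)
    if dialect == "obo":
        return _read_obo(path)
    if dialect == "edge_list":
        return _read_edge_list(path)
    raise ValueError(f"unknown ontology dialect {dialect!r}; use 'obo' or 'edge_list'")


def write_prediction_table(
    table: pd.DataFrame | Iterable[tuple[str, str, float]],
    path: str | Path,
    top_k: int = 50,
) -> pd.DataFrame:
    """Write ranked lncRNA predictions, at most ``top_k`` rows per disease.

    Rows are ordered by disease, then score descending with ties broken by
    lncRNA name ascending, so repeated runs produce byte-identical files.
    Returns the frame actually written.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table, columns=["disease", "lncRNA", "score"])
    if table.empty:
        raise ValueError("prediction table is empty")
    ordered = (
        table.sort_values(
            ["disease", "score", "lncRNA"], ascending=[True, False, True]
        )
        .groupby("disease", sort=True)
        .head(top_k)
        .reset_index(drop=True)
    )
    ordered.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return ordered
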