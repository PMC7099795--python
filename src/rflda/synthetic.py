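"""Self-contained synthetic benchmarks with planted association structure.

The generator emulates the shape of the real inputs: three sparse binary
bipartite matrices (lncRNA-disease, miRNA-disease, lncRNA-miRNA) over
shared entity axes, and a rooted IS_A ontology covering the disease axis.
Entities are assigned to ``n_clusters`` groups; within-cluster pairs
associate with probability ``within_cluster_assoc_prob`` and everything
else with ``background_assoc_prob``, and diseases of one cluster share a
low ontology ancestor while cross-cluster diseases share only the root.
A ``holdout_fraction`` of the within-cluster lncRNA-disease positives is
zeroed in the emitted LD matrix and recorded as *planted truth*, so a
model that exploits the cluster signal can be tested on recovering them.

All generators are pure functions of their configuration (including the
seed): identical inputs give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AssociationMatrix, OntologyGraph, write_association_matrix

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "cluster_assignment",
    "generate_ontology",
    "generate_associations",
    "generate_benchmark",
    "background_pairs",
    "write_benchmark",
    "worked_example_fixture",
]

ROOT = "DO:root"


@dataclass(frozen=True)
class SyntheticConfig:
    """Benchmark dimensions and planted-signal strength.

    Defaults give a desk-scale benchmark: 60 lncRNAs x 40 diseases x 50
    miRNAs in 4 clusters, background density near the real data's ~2-3%
    and a strong within-cluster signal.
    """

    n_lncrna: int = 60
    n_disease: int = 40
    n_mirna: int = 50
    n_clusters: int = 4
    within_cluster_assoc_prob: float = 0.35
    background_assoc_prob: float = 0.02
    dag_depth: int = 3
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lncrna", "n_disease", "n_mirna", "n_clusters"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in (
            "within_cluster_assoc_prob",
            "background_assoc_prob",
            "holdout_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.within_cluster_assoc_prob <= self.background_assoc_prob:
            raise ValueError(
                "within_cluster_assoc_prob must exceed background_assoc_prob"
            )
        if self.dag_depth < 1:
            raise ValueError("dag_depth must be >= 1")

    @property
    def lncrnas(self) -> tuple[str, ...]:
        return tuple(f"lnc{i:03d}" for i in range(self.n_lncrna))

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(f"disease{i:03d}" for i in range(self.n_disease))

    @property
    def mirnas(self) -> tuple[str, ...]:
        return tuple(f"mir{i:03d}" for i in range(self.n_mirna))


def cluster_assignment(n: int, n_clusters: int) -> np.ndarray:
    """Contiguous near-equal cluster blocks: item i -> i * k // n."""
    return (np.arange(n) * n_clusters) // n


def generate_ontology(config: SyntheticConfig) -> OntologyGraph:
    """A rooted IS_A DAG over the disease axis with cluster structure.

    Each cluster owns a chain of ``dag_depth - 1`` internal terms hanging
    off the root; its diseases attach to the deepest chain term (some with
    a second, shallower parent, so multi-parent paths are exercised).
    With ``dag_depth=1`` every disease is a direct child of the root (a
    star: all off-diagonal similarities equal).
    """
    rng = np.random.default_rng(config.seed)
    parents: dict[str, set[str]] = {ROOT: set()}
    clusters = cluster_assignment(config.n_disease, config.n_clusters)
    chains: list[list[str]] = []
    for c in range(config.n_clusters):
        chain = []
        for level in range(config.dag_depth - 1):
            term = f"DO:c{c}.l{level + 1}"
            parents[term] = {chain[-1] if chain else ROOT}
            chain.append(term)
        chains.append(chain)
    for disease, c in zip(config.diseases, clusters):
        chain = chains[c]
        if not chain:
            parents[disease] = {ROOT}
            continue
        ps = {chain[-1]}
        if len(chain) > 1 and rng.random() < 0.25:
            ps.add(chain[int(rng.integers(0, len(chain) - 1))])
        parents[disease] = ps
    return OntologyGraph(parents=parents)


def _planted_matrix(
    rng: np.random.Generator,
    row_clusters: np.ndarray,
    col_clusters: np.ndarray,
    within: float,
    background: float,
) -> np.ndarray:
    same = row_clusters[:, None] == col_clusters[None, :]
    prob = np.where(same, within, background)
    return (rng.random(prob.shape) < prob).astype(np.int8)


@dataclass(frozen=True)
class SyntheticBundle:
    """A generated benchmark: matrices, ontology and the planted truth."""

    config: SyntheticConfig
    ontology: OntologyGraph
    ld: AssociationMatrix
    md: AssociationMatrix
    lm: AssociationMatrix
    truth: tuple[tuple[str, str], ...]  # held-out true LD pairs, zeroed in ld


def generate_associations(
    config: SyntheticConfig, ontology: OntologyGraph
) -> tuple[AssociationMatrix, AssociationMatrix, AssociationMatrix, tuple]:
    """Draw LD/MD/LM with planted cluster structure; returns the truth too.

    The truth tuple lists the within-cluster LD positives that were zeroed
    in the emitted matrix (a ``holdout_fraction`` of them, drawn without
    replacement); they appear nowhere in LD.
    """
    missing = set(config.diseases) - set(ontology.terms)
    if missing:
        raise ValueError(f"ontology does not cover diseases: {sorted(missing)[:5]}")
    rng = np.random.default_rng(config.seed + 1)
    lc = cluster_assignment(config.n_lncrna, config.n_clusters)
    dc = cluster_assignment(config.n_disease, config.n_clusters)
    mc = cluster_assignment(config.n_mirna, config.n_clusters)
    within, back = config.within_cluster_assoc_prob, config.background_assoc_prob

    ld_values = _planted_matrix(rng, lc, dc, within, back)
    md_values = _planted_matrix(rng, mc, dc, within, back)
    lm_values = _planted_matrix(rng, lc, mc, within, back)

    within_pos = [
        (i, j)
        for i, j in zip(*np.nonzero(ld_values))
        if lc[i] == dc[j]
    ]
    n_holdout = int(round(config.holdout_fraction * len(within_pos)))
    picked = rng.choice(len(within_pos), size=n_holdout, replace=False)
    truth = []
    for p in sorted(picked):
        i, j = within_pos[p]
        ld_values[i, j] = 0
        truth.append((config.lncrnas[i], config.diseases[j]))

    ld = AssociationMatrix(config.lncrnas, config.diseases, ld_values)
    md = AssociationMatrix(config.mirnas, config.diseases, md_values)
    lm = AssociationMatrix(config.lncrnas, config.mirnas, lm_values)
    return ld, md, lm, tuple(truth)


def background_pairs(bundle: SyntheticBundle) -> list[tuple[str, str]]:
    """Cross-cluster lncRNA-disease pairs with no observed association.

    These are the benchmark's genuine negatives: pairs generated at the
    background rate.  They are the reference class for planted-truth
    recovery, because *within*-cluster unlabelled pairs are exchangeable
    with the planted hold-outs by construction (association draws are
    independent given cluster membership), so no scorer can separate the
    two classes and including them only adds an irreducible tie mass.
    """
    config = bundle.config
    lc = cluster_assignment(config.n_lncrna, config.n_clusters)
    dc = cluster_assignment(config.n_disease, config.n_clusters)
    observed = set(bundle.ld.pairs())
    return [
        (l, d)
        for i, l in enumerate(config.lncrnas)
        for j, d in enumerate(config.diseases)
        if lc[i] != dc[j] and (l, d) not in observed
    ]


def generate_benchmark(config: SyntheticConfig = SyntheticConfig()) -> SyntheticBundle:
    """Ontology plus association matrices in one deterministic bundle."""
    ontology = generate_ontology(config)
    ld, md, lm, truth = generate_associations(config, ontology)
    return SyntheticBundle(
        config=config, ontology=ontology, ld=ld, md=md, lm=lm, truth=truth
    )


def write_benchmark(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the same formats the readers accept.

    Emits ``ld.tsv``, ``md.tsv``, ``lm.tsv`` (labelled binary TSV), an
    ``ontology.tsv`` child/parent edge list, and ``truth.tsv`` listing the
    held-out pairs for recovery evaluation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ld": out / "ld.tsv",
        "md": out / "md.tsv",
        "lm": out / "lm.tsv",
        "ontology": out / "ontology.tsv",
        "truth": out / "truth.tsv",
    }
    write_association_matrix(bundle.ld, paths["ld"])
    write_association_matrix(bundle.md, paths["md"])
    write_association_matrix(bundle.lm, paths["lm"])
    with open(paths["ontology"], "w", encoding="utf-8") as fh:
        for child in sorted(bundle.ontology.parents):
            for parent in sorted(bundle.ontology.parents[child]):
                fh.write(f"{child}\t{parent}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("lncRNA\tdisease\n")
        for l, d in bundle.truth:
            fh.write(f"{l}\t{d}\n")
    return paths


def worked_example_fixture() -> dict:
    """Tiny hand-computable objects shared by the documentation and tests.

    Contains a three-node chain DAG (semantic value 1.75 at delta 0.5), a
    diamond DAG (semantic value 2.25), a sibling disease pair (semantic
    similarity 1/3) and a three-lncRNA functional-similarity toy whose
    {d1,d2}-vs-{d1} comparison gives 7/9.  Expected values are embedded as
    metadata next to each object.
    """
    chain = OntologyGraph(parents={"D": {"p"}, "p": {"g"}, "g": set()})
    diamond = OntologyGraph(
        parents={"D": {"p1", "p2"}, "p1": {"g"}, "p2": {"g"}, "g": set()}
    )
    siblings = OntologyGraph(parents={"d1": {"p"}, "d2": {"p"}, "p": set()})
    ls_ld = AssociationMatrix(
        row_ids=("la", "lb", "lc"),
        col_ids=("d1", "d2"),
        values=np.array([[1, 1], [1, 0], [0, 1]]),
    )
    return {
        "delta": 0.5,
        "chain": {
            "ontology": chain,
            "term": "D",
            "expected_contributions": {"D": 1.0, "p": 0.5, "g": 0.25},
            "expected_dv": 1.75,
        },
        "diamond": {
            "ontology": diamond,
            "term": "D",
            "expected_contributions": {"D": 1.0, "p1": 0.5, "p2": 0.5, "g": 0.25},
            "expected_dv": 2.25,
        },
        "siblings": {
            "ontology": siblings,
            "terms": ("d1", "d2"),
            "expected_ds": 1.0 / 3.0,
        },
        "ls_toy": {
            "ontology": siblings,
            "ld": ls_ld,
            "expected_ls": {
                ("la", "lb"): 7.0 / 9.0,
                ("la", "lc"): 7.0 / 9.0,
                ("lb", "lc"): 1.0 / 3.0,
            },
        },
    }
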