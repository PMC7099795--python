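import numpy as np
import pytest

from rflda.features import FeatureMatrices
from rflda.similarity import disease_similarity_matrix, lncrna_similarity_matrix
from rflda.synthetic import SyntheticConfig, generate_benchmark, worked_example_fixture


@pytest.fixture(scope="session")
def worked():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted benchmark shared by model-level tests."""
    config = SyntheticConfig(
        n_lncrna=20, n_disease=12, n_mirna=15, n_clusters=3, seed=7
    )
    return generate_benchmark(config)


def bundle_matrices(bundle) -> FeatureMatrices:
    dd = disease_similarity_matrix(
        list(bundle.ld.col_ids), bundle.ontology, delta=0.5
    )
    ll = lncrna_similarity_matrix(bundle.ld, dd)
    return FeatureMatrices(ll=ll, ld=bundle.ld, lm=bundle.lm, dd=dd, md=bundle.md)


@pytest.fixture(scope="session")
def small_matrices(small_bundle):
    return bundle_matrices(small_bundle)


def random_dag_parents(seed: int, max_nodes: int = 12) -> dict[str, set[str]]:
    """A random parent map guaranteed acyclic (edges go to lower indices)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    parents: dict[str, set[str]] = {"t0": set()}
    for i in range(1, n):
        k = int(rng.integers(0, min(i, 3) + 1))
        chosen = rng.choice(i, size=k, replace=False) if k else []
        parents[f"t{i}"] = {f"t{j}" for j in chosen}
    return parents
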