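import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from circsc.io_model import CellAnnotation, CountMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_gene_matrix() -> CountMatrix:
    """4 genes x 3 cells; gene 'mt-1' is mitochondrial."""
    values = np.array(
        [
            [3, 0, 10],
            [0, 5, 10],
            [1, 0, 0],  # mt-1
            [0, 0, 20],
        ]
    )
    return CountMatrix(
        sp.csr_matrix(values), ["g1", "g2", "mt-1", "g4"], ["cA", "cB", "cC"], "gene"
    )


@pytest.fixture
def small_circ_matrix() -> CountMatrix:
    values = np.array([[2, 0, 0], [1, 1, 0], [0, 0, 5]])
    return CountMatrix(
        sp.csr_matrix(values), ["circ1", "circ2", "circ3"], ["cA", "cB", "cC"], "circ"
    )


@pytest.fixture
def small_annotations() -> list[CellAnnotation]:
    return [
        CellAnnotation("cA", "s1", "brain", "GABAergic neurons", tumor_status="normal"),
        CellAnnotation("cB", "s1", "brain", "microglia", tumor_status="normal"),
        CellAnnotation("cC", "s2", "blood", "T cells", tumor_status="normal"),
    ]


def random_count_matrix(rng: np.random.Generator, kind: str = "gene") -> CountMatrix:
    n_feat = int(rng.integers(1, 12))
    n_cell = int(rng.integers(1, 12))
    dense = rng.poisson(0.8, size=(n_feat, n_cell))
    return CountMatrix(
        sp.csr_matrix(dense),
        [f"f{i}" for i in range(n_feat)],
        [f"c{j}" for j in range(n_cell)],
        kind,
    )
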