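import numpy as np
import networkx as nx
import pytest

from scle.expression_io import ExpressionMatrix, StageSeries
from scle.network import TemplateNetwork


def make_series(values, stage_sizes, genes=None, min_cells=3):
    """StageSeries straight from an array (already in log units)."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    assert sum(stage_sizes) == n
    genes = list(genes) if genes is not None else [f"g{i:02d}" for i in range(m)]
    cells = [f"c{j:03d}" for j in range(n)]
    stage_order = [f"S{t}" for t in range(1, len(stage_sizes) + 1)]
    stage_of_cell = {}
    j = 0
    for stage, size in zip(stage_order, stage_sizes):
        for _ in range(size):
            stage_of_cell[cells[j]] = stage
            j += 1
    matrix = ExpressionMatrix(
        genes=tuple(genes), cells=tuple(cells), values=values, normalized=True
    )
    return StageSeries(
        matrix=matrix,
        stage_of_cell=stage_of_cell,
        stage_order=tuple(stage_order),
        min_cells=min_cells,
    )


def make_single_stage_series(values, min_cells=3):
    """Two-stage series whose S2 duplicates S1, for single-stage score checks."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    return make_series(np.hstack([values, values]), [n, n], min_cells=min_cells)


def make_network(edges, provenance=None):
    g = nx.Graph()
    g.add_edges_from(edges)
    return TemplateNetwork(graph=g, provenance=provenance or {"source": "test"})


def random_instance(rng, max_genes=10, n_stages=None, cells_per_stage=None):
    """A random connected-ish network plus a matching random StageSeries."""
    m = int(rng.integers(5, max_genes + 1))
    n_stages = n_stages or int(rng.integers(2, 5))
    sizes = [
        int(cells_per_stage or rng.integers(8, 13)) for _ in range(n_stages)
    ]
    while True:
        g = nx.gnp_random_graph(m, 0.4, seed=int(rng.integers(0, 2**31 - 1)))
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_edges() >= 1:
            break
    names = {i: f"g{i:02d}" for i in g.nodes}
    network = make_network((names[a], names[b]) for a, b in g.edges)
    values = rng.normal(size=(m, sum(sizes)))
    # a few constant rows exercise the zero-variance conventions
    if rng.random() < 0.3:
        values[int(rng.integers(0, m))] = 1.0
    series = make_series(values, sizes)
    return series, network


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
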