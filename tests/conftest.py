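import numpy as np
import pytest

from spacomod import ScRnaDataset, SpatialDataset, SynthSpec, generate, select_explicit


@pytest.fixture(scope="session")
def synth_pair():
    """Default synthetic SRT + pseudo-scRNA pair with ground truth."""
    return generate(SynthSpec(seed=7))


@pytest.fixture(scope="session")
def srt(synth_pair):
    return synth_pair[0]


@pytest.fixture(scope="session")
def scrna(synth_pair):
    return synth_pair[1]


@pytest.fixture(scope="session")
def truth(synth_pair):
    return synth_pair[2]


@pytest.fixture
def all_cells(srt):
    return select_explicit(srt, list(range(srt.n_cells)))


def make_spatial(expr, coords, genes=None, annotations=None):
    """Hand-built SpatialDataset for small arithmetic fixtures."""
    expr = np.asarray(expr, dtype=float)
    n, g = expr.shape
    return SpatialDataset(
        expression=expr,
        gene_symbols=genes or [f"g{j}" for j in range(g)],
        cell_ids=[f"c{i}" for i in range(n)],
        annotations=annotations or {},
        coordinates=np.asarray(coords, dtype=float),
    )


def make_scrna(expr, genes=None, annotations=None):
    expr = np.asarray(expr, dtype=float)
    n, g = expr.shape
    return ScRnaDataset(
        expression=expr,
        gene_symbols=genes or [f"g{j}" for j in range(g)],
        cell_ids=[f"c{i}" for i in range(n)],
        annotations=annotations or {},
    )
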