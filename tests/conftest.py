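import numpy as np
import pytest

from longdbn.core_io import DynamicSeries, Layer, OmicsDataset
from longdbn.synthetic import SimulationConfig, generate


@pytest.fixture
def tiny_dataset() -> OmicsDataset:
    """Two subjects, two taxa/metabolites, hand-written values."""
    taxa = Layer("taxa", "taxon", True, ["A", "B"], {
        "s1": DynamicSeries([0.0, 7.0, 14.0], [[2.0, 2.0], [1.0, 3.0],
                                               [4.0, 0.0]]),
        "s2": DynamicSeries([0.0, 10.0], [[1.0, 1.0], [0.5, 1.5]]),
    })
    mets = Layer("metabolites", "metabolite", True, ["m1", "m2"], {
        "s1": DynamicSeries([0.0, 7.0, 14.0], [[1.0, 0.0], [1.0, 1.0],
                                               [1.0, 3.0]]),
        "s2": DynamicSeries([0.0, 10.0], [[2.0, 2.0], [2.0, 6.0]]),
    })
    host = Layer("host_genes", "host_gene", False, ["h1"],
                 {"s1": np.array([0.3]), "s2": np.array([-1.2])})
    return OmicsDataset(["s1", "s2"], {"taxa": taxa, "metabolites": mets,
                                       "host_genes": host})


@pytest.fixture(scope="session")
def small_truth():
    """A small generated dataset with known ground truth (raw emission)."""
    cfg = SimulationConfig(n_subjects=10, grid_points=12, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def default_truth():
    """The default-scale generated dataset (50 subjects, 25 grid points)."""
    cfg = SimulationConfig(seed=3)
    return generate(cfg)
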