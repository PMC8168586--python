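import numpy as np
import pandas as pd
import pytest

from capseq.cluster_de import normalize_log
from capseq.grn import impute_capture
from capseq.simulate import SimulationConfig, simulate_prepost
from capseq.types import CountMatrix


@pytest.fixture(scope="session")
def default_sim():
    """One paired pre/post draw at the generator's default conditions."""
    return simulate_prepost(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Imputed matrix and log-normalized views of the default draw."""
    pre, post, truth = default_sim
    imputed = impute_capture(pre, post, truth.panel)
    return {
        "pre": pre, "post": post, "truth": truth, "imputed": imputed,
        "norm_pre": normalize_log(pre), "norm_imputed": normalize_log(imputed),
    }


@pytest.fixture
def small_matrix():
    """3 genes x 2 cells toy with known column sums (3, 6)."""
    counts = np.array([[0, 5], [2, 0], [1, 1]])
    return CountMatrix(["g1", "g2", "g3"], ["c1", "c2"], counts)


def make_matrix(values, genes=None, cells=None, **kw) -> CountMatrix:
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return CountMatrix(genes, cells, values, **kw)
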