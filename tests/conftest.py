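import numpy as np
import pandas as pd
import pytest

from bmptc.io_model import CANONICAL_TIMES, EventKey, ExpressionMatrix
from bmptc.synthetic_data import SimulationConfig, generate_dataset


def make_matrix(values, cell_lines=("L1",), ligand="BMP4", probe_ids=None):
    """Build an ExpressionMatrix from an array shaped (probes, 6*len(cell_lines))."""
    values = np.asarray(values, dtype=float)
    cols = [EventKey(cl, ligand, t).token for cl in cell_lines for t in CANONICAL_TIMES]
    if probe_ids is None:
        probe_ids = [f"p{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=cols))


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study: both ligands, 5 cell lines each, seed 1."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SimulationConfig(seed=2, n_probes=400, group_size=20))
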