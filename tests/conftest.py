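import numpy as np
import pandas as pd
import pytest

from metkinsig import (
    GeneSet,
    KineticExpressionMatrix,
    SimulationConfig,
    simulate_cell_model,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small but fully structured world: fast for most unit tests."""
    return SimulationConfig(
        n_genes=400,
        planted_group_sizes={("down", 10): 30, ("up", 30): 15, ("down", 1440): 15},
        n_patients=150,
        ppi_n_nodes=150,
        ppi_n_edges=600,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_model(small_config):
    matrix, truth = simulate_cell_model(small_config)
    return matrix, truth


@pytest.fixture(scope="session")
def planted_signature(small_model) -> GeneSet:
    _, truth = small_model
    return GeneSet("planted", set(truth.index[truth["is_signature"]]), "ground truth")


def make_matrix(values: np.ndarray, genes, meta_rows) -> KineticExpressionMatrix:
    """Hand-built matrix helper: meta_rows = (sample, cell_line, group, time, rep)."""
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "cell_line", "met_group", "time_min", "replicate"]
    ).set_index("sample_id")
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=meta.index)
    return KineticExpressionMatrix(vals, meta)


@pytest.fixture()
def tiny_timecourse():
    """Two cell lines (one high, one low), 1 replicate, 4 time points, 3 genes.

    Gene g_down drops by exactly 1 from 10 min onward; g_flat is
    constant; g_up rises by 0.5 from 30 min onward. Noise-free.
    """
    rows = []
    for cl, grp in (("h1", "high"), ("l1", "low")):
        for t in (0, 10, 30, 1440):
            rows.append((f"{cl}_t{t}", cl, grp, t, 1))
    base = {"g_down": 5.0, "g_flat": 3.0, "g_up": 7.0}
    values = np.zeros((3, len(rows)))
    for j, (sid, cl, grp, t, rep) in enumerate(rows):
        values[0, j] = base["g_down"] - (1.0 if t >= 10 else 0.0)
        values[1, j] = base["g_flat"]
        values[2, j] = base["g_up"] + (0.5 if t >= 30 else 0.0)
    return make_matrix(values, ["g_down", "g_flat", "g_up"], rows)
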