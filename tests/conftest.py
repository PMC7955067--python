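import numpy as np
import pandas as pd
import pytest

from crisprmerge.data import ScreenMatrix, ScreenMetadata
from crisprmerge.integrate import run_pipeline
from crisprmerge.simulate import SimulationConfig, simulate_dual_screens


@pytest.fixture(scope="session")
def small_cohort():
    """Small two-institute cohort for fast end-to-end checks."""
    cfg = SimulationConfig(
        n_genes=300, n_screens_a=60, n_screens_b=70, n_overlap=40,
        n_lineages=5, seed=11,
    )
    return cfg, *simulate_dual_screens(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale cohort: 1000 genes, 168 overlap lines, 16 lineages."""
    cfg = SimulationConfig(seed=3)
    return cfg, *simulate_dual_screens(cfg)


@pytest.fixture(scope="session")
def integrated_default(default_cohort):
    _cfg, a, b, meta, refs, gt = default_cohort
    return run_pipeline(a, meta, b, meta, pipeline="combat_qn_pc1", refs=refs)


def make_matrix(values, genes=None, screens=None, mask=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    screens = screens or [f"s{j}" for j in range(values.shape[1])]
    return ScreenMatrix(values, genes, screens, mask)


def make_meta(screen_ids, cell_lines=None, batches=None, lineages=None, subtypes=None):
    n = len(screen_ids)
    return ScreenMetadata(pd.DataFrame({
        "screen_id": screen_ids,
        "cell_line_id": cell_lines or [f"cl{i}" for i in range(n)],
        "batch": batches or ["x"] * n,
        "lineage": lineages or ["t0"] * n,
        "subtype": subtypes or [None] * n,
    }))
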