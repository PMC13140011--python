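import numpy as np
import pandas as pd
import pytest

from oatsalt import ExpressionMatrix, SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_triads=40, n_dyads_per_pattern=5, n_singletons_per_subgenome=5,
        n_markers=100, n_accessions=80, n_modules=2, module_size_range=(10, 14),
        seed=11)


@pytest.fixture(scope="session")
def sim(small_config):
    return simulate_all(small_config)


def make_expr(fpkm: pd.DataFrame, design: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Build an ExpressionMatrix whose FPKM equals the given table exactly."""
    if design is None:
        design = pd.DataFrame({
            "sample_id": fpkm.columns,
            "tissue": ["Seed"] * len(fpkm.columns),
            "timepoint_h": [0 if c.endswith("c") else 6 for c in fpkm.columns],
            "replicate": range(1, len(fpkm.columns) + 1),
        }).set_index("sample_id")
    counts = pd.DataFrame(np.ones_like(fpkm, dtype=int),
                          index=fpkm.index, columns=fpkm.columns)
    lengths = pd.Series(1000, index=fpkm.index, name="length_bp")
    expr = ExpressionMatrix(counts, lengths, design)
    expr._fpkm = fpkm.astype(float)
    return expr
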