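import numpy as np
import pandas as pd
import pytest

from coessence import (
    DependencyMatrix,
    FactorSpec,
    LatentFactorDesign,
    simulate_dependency,
)


@pytest.fixture
def toy_dep() -> DependencyMatrix:
    """4 genes × 5 cell lines with one missing entry and known values."""
    data = pd.DataFrame(
        {
            "CL1": [1.0, 4.0, 0.5, 2.0],
            "CL2": [2.0, 3.0, 1.5, np.nan],
            "CL3": [3.0, 2.0, 0.7, 1.0],
            "CL4": [4.0, 1.0, 2.2, 3.0],
            "CL5": [5.0, 0.0, 1.9, 2.5],
        },
        index=["G1", "G2", "G3", "G4"],
    )
    return DependencyMatrix(data)


@pytest.fixture
def module_dep() -> DependencyMatrix:
    """Planted 4-gene co-essential module among 12 background genes."""
    design = LatentFactorDesign(
        n_cell_lines=300,
        factors=[FactorSpec("F1", ["M1", "M2", "M3", "M4"], 1.0, 0.0)],
        noise_sd=0.5,
        seed=11,
        background_genes=[f"B{i}" for i in range(12)],
    )
    dep, _ = simulate_dependency(design)
    return dep


def random_dependency(
    n_genes: int, n_lines: int, seed: int, missing_rate: float = 0.0
) -> DependencyMatrix:
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_lines))
    if missing_rate:
        values[rng.random(values.shape) < missing_rate] = np.nan
    return DependencyMatrix(
        pd.DataFrame(
            values,
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"CL{j}" for j in range(n_lines)],
        )
    )
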