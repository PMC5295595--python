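import numpy as np
import pandas as pd
import pytest

from gxepred import (
    GenotypeMatrix,
    IncidenceMap,
    LineEnvTable,
    PedigreeTable,
    RelationshipKernel,
    SimulationConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """A 40-line, 4-environment study with all effect classes active."""
    cfg = SimulationConfig(
        n_lines=40,
        n_markers=300,
        n_founders=15,
        n_generations=2,
        n_envs=4,
        n_reps=2,
        blocks_per_rep=3,
        var_env=1.0,
        var_line=0.05,
        var_g=0.4,
        var_a=0.15,
        var_ge=0.3,
        var_ae=0.1,
        var_rep=0.05,
        var_block=0.05,
        var_e=0.8,
        missing_cell_rate=0.05,
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture
def textbook_pedigree():
    """Founders S, D; full sibs C, C2; half sib H; selfed offspring SF."""
    return PedigreeTable(
        ["S", "D", "C", "C2", "H", "SF"],
        ["0", "0", "S", "S", "S", "C"],
        ["0", "0", "D", "D", "0", "C"],
    )


@pytest.fixture
def grid_table():
    """Deterministic 12-line × 5-environment cell table."""
    rng = np.random.default_rng(99)
    lines = [f"l{i:02d}" for i in range(12)]
    envs = [f"e{j}" for j in range(5)]
    rows = [("t", e, l, rng.normal()) for e in envs for l in lines]
    table = LineEnvTable(
        pd.DataFrame(rows, columns=["trait", "environment", "line", "value"])
    )
    cells = IncidenceMap.from_cells([(l, e) for e in envs for l in lines])
    k = 0.3 + 0.7 * np.eye(12)
    kernel = RelationshipKernel(lines, k, "G")
    return table, cells, kernel


def random_genotypes(n_lines, n_markers, seed, missing_rate=0.0):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_markers)
    d = rng.binomial(2, p, size=(n_lines, n_markers)).astype(float)
    if missing_rate:
        d[rng.random(d.shape) < missing_rate] = np.nan
    return GenotypeMatrix(
        [f"l{i}" for i in range(n_lines)],
        [f"m{j}" for j in range(n_markers)],
        d,
    )
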