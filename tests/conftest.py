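import numpy as np
import pandas as pd
import pytest

from refstab import CqTable, default_hatching_scenario, simulate_cq


@pytest.fixture
def toy_cq() -> CqTable:
    """3 genes x 4 samples over 2 conditions, fixed values."""
    values = pd.DataFrame(
        {
            "c1_1": [20.0, 22.0, 25.0],
            "c1_2": [20.5, 22.4, 24.2],
            "c2_1": [19.8, 22.1, 26.0],
            "c2_2": [20.2, 21.9, 25.5],
        },
        index=["A", "B", "C"],
    )
    meta = pd.DataFrame(
        {
            "condition": ["c1", "c1", "c2", "c2"],
            "replicate": [1, 2, 1, 2],
        },
        index=["c1_1", "c1_2", "c2_1", "c2_2"],
    )
    return CqTable(values, meta)


def random_cq_table(rng: np.random.Generator, n_genes=5, n_samples=8,
                    n_conditions=2) -> CqTable:
    genes = [f"G{i}" for i in range(n_genes)]
    reps = n_samples // n_conditions
    samples, conds, rep_idx = [], [], []
    for c in range(n_conditions):
        for r in range(reps):
            samples.append(f"cond{c}_{r + 1}")
            conds.append(f"cond{c}")
            rep_idx.append(r + 1)
    values = pd.DataFrame(
        rng.normal(24.0, 2.0, size=(n_genes, len(samples))),
        index=genes,
        columns=samples,
    )
    meta = pd.DataFrame({"condition": conds, "replicate": rep_idx}, index=samples)
    return CqTable(values, meta)


@pytest.fixture(scope="session")
def hatching_cq():
    """One draw of the bundled hatching-scenario Cq table (seed 1)."""
    cfg = default_hatching_scenario(seed=1)
    table, truth = simulate_cq(cfg)
    return cfg, table, truth
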