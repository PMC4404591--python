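import numpy as np
import pandas as pd
import pytest

import varapport as vp


def make_design(n_groups, n_indiv, n_reps, rng=None):
    """Minimal library-level design table for hand-built tests."""
    rows = []
    for g in range(n_groups):
        for i in range(n_indiv):
            for r in range(n_reps):
                rows.append({
                    "library_id": f"G{g+1}_I{i+1:02d}_R{r+1}",
                    "individual": f"G{g+1}_I{i+1:02d}",
                    "group": f"G{g+1}",
                    "mapped_reads": 1_000_000,
                    "rin": 8.0,
                })
    design = pd.DataFrame(rows).set_index("library_id")
    if rng is not None:
        design["mapped_reads"] = rng.integers(8e5, 1.6e6, len(design))
        design["rin"] = np.round(rng.uniform(7, 10, len(design)), 2)
    return design


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene neutral data set at the study's 4 x 10 x 2 design."""
    return vp.generate_dataset(vp.SimulationConfig(n_genes=300, seed=7))


@pytest.fixture(scope="session")
def small_expr(small_dataset):
    return vp.variance_stabilize(small_dataset.counts)


@pytest.fixture()
def balanced_toy():
    """2 groups x 2 individuals x 2 replicates; group means 0 and 2."""
    design = make_design(2, 2, 2)
    values = np.array([[0.0] * 4 + [2.0] * 4])
    expr = pd.DataFrame(values, index=["gene_1"], columns=design.index)
    return expr, design
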