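import numpy as np
import pandas as pd
import pytest

from dbtlopt.design_space import Design, Factor, Level, LibrarySpec, pal_library


def toy_library(level_counts=(2, 3), name="toy", strengths=None):
    """Small library with factors fA, fB, ... and levels like fA_L0."""
    names = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    factors = []
    for i, n in enumerate(level_counts):
        levels = []
        for j in range(n):
            strength = (
                strengths[i][j]
                if strengths
                else ("strong", "medium", "weak", "unknown")[min(j, 3)]
            )
            levels.append(
                Level(f"f{names[i]}_L{j}", promoter=f"p{j}", orf=f"orf{names[i]}",
                      strength=strength)
            )
        factors.append(Factor(f"f{names[i]}", i + 1, tuple(levels)))
    return LibrarySpec(name, tuple(factors))


@pytest.fixture
def toy2x3():
    return toy_library((2, 3))


@pytest.fixture
def pal_full():
    return pal_library(reduced=False)


@pytest.fixture
def pal_reduced():
    return pal_library(reduced=True)


def make_dataset(library, titers, seed=0, n_replicates=None, detection_limit=0.05):
    """DesignDataset over the first len(titers) enumerated designs."""
    from dbtlopt.datasets import DesignDataset
    from dbtlopt.design_space import enumerate_designs

    designs = enumerate_designs(library)[: len(titers)]
    rows = []
    for i, (d, t) in enumerate(zip(designs, titers)):
        rows.append({**d.as_dict(), "mean_titer": float(t),
                     "n_replicates": 1 if n_replicates is None else n_replicates[i],
                     "producer": float(t) >= detection_limit})
    return DesignDataset(pd.DataFrame(rows), library, "complete", detection_limit)
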