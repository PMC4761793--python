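import numpy as np
import pandas as pd
import pytest

from dartpop import MarkerMatrix


@pytest.fixture
def toy_matrix():
    """3 individuals x 4 markers, one missing call, two groups."""
    calls = pd.DataFrame(
        [[1, 1, 0, 1], [1, 0, 0, 1], [0, np.nan, 1, 0]],
        index=["X", "Y", "Z"],
        columns=["m1", "m2", "m3", "m4"],
        dtype=float,
    )
    groups = pd.Series(["A", "A", "B"], index=calls.index)
    return MarkerMatrix(calls, groups)


@pytest.fixture
def two_block_matrix():
    """Two homogeneous groups of 3: group A carries m1/m2, group B m3/m4."""
    rows = {
        "a1": [1, 1, 0, 0], "a2": [1, 1, 0, 0], "a3": [1, 1, 0, 0],
        "b1": [0, 0, 1, 1], "b2": [0, 0, 1, 1], "b3": [0, 0, 1, 1],
    }
    calls = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    calls.columns = ["m1", "m2", "m3", "m4"]
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=calls.index)
    return MarkerMatrix(calls, groups)


def random_marker_matrix(rng, n_ind=8, n_loci=12, missing_rate=0.0, n_groups=2):
    """Unstructured random matrix helper used by several suites."""
    calls = (rng.random((n_ind, n_loci)) < rng.uniform(0.2, 0.8, size=n_loci)).astype(float)
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = np.nan
    idx = [f"i{k}" for k in range(n_ind)]
    groups = pd.Series(rng.integers(0, n_groups, n_ind).astype(str), index=idx)
    # ensure every group non-empty
    for g in range(n_groups):
        groups.iloc[g] = str(g)
    df = pd.DataFrame(calls, index=idx, columns=[f"L{j}" for j in range(n_loci)])
    return MarkerMatrix(df, groups)
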