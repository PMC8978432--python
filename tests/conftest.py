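import numpy as np
import pandas as pd
import pytest

from altrec import EpisodeTable, parse_long_table

# Toy three-subject table used throughout: subject 1 has two episodes
# (last Type II gap censored), subject 2 has three (last pair fully
# censored), subject 3 a single fully censored pair.
T1_ROWS = [
    (1, 1, 2, 3, 1, 1),
    (1, 2, 4, 2, 1, 0),
    (2, 1, 1, 1, 1, 1),
    (2, 2, 3, 4, 1, 1),
    (2, 3, 2, 1, 0, 0),
    (3, 1, 5, 0, 0, 0),
]


def t1_frame() -> pd.DataFrame:
    return pd.DataFrame(
        T1_ROWS, columns=["id", "episode", "xij", "yij", "d1", "d2"]
    )


@pytest.fixture
def t1() -> EpisodeTable:
    return parse_long_table(t1_frame())


@pytest.fixture
def t1_cov() -> EpisodeTable:
    """T1 with one binary baseline covariate a = (1, 0, 0) per subject."""
    df = t1_frame()
    df["a"] = df["id"].map({1: 1.0, 2: 0.0, 3: 0.0})
    return parse_long_table(df, covariate_names=["a"])


def random_table(rng: np.random.Generator, n: int = 5, p: int = 0) -> EpisodeTable:
    """Random structurally valid table with occasional gap-time ties."""
    rows = []
    covs = {f"c{k}": {} for k in range(p)}
    for i in range(n):
        m = int(rng.integers(2, 4)) if i == 0 else int(rng.integers(1, 4))
        for k in range(p):
            covs[f"c{k}"][i] = float(rng.integers(0, 2)) if k == 0 else float(
                np.round(rng.uniform(), 2)
            )
        for j in range(1, m + 1):
            x = float(np.round(rng.uniform(0.5, 5.0) * 2) / 2)  # ties likely
            if j < m:
                y = float(np.round(rng.uniform(0.5, 5.0) * 2) / 2)
                rows.append((i, j, x, y, 1, 1))
            else:
                d1 = int(rng.integers(0, 2))
                y = float(np.round(rng.uniform(0.5, 5.0) * 2) / 2) if d1 else 0.0
                rows.append((i, j, x, y, d1, 0))
    df = pd.DataFrame(rows, columns=["id", "episode", "xij", "yij", "d1", "d2"])
    for k in range(p):
        df[f"c{k}"] = df["id"].map(covs[f"c{k}"])
    # guarantee covariate variation in the binary column
    if p and df.groupby("id")["c0"].first().nunique() < 2:
        first = df["id"] == df["id"].iloc[0]
        df.loc[first, "c0"] = 1.0 - df.loc[~first, "c0"].iloc[0]
    return parse_long_table(df, covariate_names=[f"c{k}" for k in range(p)])
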