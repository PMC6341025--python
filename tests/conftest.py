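"""Shared fixtures and the independent brute-force measurement oracle."""

from __future__ import annotations

import numpy as np
import pytest

from netmiss import MISSING, ObservedReports, TrueNetwork


# ---------------------------------------------------------------------------
# Brute-force oracle: recompute every measure by enumerating the tie list with
# plain Python loops.  Deliberately independent of the numpy implementation.
# ---------------------------------------------------------------------------

def oracle_degree(ties: list[list[int]], k: int, directed: bool, mode: str) -> float:
    n = len(ties)
    if not directed:
        d = sum(ties[k][i] for i in range(n) if i != k)
        return d / (n - 1)
    din = sum(ties[i][k] for i in range(n) if i != k)
    dout = sum(ties[k][i] for i in range(n) if i != k)
    if mode == "in":
        return din / (n - 1)
    if mode == "out":
        return dout / (n - 1)
    return (din + dout) / (2 * (n - 1))


def oracle_measures(ties: list[list[int]], directed: bool, mode: str = "in") -> dict:
    n = len(ties)
    present = sum(ties[i][j] for i in range(n) for j in range(n) if i != j)
    if directed:
        dens = present / (n * (n - 1))
    else:
        dens = (present / 2) / (n * (n - 1) / 2)
    degs = [oracle_degree(ties, k, directed, mode) for k in range(n)]
    cmax = max(degs)
    numer = sum(cmax - d for d in degs)
    denom = (n - 1) if directed and mode in ("in", "out") else (n - 2)
    return {
        "density": dens,
        "mean_normalized_degree": sum(degs) / n,
        "centralization": numer / denom,
    }


def random_small_network(rng: np.random.Generator, directed: bool | None = None) -> TrueNetwork:
    n = int(rng.integers(3, 8))
    if directed is None:
        directed = bool(rng.integers(2))
    mat = rng.integers(0, 2, size=(n, n))
    if not directed:
        mat = np.triu(mat, 1)
        mat = mat + mat.T
    np.fill_diagonal(mat, 0)
    return TrueNetwork(mat.astype(np.int8), directed=directed)


# ---------------------------------------------------------------------------
# Worked-example matrices, frozen from the printed 7-actor tables.
# ---------------------------------------------------------------------------

N = MISSING


@pytest.fixture
def example_reports() -> ObservedReports:
    """7-actor report matrix with whole-row non-response of A, D, F."""
    entries = np.array(
        [
            [0, N, N, N, N, N, N],
            [1, 0, 1, 0, 1, 0, 0],
            [1, 1, 0, 0, 1, 1, 1],
            [N, N, N, 0, N, N, N],
            [1, 1, 1, 0, 0, 1, 0],
            [N, N, N, N, N, 0, N],
            [1, 0, 1, 1, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    return ObservedReports(entries, directed_data=True, labels=tuple("ABCDEFG"))


#: The printed reduced network after listwise deletion (actors B, C, E, G).
REDUCED_EXPECTED = np.array(
    [
        [0, 1, 1, 0],
        [1, 0, 1, 1],
        [1, 1, 0, 0],
        [0, 1, 1, 0],
    ],
    dtype=np.int8,
)

#: The printed reconstruction of rows A, D, F (N = both reports missing,
#: resolved by the secondary rule, not compared against the printed table).
RECONSTRUCTED_ROWS = {
    "A": [None, 1, 1, N, 1, N, 1],
    "D": [N, 0, 0, None, 0, N, 1],
    "F": [N, 0, 1, N, 1, None, 0],
}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
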