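"""Synthetic complete networks and actor attributes for the simulation study.

The study conditions emulate a 50-actor adolescent friendship network
collected with a name generator (up to six best-friend nominations) together
with a 5-point alcohol-consumption score per actor, from 1 ("I don't drink")
to 5 ("more than once a week").  The directed network has density 0.047 and
its max-symmetrized undirected version density 0.066; larger networks (150,
250 actors) are density-matched Bernoulli random graphs.

Seed management: one master seed expands into named substreams (network,
attributes, missingness, imputation) so each pipeline stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .missingness import MISSING, ConfigurationError, ObservedReports
from .net_core import TrueNetwork

__all__ = [
    "ActorAttributes",
    "DIRECTED_DENSITY",
    "GenerationSpec",
    "UNDIRECTED_DENSITY",
    "generate_attributes",
    "generate_network",
    "load_fixture",
    "substream",
]

#: Empirical densities of the reference friendship network.
DIRECTED_DENSITY = 0.047
UNDIRECTED_DENSITY = 0.066

ALCOHOL_LEVELS = np.arange(1, 6)

#: Fixed substream indices; adding new stages must not reshuffle existing ones.
_STREAMS = {"network": 0, "attributes": 1, "missingness": 2, "imputation": 3}

ActorAttributes = np.ndarray  # integer alcohol scores in 1..5, one per actor


def substream(master_seed: int, name: str, replicate: int = 0) -> np.random.Generator:
    """Named, replicate-indexed random stream derived from one master seed."""
    if name not in _STREAMS:
        raise ConfigurationError(f"unknown stream {name!r}; expected one of {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(replicate, _STREAMS[name]))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class GenerationSpec:
    """Conditions for one generated network.

    ``target_density`` defaults to the reference network's density for the
    chosen direction (0.047 directed, 0.066 undirected).  ``max_outdegree``
    optionally caps outgoing nominations per actor; 6 emulates the name
    generator instrument and is off by default because the density-matched
    random graphs are described by density alone.
    """

    n: int = 50
    directed: bool = True
    target_density: Optional[float] = None
    max_outdegree: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ConfigurationError("need at least 3 actors")
        p = self.density
        if not 0.0 < p < 1.0:
            raise ConfigurationError("target_density must be in (0, 1)")
        if self.max_outdegree is not None:
            if not self.directed:
                raise ConfigurationError("outdegree cap applies to directed nominations only")
            if p * (self.n - 1) > self.max_outdegree:
                raise ConfigurationError(
                    f"expected outdegree {p * (self.n - 1):.2f} exceeds cap {self.max_outdegree}"
                )

    @property
    def density(self) -> float:
        if self.target_density is not None:
            return self.target_density
        return DIRECTED_DENSITY if self.directed else UNDIRECTED_DENSITY


def generate_network(
    spec: GenerationSpec, rng: Optional[np.random.Generator] = None
) -> TrueNetwork:
    """Bernoulli random graph at the spec's target density.

    Each ordered off-diagonal cell (directed) or unordered pair (undirected)
    carries a tie independently with probability ``target_density``.  With a
    ``max_outdegree`` cap, rows exceeding the cap are thinned by uniform
    random removal of their excess ties.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, p = spec.n, spec.density
    if spec.directed:
        ties = (rng.random((n, n)) < p).astype(np.int8)
        np.fill_diagonal(ties, 0)
        if spec.max_outdegree is not None:
            cap = spec.max_outdegree
            for i in np.flatnonzero(ties.sum(axis=1) > cap):
                nbrs = np.flatnonzero(ties[i])
                drop = rng.choice(nbrs, size=len(nbrs) - cap, replace=False)
                ties[i, drop] = 0
    else:
        upper = np.triu((rng.random((n, n)) < p), k=1).astype(np.int8)
        ties = upper + upper.T
    return TrueNetwork(ties, directed=spec.directed)


def generate_attributes(
    n: int,
    distribution: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ActorAttributes:
    """I.i.d. alcohol scores on the 1-5 scale (uniform by default)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if distribution is None:
        weights = np.ones(5)
    else:
        weights = np.asarray(distribution, dtype=float)
        if weights.shape != (5,) or (weights < 0).any() or weights.sum() <= 0:
            raise ConfigurationError("distribution must be 5 nonnegative weights with positive sum")
    return rng.choice(ALCOHOL_LEVELS, size=n, p=weights / weights.sum())


# Classic 7-actor worked example of whole-row tie non-response: actors A, D
# and F returned no outgoing reports at all.  The same matrix is printed in
# the literature both as an emotional-support network and as a friendship
# network; both fixture names load it.  "." marks the structural diagonal,
# "N" a missing report.
_EXAMPLE_ROWS = """
. N N N N N N
1 . 1 0 1 0 0
1 1 . 0 1 1 1
N N N . N N N
1 1 1 0 . 1 0
N N N N N . N
1 0 1 1 1 0 .
"""

FIXTURE_NAMES = ("emotional", "friendship")


def load_fixture(name: str) -> ObservedReports:
    """Ternary 7-actor report matrix of the worked non-response examples.

    ``"emotional"`` and ``"friendship"`` load the same matrix: rows A, D, F
    entirely missing, 18 missing cells.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    code = {"0": 0, "1": 1, "N": MISSING, ".": 0}
    entries = np.array(
        [[code[tok] for tok in line.split()] for line in _EXAMPLE_ROWS.strip().splitlines()],
        dtype=np.int8,
    )
    return ObservedReports(entries, directed_data=True, labels=tuple("ABCDEFG"))
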