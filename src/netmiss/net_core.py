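"""Core sociomatrix types and descriptive network measures.

A social network on ``n`` actors is stored as a square binary adjacency
matrix (*sociomatrix*): entry ``(i, j)`` records whether actor ``i`` has a
tie to actor ``j``.  Self-ties are structurally absent, so the diagonal is
always zero and never counted.  Undirected networks are stored as exactly
symmetric matrices and their unordered pairs are counted once.

The measures implemented here are the ones evaluated throughout the
missing-data simulation pipeline:

* **density** — fraction of possible ties that are present;
* **normalized degree centrality** — an actor's tie count divided by
  ``n - 1`` (Freeman's C'_D);
* **degree centralization** — Freeman's network-level statistic, the sum of
  differences between the maximum centrality and each actor's centrality
  divided by the maximum such sum any network of the same size can attain
  (1 on a star, 0 on any regular graph).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DegreeMode",
    "InvalidNetworkError",
    "NetworkMeasures",
    "TrueNetwork",
    "UndefinedMeasureError",
    "UnknownActorError",
    "centralization",
    "default_labels",
    "density",
    "network_measures",
    "normalized_degree",
    "subnetwork",
    "symmetrize_max",
]

DEGREE_MODES = ("in", "out", "total")
DegreeMode = str  # one of DEGREE_MODES; plain strings keep the API light


class InvalidNetworkError(ValueError):
    """The adjacency matrix violates a structural invariant."""


class UndefinedMeasureError(ValueError):
    """The requested measure is undefined for this network size."""


class UnknownActorError(KeyError):
    """The actor label is not on the network's roster."""


def default_labels(n: int) -> tuple[str, ...]:
    """Spreadsheet-style labels A, B, ..., Z, AA, AB, ... for ``n`` actors."""
    out = []
    for i in range(n):
        s, k = "", i
        while True:
            s = chr(ord("A") + k % 26) + s
            k = k // 26 - 1
            if k < 0:
                break
        out.append(s)
    return tuple(out)


@dataclass(frozen=True)
class TrueNetwork:
    """A completely observed binary network (the simulation ground truth).

    Parameters
    ----------
    ties
        ``(n, n)`` matrix with entries in {0, 1} and a zero diagonal.
    directed
        Whether ordered ties are distinct.  Undirected networks must be
        exactly symmetric.
    labels
        Actor identifiers; generated as A, B, C, ... when omitted.
    """

    ties: np.ndarray
    directed: bool = True
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        ties = np.asarray(self.ties)
        if ties.ndim != 2 or ties.shape[0] != ties.shape[1]:
            raise InvalidNetworkError(f"adjacency matrix must be square, got {ties.shape}")
        n = ties.shape[0]
        if n < 2:
            raise InvalidNetworkError("a network needs at least 2 actors")
        if not np.isin(ties, (0, 1)).all():
            raise InvalidNetworkError("tie entries must be 0 or 1")
        if np.diagonal(ties).any():
            raise InvalidNetworkError("self-ties are structurally absent; diagonal must be 0")
        if not self.directed and not np.array_equal(ties, ties.T):
            raise InvalidNetworkError("undirected network must have a symmetric matrix")
        ties = np.ascontiguousarray(ties, dtype=np.int8)
        ties.setflags(write=False)
        object.__setattr__(self, "ties", ties)
        labels = tuple(self.labels) if self.labels else default_labels(n)
        if len(labels) != n:
            raise InvalidNetworkError(f"{len(labels)} labels for {n} actors")
        if len(set(labels)) != n:
            raise InvalidNetworkError("actor labels must be unique")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.ties.shape[0]

    def index_of(self, actor: str) -> int:
        try:
            return self.labels.index(actor)
        except ValueError:
            raise UnknownActorError(actor) from None

    def out_degrees(self) -> np.ndarray:
        """Row sums: number of outgoing nominations per actor."""
        return self.ties.sum(axis=1)

    def in_degrees(self) -> np.ndarray:
        return self.ties.sum(axis=0)


@dataclass(frozen=True)
class NetworkMeasures:
    """Bundle of the descriptive measures tracked by the simulation study."""

    density: float
    mean_normalized_degree: float
    centralization: float
    degree_mode: DegreeMode
    n: int


def density(net: TrueNetwork) -> float:
    """Fraction of possible ties present.

    Directed networks count ordered off-diagonal cells, ``n(n-1)``;
    undirected networks count unordered pairs, ``n(n-1)/2``.  Because a
    symmetric matrix stores each pair twice, both reduce to
    ``ties.sum() / (n(n-1))``.
    """
    n = net.n
    return float(net.ties.sum()) / (n * (n - 1))


def _normalized_degree_vector(net: TrueNetwork, mode: DegreeMode) -> np.ndarray:
    n = net.n
    if not net.directed:
        return net.ties.sum(axis=1) / (n - 1)
    if mode == "in":
        return net.in_degrees() / (n - 1)
    if mode == "out":
        return net.out_degrees() / (n - 1)
    if mode == "total":
        # normalized by the maximum attainable total degree 2(n-1) so the
        # statistic stays in [0, 1] like the other modes
        return (net.in_degrees() + net.out_degrees()) / (2 * (n - 1))
    raise ValueError(f"unknown degree mode {mode!r}; expected one of {DEGREE_MODES}")


def normalized_degree(net: TrueNetwork, actor: str, mode: DegreeMode = "in") -> float:
    """Freeman normalized degree centrality C'_D of one actor.

    ``mode`` selects incoming, outgoing, or total nominations for directed
    networks and is ignored for undirected ones.
    """
    return float(_normalized_degree_vector(net, mode)[net.index_of(actor)])


def centralization(net: TrueNetwork, mode: DegreeMode = "in") -> float:
    """Freeman degree centralization.

    ``sum_i (C_max - C'_D(i))`` divided by the maximum possible such sum for
    a network of the same size, which a star attains: ``n - 2`` for
    undirected (and directed-total) normalized degree, ``n - 1`` for
    directed in- or out-degree, where a single actor can monopolise all
    nominations.  Undefined for ``n < 3`` (the denominator vanishes).
    """
    n = net.n
    if n < 3:
        raise UndefinedMeasureError("centralization needs at least 3 actors")
    c = _normalized_degree_vector(net, mode)
    numer = float((c.max() - c).sum())
    if net.directed and mode in ("in", "out"):
        denom = n - 1
    else:
        denom = n - 2
    return numer / denom


def symmetrize_max(net: TrueNetwork) -> TrueNetwork:
    """Undirected network whose pair tie is the maximum of the two directed ties.

    A pair is tied iff either directed tie is present.  Already-undirected
    input is returned unchanged with a warning (the operation is a no-op).
    """
    if not net.directed:
        warnings.warn("symmetrize_max called on an undirected network; no-op", stacklevel=2)
        return net
    ties = np.maximum(net.ties, net.ties.T)
    return TrueNetwork(ties, directed=False, labels=net.labels)


def network_measures(net: TrueNetwork, mode: DegreeMode = "in") -> NetworkMeasures:
    """Density, mean normalized degree and centralization in one bundle."""
    c = _normalized_degree_vector(net, mode)
    return NetworkMeasures(
        density=density(net),
        mean_normalized_degree=float(c.mean()),
        centralization=centralization(net, mode),
        degree_mode=mode if net.directed else "total",
        n=net.n,
    )


def subnetwork(net: TrueNetwork, keep: Sequence[str]) -> TrueNetwork:
    """Principal sub-matrix restricted to the listed actors (label order kept)."""
    idx = [net.index_of(a) for a in keep]
    return TrueNetwork(
        net.ties[np.ix_(idx, idx)], directed=net.directed, labels=tuple(net.labels[i] for i in idx)
    )
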