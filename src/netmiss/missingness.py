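"""Tie non-response mechanisms: deleting ties from a complete network.

Tie non-response means an actor took part in the survey but some of their
reported ties are absent.  Each actor's *outgoing report* row is what the
survey instrument collects, so missingness always acts on ordered report
cells — also for undirected networks, where the one true pair value is
reported independently by both endpoints and either report can go missing.

Three mechanisms are supported, all acting through a per-sender weight:

* **MCAR** — every report cell equally likely to be missing (weight 1);
* **MAR**  — weight ``1 / alcohol_i**2``: heavy drinkers respond better
  (the alcohol score is fully observed, so missingness is at random);
* **MNAR** — weight ``1 / (outdegree_i + 1)**2`` with the outdegree taken
  from the complete network: actors with few nominations respond worse, and
  since the outdegree is exactly what goes unobserved the mechanism is not
  at random.

Deletion hits an exact target count ``M = round_half_up(proportion * n(n-1))``
by weighted sampling without replacement, so the nominal missing proportion
holds in every replicate instead of only in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .net_core import TrueNetwork

__all__ = [
    "MISSING",
    "ConfigurationError",
    "MissingnessSpec",
    "ObservedReports",
    "delete_ties",
    "mechanism_weights",
    "nonrespondents",
    "pair_reports",
]

#: Internal code for a missing report cell (files use a textual code, default "N").
MISSING = -1

MECHANISMS = ("MCAR", "MAR", "MNAR")


class ConfigurationError(ValueError):
    """Inconsistent missingness/generation configuration."""


@dataclass(frozen=True)
class ObservedReports:
    """Partially observed report matrix with entries in {0, 1, MISSING}.

    ``directed_data`` records whether the underlying truth is directed; an
    undirected truth still yields an ordered report matrix (symmetric where
    observed) because both endpoints report the pair independently.
    """

    entries: np.ndarray
    directed_data: bool = True
    labels: tuple[str, ...] = field(default=())
    source: Optional[TrueNetwork] = None

    def __post_init__(self) -> None:
        e = np.asarray(self.entries)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ConfigurationError(f"report matrix must be square, got {e.shape}")
        if not np.isin(e, (0, 1, MISSING)).all():
            raise ConfigurationError("report entries must be 0, 1 or MISSING")
        if np.diagonal(e).any():
            raise ConfigurationError("diagonal is structurally absent; must be 0")
        e = np.ascontiguousarray(e, dtype=np.int8)
        e.setflags(write=False)
        object.__setattr__(self, "entries", e)
        labels = tuple(self.labels) if self.labels else None
        if labels is None:
            from .net_core import default_labels

            labels = self.source.labels if self.source is not None else default_labels(e.shape[0])
        if len(labels) != e.shape[0] or len(set(labels)) != len(labels):
            raise ConfigurationError("labels must be unique and match the matrix size")
        object.__setattr__(self, "labels", labels)
        if self.source is not None:
            obs = self.entries != MISSING
            off = ~np.eye(self.n, dtype=bool)
            if not np.array_equal(self.entries[obs & off], self.source.ties[obs & off]):
                raise ConfigurationError("observed entries differ from the source network")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing off-diagonal report cells."""
        return self.entries == MISSING

    def n_missing(self) -> int:
        return int(self.missing_mask.sum())


@dataclass(frozen=True)
class MissingnessSpec:
    """Mechanism, target missing proportion and granularity of deletion.

    ``granularity="cell"`` deletes individual report cells; ``"row"``
    deletes whole outgoing rows (the whole-questionnaire non-response of the
    worked examples) until the deleted-cell count first reaches the target.
    """

    mechanism: str = "MCAR"
    proportion: float = 0.1
    granularity: str = "cell"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 <= self.proportion < 1.0:
            raise ConfigurationError("proportion must be in [0, 1)")
        if self.granularity not in ("cell", "row"):
            raise ConfigurationError("granularity must be 'cell' or 'row'")


def mechanism_weights(
    mechanism: str,
    net: TrueNetwork,
    attrs: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-sender non-response weight under the given mechanism.

    All of a sender's outgoing report cells share the sender's weight;
    weights are relative (only ratios matter for the sampling).
    """
    n = net.n
    if mechanism == "MCAR":
        return np.ones(n)
    if mechanism == "MAR":
        if attrs is None:
            raise ConfigurationError("MAR needs the actor alcohol scores")
        a = np.asarray(attrs, dtype=float)
        if a.shape != (n,) or (a <= 0).any():
            raise ConfigurationError("alcohol scores must be positive, one per actor")
        w = 1.0 / a**2
    elif mechanism == "MNAR":
        w = 1.0 / (net.out_degrees().astype(float) + 1.0) ** 2
    else:
        raise ConfigurationError(f"mechanism must be one of {MECHANISMS}")
    if w.sum() <= 0:
        raise ConfigurationError("total mechanism weight is zero")
    return w


def _target_count(proportion: float, n_cells: int) -> int:
    # round half up, so 0.25 * 2450 -> 613
    return int(np.floor(proportion * n_cells + 0.5))


def delete_ties(
    net: TrueNetwork,
    spec: MissingnessSpec,
    attrs: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> ObservedReports:
    """Impose tie non-response on a complete network.

    Exactly ``M = round_half_up(proportion * n(n-1))`` report cells are set
    to MISSING (row granularity may overshoot by at most ``n - 2`` cells,
    keeping the last sampled row whole).  Cells are chosen by weighted
    sampling without replacement with per-cell weight equal to the sending
    actor's mechanism weight; observed cells are never altered.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = net.n
    n_cells = n * (n - 1)
    m_target = _target_count(spec.proportion, n_cells)
    entries = net.ties.astype(np.int8).copy()
    if m_target == 0:
        if spec.proportion > 0:
            warnings.warn(
                f"proportion {spec.proportion} rounds to zero cells at n={n}; "
                "returning complete reports",
                stacklevel=2,
            )
        return ObservedReports(entries, directed_data=net.directed, labels=net.labels, source=net)

    w_actor = mechanism_weights(spec.mechanism, net, attrs)
    off = ~np.eye(n, dtype=bool)

    if spec.granularity == "cell":
        # Efraimidis-Spirakis: smallest Exp(1)/w keys form a weighted sample
        # without replacement; deterministic for a fixed generator state.
        keys = np.full((n, n), np.inf)
        keys[off] = rng.exponential(size=n_cells)
        keys /= w_actor[:, None]
        flat = np.argsort(keys, axis=None, kind="stable")[:m_target]
        entries[np.unravel_index(flat, (n, n))] = MISSING
    else:
        keys = rng.exponential(size=n) / w_actor
        deleted = 0
        for i in np.argsort(keys, kind="stable"):
            entries[i, off[i]] = MISSING
            deleted += n - 1
            if deleted >= m_target:
                break
    return ObservedReports(entries, directed_data=net.directed, labels=net.labels, source=net)


def nonrespondents(reports: ObservedReports) -> set[str]:
    """Actors with at least one missing outgoing report cell."""
    rows = reports.missing_mask.any(axis=1)
    return {reports.labels[i] for i in np.flatnonzero(rows)}


def pair_reports(reports: ObservedReports) -> np.ndarray:
    """Collapse an undirected network's two ordered reports per pair.

    The surviving report wins (deletion never alters values, so two observed
    reports of the same pair agree); a pair is missing only when both
    endpoints' reports are missing.  Returns a symmetric {0, 1, MISSING}
    matrix.
    """
    e = reports.entries
    return np.where(e != MISSING, e, e.T).astype(np.int8)
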