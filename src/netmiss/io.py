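"""Plain-text file formats for networks and reports.

Two formats are supported, both label-carrying and binary-free:

* **adjacency matrix** — delimited square matrix with actor labels as header
  and index; missing reports use a configurable code (default ``"N"``, the
  convention of printed sociomatrices) and the structural diagonal a
  configurable code (default empty);
* **edge list** — one ``source,target`` row per tie, for complete networks
  only (missingness is cell-level and needs the matrix form).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .missingness import MISSING, ObservedReports
from .net_core import TrueNetwork

__all__ = [
    "AdjacencyDialect",
    "ParseError",
    "read_adjacency",
    "read_edgelist",
    "write_adjacency",
    "write_edgelist",
]

PathLike = Union[str, Path, _io.TextIOBase]


class ParseError(ValueError):
    """Malformed network file."""


@dataclass(frozen=True)
class AdjacencyDialect:
    missing_code: str = "N"
    delimiter: str = ","
    header_labels: bool = True
    diagonal_code: str = ""

    def __post_init__(self) -> None:
        if self.missing_code in ("0", "1"):
            raise ParseError("missing_code must differ from the tie codes 0 and 1")


def _frame(obj: Union[TrueNetwork, ObservedReports], dialect: AdjacencyDialect) -> pd.DataFrame:
    mat = obj.ties if isinstance(obj, TrueNetwork) else obj.entries
    order = np.argsort(np.asarray(obj.labels))  # deterministic row order by label
    labels = [obj.labels[i] for i in order]
    mat = mat[np.ix_(order, order)]
    cells = mat.astype(object)
    cells[mat == MISSING] = dialect.missing_code
    np.fill_diagonal(cells, dialect.diagonal_code)
    return pd.DataFrame(cells, index=labels, columns=labels)


def write_adjacency(
    obj: Union[TrueNetwork, ObservedReports],
    path: PathLike,
    dialect: AdjacencyDialect = AdjacencyDialect(),
) -> None:
    """Write a network or report matrix as a labelled delimited file."""
    df = _frame(obj, dialect)
    df.to_csv(path, sep=dialect.delimiter, header=dialect.header_labels,
              index=dialect.header_labels)


def read_adjacency(
    path: PathLike,
    dialect: AdjacencyDialect = AdjacencyDialect(),
    directed: Optional[bool] = None,
) -> Union[TrueNetwork, ObservedReports]:
    """Read a labelled adjacency file.

    Returns :class:`ObservedReports` when any missing code is present, else a
    :class:`TrueNetwork`.  ``directed`` defaults to inferring: an exactly
    symmetric complete matrix is read as undirected.
    """
    try:
        df = pd.read_csv(
            path, sep=dialect.delimiter, index_col=0, dtype=str,
            keep_default_na=False, header=0 if dialect.header_labels else None,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise ParseError(f"cannot parse adjacency file: {e}") from e
    labels = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if len(labels) != len(cols):
        raise ParseError(f"matrix is not square: {len(labels)} rows x {len(cols)} columns")
    if labels != cols:
        raise ParseError("row labels and column labels disagree")
    if len(set(labels)) != len(labels):
        raise ParseError("duplicate actor labels")
    n = len(labels)
    entries = np.zeros((n, n), dtype=np.int8)
    any_missing = False
    for i in range(n):
        for j in range(n):
            tok = str(df.iat[i, j]).strip()
            if i == j:
                if tok not in (dialect.diagonal_code.strip(), "0", ""):
                    raise ParseError(f"diagonal cell ({labels[i]},{labels[j]}) holds {tok!r}")
                continue
            if tok == "0":
                entries[i, j] = 0
            elif tok == "1":
                entries[i, j] = 1
            elif tok == dialect.missing_code:
                entries[i, j] = MISSING
                any_missing = True
            else:
                raise ParseError(f"unknown token {tok!r} at row {labels[i]}, column {labels[j]}")
    if any_missing:
        if directed is None:
            directed = True
        return ObservedReports(entries, directed_data=directed, labels=tuple(labels))
    if directed is None:
        directed = not np.array_equal(entries, entries.T)
    return TrueNetwork(entries, directed=directed, labels=tuple(labels))


def write_edgelist(net: TrueNetwork, path: PathLike, delimiter: str = ",") -> None:
    """One source,target row per tie; undirected pairs written once (i < j)."""
    rows = []
    n = net.n
    for i in range(n):
        for j in range(n):
            if net.ties[i, j] and (net.directed or i < j):
                rows.append((net.labels[i], net.labels[j]))
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, sep=delimiter, index=False)


def read_edgelist(
    path: PathLike,
    labels: Optional[Sequence[str]] = None,
    directed: bool = True,
    delimiter: str = ",",
) -> TrueNetwork:
    """Edge list -> complete network; ``labels`` supplies the full roster
    (required to represent isolated actors; inferred from the edges if omitted)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["source", "target"]:
        raise ParseError("edge list needs 'source' and 'target' columns")
    edges = list(zip(df["source"], df["target"]))
    for s, t in edges:
        if s == t:
            raise ParseError(f"self-loop on actor {s!r} rejected")
    if labels is None:
        labels = sorted({a for e in edges for a in e})
    labels = tuple(str(x) for x in labels)
    idx = {a: i for i, a in enumerate(labels)}
    ties = np.zeros((len(labels), len(labels)), dtype=np.int8)
    for s, t in edges:
        if s not in idx or t not in idx:
            raise ParseError(f"edge ({s},{t}) uses an actor missing from the roster")
        ties[idx[s], idx[t]] = 1
        if not directed:
            ties[idx[t], idx[s]] = 1
    return TrueNetwork(ties, directed=directed, labels=labels)
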