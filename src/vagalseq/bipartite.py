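"""Correlation index between two categorical cell characteristics.

Two characteristics (say, ending type and tissue layer) are summarised by a
bipartite map of observed connections between their variables.  A one-to-one
pattern carries the minimum possible number of connections and is scored 1
(perfect correlation); an all-to-all pattern carries the maximum and is
scored 0.  With the connection count fixed, more evenly distributed
connections score higher, which is captured by the per-side variance of
connection counts.  The index is

    (1 - C) / ((v1 + 1) * (v2 + 1))

where C is the normalised connection count and v1, v2 are population
variances of per-variable degrees on the two sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectionMap",
    "prune_unconnected",
    "normalized_connections",
    "connection_variance",
    "correlation_index",
]


@dataclass(frozen=True)
class ConnectionMap:
    """Bipartite connection map between two characteristics.

    Parameters
    ----------
    side1, side2 :
        Variable names of the two characteristics.
    connections :
        Observed (v1, v2) pairs; v1 from side1, v2 from side2.
    """

    side1: tuple[str, ...]
    side2: tuple[str, ...]
    connections: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "side1", tuple(self.side1))
        object.__setattr__(self, "side2", tuple(self.side2))
        object.__setattr__(self, "connections", frozenset(self.connections))
        s1, s2 = set(self.side1), set(self.side2)
        for a, b in self.connections:
            if a not in s1 or b not in s2:
                raise ValueError(f"connection ({a!r}, {b!r}) references undeclared variable")

    def degrees(self, side: int) -> np.ndarray:
        """Connection counts per variable on the given side (1 or 2)."""
        names = self.side1 if side == 1 else self.side2
        idx = 0 if side == 1 else 1
        return np.array([sum(1 for c in self.connections if c[idx] == v) for v in names])


def prune_unconnected(cmap: ConnectionMap) -> ConnectionMap:
    """Drop variables with no connections from both sides.

    Raises
    ------
    ValueError
        If every variable is unconnected (nothing left to analyse).
    """
    used1 = {a for a, _ in cmap.connections}
    used2 = {b for _, b in cmap.connections}
    side1 = tuple(v for v in cmap.side1 if v in used1)
    side2 = tuple(v for v in cmap.side2 if v in used2)
    if not side1 or not side2:
        raise ValueError("all variables are unconnected")
    return ConnectionMap(side1, side2, cmap.connections)


def normalized_connections(cmap: ConnectionMap) -> float:
    """Normalised connection count C in [0, 1].

    C = (E - E_min) / (E_max - E_min) with E_min = max(n1, n2) (every
    retained variable must have at least one connection) and E_max = n1*n2.
    A degenerate map with E_max == E_min is defined to have C = 0.
    """
    n1, n2 = len(cmap.side1), len(cmap.side2)
    e = len(cmap.connections)
    e_min, e_max = max(n1, n2), n1 * n2
    if e_max == e_min:
        return 0.0
    return (e - e_min) / (e_max - e_min)


def connection_variance(cmap: ConnectionMap, side: int) -> float:
    """Population variance of per-variable connection counts on one side."""
    if side not in (1, 2):
        raise ValueError("side must be 1 or 2")
    return float(np.var(cmap.degrees(side)))


def correlation_index(cmap: ConnectionMap, prune: bool = True) -> float:
    """Correlation index (1 - C) / ((v1 + 1) * (v2 + 1)) in [0, 1]."""
    if prune:
        cmap = prune_unconnected(cmap)
    c = normalized_connections(cmap)
    v1 = connection_variance(cmap, 1)
    v2 = connection_variance(cmap, 2)
    return (1.0 - c) / ((v1 + 1.0) * (v2 + 1.0))
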