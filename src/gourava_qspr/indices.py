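"""Degree-based edge-sum topological indices: the Gourava family.

Each index is a sum over bonds of a polynomial in the two endpoint degrees
``d`` and ``e``:

=======  =====================  ========================================
id       per-edge term          name
=======  =====================  ========================================
GO1      d + e + d*e            first Gourava index
GO2      (d + e) * (d*e)        second Gourava index
HGO1     (d + e + d*e)**2       first hyper-Gourava index
HGO2     ((d + e) * (d*e))**2   second hyper-Gourava index
AGO1     d**2 + e**2 + d*e      first alpha-Gourava index
AGO2     (d**2 + e**2) * (d*e)  second alpha-Gourava index
GGO1     d**3 + e**3 + d*e      first gamma-Gourava index
GGO2     (d**3 + e**3) * (d*e)  second gamma-Gourava index
=======  =====================  ========================================

All eight are polynomials in integer degrees, so computation stays in
exact integer arithmetic.  A small registry maps index ids to per-edge
contribution functions; additional degree-based indices (the classic
Randić, sum-connectivity and Zagreb indices are pre-registered) can be
added with :func:`register_index` without touching the core.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable

import pandas as pd

from .molgraph import MolecularGraph, edge_degree_partition

__all__ = [
    "GOURAVA_INDICES",
    "IndexRecord",
    "compute_index",
    "compute_all_indices",
    "index_table",
    "register_index",
]

#: The eight core ids, in the column order of the published table.
GOURAVA_INDICES = ("GO1", "GO2", "HGO1", "HGO2", "AGO1", "AGO2", "GGO1", "GGO2")

#: id -> f(d, e): contribution of one bond with endpoint degrees d, e.
_REGISTRY: dict[str, Callable] = {}


def register_index(index_id: str, per_edge: Callable) -> None:
    """Register ``per_edge(d, e)`` as the contribution function of ``index_id``."""
    _REGISTRY[index_id] = per_edge


register_index("GO1", lambda d, e: d + e + d * e)
register_index("GO2", lambda d, e: (d + e) * (d * e))
register_index("HGO1", lambda d, e: (d + e + d * e) ** 2)
register_index("HGO2", lambda d, e: ((d + e) * (d * e)) ** 2)
register_index("AGO1", lambda d, e: d * d + e * e + d * e)
register_index("AGO2", lambda d, e: (d * d + e * e) * (d * e))
register_index("GGO1", lambda d, e: d ** 3 + e ** 3 + d * e)
register_index("GGO2", lambda d, e: (d ** 3 + e ** 3) * (d * e))

# Classic degree-based indices, available through the same registry as
# optional extras (not part of the core eight-column table).
register_index("M1", lambda d, e: d + e)
register_index("M2", lambda d, e: d * e)
register_index("RANDIC", lambda d, e: (d * e) ** -0.5)
register_index("SUM_CONNECTIVITY", lambda d, e: (d + e) ** -0.5)


@dataclass(frozen=True)
class IndexRecord:
    """The eight Gourava-family values of one molecule (one table row)."""

    molecule: str
    go1: int
    go2: int
    hgo1: int
    hgo2: int
    ago1: int
    ago2: int
    ggo1: int
    ggo2: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def values(self) -> tuple:
        """The eight index values in canonical column order."""
        return tuple(getattr(self, i.lower()) for i in GOURAVA_INDICES)


def compute_index(g: MolecularGraph, index_id: str):
    """Value of one degree-based index on ``g`` (0 for a bond-less graph).

    Computed through the edge-degree partition: each distinct degree pair
    contributes ``per_edge(d, e) * multiplicity``, which equals the plain
    edge-by-edge sum.
    """
    try:
        per_edge = _REGISTRY[index_id]
    except KeyError:
        raise KeyError(
            f"unknown index id {index_id!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    partition = edge_degree_partition(g)
    return sum(per_edge(d, e) * mult for (d, e), mult in partition.items())


def compute_all_indices(g: MolecularGraph) -> IndexRecord:
    """All eight Gourava-family indices of ``g``."""
    vals = {i.lower(): compute_index(g, i) for i in GOURAVA_INDICES}
    return IndexRecord(molecule=g.name, **vals)


def index_table(graphs) -> pd.DataFrame:
    """Eight-column index table (one row per molecule, indexed by name)."""
    rows = [compute_all_indices(g) for g in graphs]
    df = pd.DataFrame(
        [[r.molecule, *r.values()] for r in rows],
        columns=["molecule", *GOURAVA_INDICES],
    )
    return df.set_index("molecule")
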