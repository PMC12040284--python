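"""Hydrogen-included molecular graphs for degree-based topological indices.

A molecule is modelled as a simple, connected, undirected graph: atoms are
vertices labelled with element symbols and every chemical bond contributes
exactly one edge regardless of its order, so a carbonyl C=O leaves the
oxygen at degree 1.  Hydrogens are explicit vertices.  This convention is
what reproduces the published index values for the amino-acid series; see
``docs/methods.md`` for the full rationale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "MolecularGraph",
    "EdgeDegreePartition",
    "InvalidGraphError",
    "SmilesError",
    "edge_degree_partition",
    "from_smiles",
    "read_smiles_file",
]

#: Maximum number of *distinct neighbours* allowed per heavy element.
#: Bond orders are not recorded, so these are caps on graph degree, not
#: on total bond valence (a carboxyl carbon has graph degree 3).
VALENCE_CAPS = {"C": 4, "N": 4, "O": 2, "S": 2, "H": 1}


class InvalidGraphError(ValueError):
    """Raised when atom/bond data violate the molecular-graph invariants."""


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be turned into a valid graph."""


@dataclass(frozen=True)
class MolecularGraph:
    """Simple undirected labelled graph of one molecule.

    Parameters
    ----------
    name : str
        Human-readable label.
    atoms : tuple of str
        Element symbol per vertex; vertex ids are the 0-based positions.
    bonds : tuple of (int, int)
        Unordered atom-index pairs, stored sorted ``(a, b)`` with ``a < b``.
    hydrogens_explicit : bool
        When true (the default and the convention used throughout), every
        hydrogen is a vertex of degree exactly 1.
    """

    name: str
    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    hydrogens_explicit: bool = True

    def __init__(self, name, atoms, bonds, hydrogens_explicit=True):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "atoms", tuple(atoms))
        norm = sorted(tuple(sorted(map(int, b))) for b in bonds)
        object.__setattr__(self, "bonds", tuple(norm))
        object.__setattr__(self, "hydrogens_explicit", bool(hydrogens_explicit))
        self._validate()

    # -- invariants --------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise InvalidGraphError(f"{self.name}: graph has no atoms")
        seen = set()
        for a, b in self.bonds:
            if a == b:
                raise InvalidGraphError(f"{self.name}: self-loop on atom {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise InvalidGraphError(f"{self.name}: bond ({a},{b}) out of range")
            if (a, b) in seen:
                raise InvalidGraphError(f"{self.name}: duplicate bond ({a},{b})")
            seen.add((a, b))
        deg = self.degrees()
        if n > 1 and min(deg) < 1:
            isolated = deg.index(0)
            raise InvalidGraphError(f"{self.name}: atom {isolated} has no bonds")
        if n > 1 and not nx.is_connected(self.to_networkx()):
            raise InvalidGraphError(f"{self.name}: graph is disconnected")
        for i, (el, d) in enumerate(zip(self.atoms, deg)):
            cap = VALENCE_CAPS.get(el)
            if cap is not None and d > cap:
                raise InvalidGraphError(
                    f"{self.name}: atom {i} ({el}) has degree {d} > valence cap {cap}"
                )
            if self.hydrogens_explicit and el == "H" and d != 1:
                raise InvalidGraphError(
                    f"{self.name}: explicit hydrogen {i} has degree {d} != 1"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degrees(self) -> list[int]:
        """Degree (number of distinct neighbours) of every atom."""
        deg = [0] * len(self.atoms)
        for a, b in self.bonds:
            deg[a] += 1
            deg[b] += 1
        return deg

    def formula(self) -> dict[str, int]:
        """Element counts, e.g. ``{"C": 2, "H": 5, "N": 1, "O": 2}``."""
        return dict(Counter(self.atoms))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from((i, {"element": el}) for i, el in enumerate(self.atoms))
        g.add_edges_from(self.bonds)
        return g

    def is_isomorphic(self, other: "MolecularGraph") -> bool:
        """Element-label-preserving graph isomorphism test."""
        return nx.is_isomorphic(
            self.to_networkx(),
            other.to_networkx(),
            node_match=lambda u, v: u["element"] == v["element"],
        )


@dataclass(frozen=True)
class EdgeDegreePartition:
    """Multiset of endpoint-degree pairs ``(d_u, d_v)`` with ``d_u <= d_v``.

    The sufficient statistic for every degree-based edge-sum index: the
    index value is the multiplicity-weighted sum of per-pair contributions.
    """

    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def items(self):
        return self.counts.items()


def edge_degree_partition(g: MolecularGraph) -> EdgeDegreePartition:
    """Edge-degree partition of ``g``: one ``(d_u, d_v)`` pair per bond."""
    deg = g.degrees()
    pairs = Counter(tuple(sorted((deg[a], deg[b]))) for a, b in g.bonds)
    return EdgeDegreePartition(dict(pairs))


# -- SMILES convenience path ------------------------------------------------


def from_smiles(smiles: str, name: str | None = None) -> MolecularGraph:
    """Build a hydrogen-included :class:`MolecularGraph` from a SMILES string.

    Hydrogens are added to satisfy standard valences and bond orders are
    collapsed, so a double bond contributes a single edge.  Requires rdkit.

    Raises
    ------
    SmilesError
        If the string cannot be parsed or encodes a disconnected
        (dot-separated) species.
    """
    from rdkit import Chem

    if "." in smiles:
        raise SmilesError(f"disconnected SMILES (dot-separated): {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    atoms = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return MolecularGraph(name or smiles, atoms, bonds)


def read_smiles_file(path) -> list[MolecularGraph]:
    """Read ``name<TAB>smiles`` lines (blank lines and ``#`` comments skipped)."""
    graphs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                name, smiles = line.split("\t")
            except ValueError as exc:
                raise SmilesError(
                    f"{path}:{lineno}: expected 'name<TAB>smiles', got {line!r}"
                ) from exc
            graphs.append(from_smiles(smiles, name=name))
    return graphs
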