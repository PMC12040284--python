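"""Molecular-graph construction, invariants and the SMILES path."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gourava_qspr import (
    AMINO_ACID_SMILES,
    AMINO_ACIDS,
    InvalidGraphError,
    MolecularGraph,
    SmilesError,
    amino_acid_fixture,
    edge_degree_partition,
    from_smiles,
)
from gourava_qspr.molgraph import read_smiles_file
from gourava_qspr.synthetic import random_molecular_graph

# Standard molecular formulas of the neutral forms.
FORMULAS = {
    "glycine": {"C": 2, "H": 5, "N": 1, "O": 2},
    "alanine": {"C": 3, "H": 7, "N": 1, "O": 2},
    "serine": {"C": 3, "H": 7, "N": 1, "O": 3},
    "aspartic acid": {"C": 4, "H": 7, "N": 1, "O": 4},
    "isoleucine": {"C": 6, "H": 13, "N": 1, "O": 2},
    "threonine": {"C": 4, "H": 9, "N": 1, "O": 3},
    "glutamic acid": {"C": 5, "H": 9, "N": 1, "O": 4},
    "valine": {"C": 5, "H": 11, "N": 1, "O": 2},
    "methionine": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "glutamine": {"C": 5, "H": 10, "N": 2, "O": 3},
    "leucine": {"C": 6, "H": 13, "N": 1, "O": 2},
    "lysine": {"C": 6, "H": 14, "N": 2, "O": 2},
    "arginine": {"C": 6, "H": 14, "N": 4, "O": 2},
}


@pytest.mark.parametrize("name", AMINO_ACIDS)
def test_fixture_formula_and_handshake(name):
    g = amino_acid_fixture(name)
    assert g.formula() == FORMULAS[name]
    assert sum(g.degrees()) == 2 * g.n_bonds
    # a molecule is acyclic here: tree => bonds = atoms - 1
    assert g.n_bonds == g.n_atoms - 1


def test_glycine_and_alanine_sizes(glycine, alanine):
    assert (glycine.n_atoms, glycine.n_bonds) == (10, 9)
    assert sum(el == "H" for el in glycine.atoms) == 5
    assert (alanine.n_atoms, alanine.n_bonds) == (13, 12)


@pytest.mark.parametrize("query", ["Gly", "GLYCINE", "gly"])
def test_fixture_name_resolution(query, glycine):
    assert amino_acid_fixture(query).bonds == glycine.bonds


def test_unknown_fixture_name_lists_valid_names():
    with pytest.raises(KeyError, match="glycine"):
        amino_acid_fixture("xyz")


def test_edge_degree_partition_glycine(glycine):
    # two N-H plus the carbonyl C=O give (1,3); two C(alpha)-H give (1,4);
    # N-C(alpha) and C(alpha)-C give (3,4); C-O(H) gives (2,3); O-H gives (1,2)
    part = edge_degree_partition(glycine)
    assert part.counts == {(1, 3): 3, (1, 4): 2, (3, 4): 2, (2, 3): 1, (1, 2): 1}
    assert part.total == glycine.n_bonds


@pytest.mark.parametrize(
    "atoms, bonds, expected",
    [
        (["C", "C", "C"], [(0, 1), (1, 2)], {(1, 2): 2}),  # path of 3
        (["C", "C"], [(0, 1)], {(1, 1): 1}),  # single bond
    ],
)
def test_edge_degree_partition_small(atoms, bonds, expected):
    g = MolecularGraph("toy", atoms, bonds, hydrogens_explicit=False)
    assert edge_degree_partition(g).counts == expected


@pytest.mark.parametrize(
    "atoms, bonds, message",
    [
        (["C", "C"], [(0, 0)], "self-loop"),
        (["C", "C"], [(0, 1), (1, 0)], "duplicate"),
        (["C", "C", "C", "C"], [(0, 1), (2, 3)], "disconnected"),
        (["O", "C", "C", "C"], [(0, 1), (0, 2), (0, 3)], "valence cap"),
        (["H", "C", "C"], [(0, 1), (0, 2)], "degree 2"),
        (["C", "C", "C"], [(0, 1)], "no bonds"),
    ],
)
def test_invariant_violations_raise(atoms, bonds, message):
    with pytest.raises(InvalidGraphError, match=message):
        MolecularGraph("bad", atoms, bonds)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(n_heavy=st.integers(1, 14), seed=st.integers(0, 2 ** 20))
def test_random_graph_handshake_and_hydrogen_degrees(n_heavy, seed):
    g = random_molecular_graph(n_heavy, seed)
    deg = g.degrees()
    assert sum(deg) == 2 * g.n_bonds
    assert all(deg[i] == 1 for i, el in enumerate(g.atoms) if el == "H")
    assert min(deg) >= 1


class TestSmiles:
    def test_water(self):
        g = from_smiles("O")
        assert g.n_atoms == 3 and g.n_bonds == 2
        assert sorted(g.degrees()) == [1, 1, 2]

    def test_glycine_isomorphic_to_fixture(self, glycine):
        assert from_smiles("NCC(=O)O").is_isomorphic(glycine)

    @pytest.mark.parametrize("name", AMINO_ACIDS)
    def test_all_fixture_smiles_isomorphic(self, name):
        assert from_smiles(AMINO_ACID_SMILES[name]).is_isomorphic(
            amino_acid_fixture(name)
        )

    def test_disconnected_smiles_rejected(self):
        with pytest.raises(SmilesError, match="disconnected"):
            from_smiles("C.C")

    def test_unparsable_smiles_rejected(self):
        with pytest.raises(SmilesError, match="unparsable"):
            from_smiles("not-a-smiles(((")

    def test_read_smiles_file(self, tmp_path, glycine):
        path = tmp_path / "mols.smi"
        path.write_text("# comment\nglycine\tNCC(=O)O\nwater\tO\n")
        graphs = read_smiles_file(path)
        assert [g.name for g in graphs] == ["glycine", "water"]
        assert graphs[0].is_isomorphic(glycine)
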