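import numpy as np
import pytest

from gourava_qspr import amino_acid_fixture, load_printed_index_table, load_property_table


@pytest.fixture(scope="session")
def glycine():
    return amino_acid_fixture("glycine")


@pytest.fixture(scope="session")
def alanine():
    return amino_acid_fixture("alanine")


@pytest.fixture(scope="session")
def properties():
    return load_property_table()


@pytest.fixture(scope="session")
def printed_indices():
    return load_printed_index_table()


# Independent brute-force oracle: per-edge formulas re-stated from scratch,
# looping over the raw bond list with no partition intermediate.
def brute_force_index(graph, index_id):
    deg = [0] * graph.n_atoms
    for a, b in graph.bonds:
        deg[a] += 1
        deg[b] += 1
    total = 0
    for a, b in graph.bonds:
        d, e = deg[a], deg[b]
        total += {
            "GO1": d + e + d * e,
            "GO2": (d + e) * d * e,
            "HGO1": (d + e + d * e) ** 2,
            "HGO2": ((d + e) * d * e) ** 2,
            "AGO1": d ** 2 + e ** 2 + d * e,
            "AGO2": (d ** 2 + e ** 2) * d * e,
            "GGO1": d ** 3 + e ** 3 + d * e,
            "GGO2": (d ** 3 + e ** 3) * d * e,
        }[index_id]
    return total


@pytest.fixture(scope="session")
def brute_force():
    return brute_force_index


def normal_equations_coefficients(X, y):
    """Textbook normal-equations OLS: solve (X'X) beta = X'y directly."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.fixture(scope="session")
def normal_equations():
    return normal_equations_coefficients
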