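"""Built-in hydrogen-included graphs of the 13 amino acids under study.

The structures are the neutral (non-zwitterionic) forms.  Atom and bond
lists are frozen literals — hand-checked against the structural formulas —
rather than being regenerated from SMILES at import time, so the core
package has no chemistry-toolkit dependency and atom ordering is stable
across versions.  The SMILES strings are kept alongside as the input to
the optional :func:`gourava_qspr.molgraph.from_smiles` convenience path;
tests assert label-preserving isomorphism between the two routes.

Atom ordering convention: heavy atoms first (main chain then substituents,
in SMILES order), hydrogens appended grouped by parent atom.
"""

from __future__ import annotations

from .molgraph import MolecularGraph

__all__ = ["AMINO_ACIDS", "AMINO_ACID_SMILES", "amino_acid_fixture"]

#: name -> neutral-form SMILES (optional convenience path; see module docstring)
AMINO_ACID_SMILES = {
    "glycine": "NCC(=O)O",
    "alanine": "CC(N)C(=O)O",
    "serine": "OCC(N)C(=O)O",
    "aspartic acid": "OC(=O)CC(N)C(=O)O",
    "isoleucine": "CCC(C)C(N)C(=O)O",
    "threonine": "CC(O)C(N)C(=O)O",
    "glutamic acid": "OC(=O)CCC(N)C(=O)O",
    "valine": "CC(C)C(N)C(=O)O",
    "methionine": "CSCCC(N)C(=O)O",
    "glutamine": "NC(=O)CCC(N)C(=O)O",
    "leucine": "CC(C)CC(N)C(=O)O",
    "lysine": "NCCCCC(N)C(=O)O",
    "arginine": "NC(=N)NCCCC(N)C(=O)O",
}

# name -> (element string, bond list); one character per atom.
_RAW = {
    "glycine": (
        "NCCOOHHHHH",
        [(0, 1), (0, 5), (0, 6), (1, 2), (1, 7), (1, 8), (2, 3), (2, 4), (4, 9)],
    ),
    "alanine": (
        "CCNCOOHHHHHHH",
        [(0, 1), (0, 6), (0, 7), (0, 8), (1, 2), (1, 3), (1, 9), (2, 10), (2, 11),
         (3, 4), (3, 5), (5, 12)],
    ),
    "serine": (
        "OCCNCOOHHHHHHH",
        [(0, 1), (0, 7), (1, 2), (1, 8), (1, 9), (2, 3), (2, 4), (2, 10), (3, 11),
         (3, 12), (4, 5), (4, 6), (6, 13)],
    ),
    "aspartic acid": (
        "OCOCCNCOOHHHHHHH",
        [(0, 1), (0, 9), (1, 2), (1, 3), (3, 4), (3, 10), (3, 11), (4, 5), (4, 6),
         (4, 12), (5, 13), (5, 14), (6, 7), (6, 8), (8, 15)],
    ),
    "isoleucine": (
        "CCCCCNCOOHHHHHHHHHHHHH",
        [(0, 1), (0, 9), (0, 10), (0, 11), (1, 2), (1, 12), (1, 13), (2, 3), (2, 4),
         (2, 14), (3, 15), (3, 16), (3, 17), (4, 5), (4, 6), (4, 18), (5, 19),
         (5, 20), (6, 7), (6, 8), (8, 21)],
    ),
    "threonine": (
        "CCOCNCOOHHHHHHHHH",
        [(0, 1), (0, 8), (0, 9), (0, 10), (1, 2), (1, 3), (1, 11), (2, 12), (3, 4),
         (3, 5), (3, 13), (4, 14), (4, 15), (5, 6), (5, 7), (7, 16)],
    ),
    "glutamic acid": (
        "OCOCCCNCOOHHHHHHHHH",
        [(0, 1), (0, 10), (1, 2), (1, 3), (3, 4), (3, 11), (3, 12), (4, 5), (4, 13),
         (4, 14), (5, 6), (5, 7), (5, 15), (6, 16), (6, 17), (7, 8), (7, 9), (9, 18)],
    ),
    "valine": (
        "CCCCNCOOHHHHHHHHHHH",
        [(0, 1), (0, 8), (0, 9), (0, 10), (1, 2), (1, 3), (1, 11), (2, 12), (2, 13),
         (2, 14), (3, 4), (3, 5), (3, 15), (4, 16), (4, 17), (5, 6), (5, 7), (7, 18)],
    ),
    "methionine": (
        "CSCCCNCOOHHHHHHHHHHH",
        [(0, 1), (0, 9), (0, 10), (0, 11), (1, 2), (2, 3), (2, 12), (2, 13), (3, 4),
         (3, 14), (3, 15), (4, 5), (4, 6), (4, 16), (5, 17), (5, 18), (6, 7), (6, 8),
         (8, 19)],
    ),
    "glutamine": (
        "NCOCCCNCOOHHHHHHHHHH",
        [(0, 1), (0, 10), (0, 11), (1, 2), (1, 3), (3, 4), (3, 12), (3, 13), (4, 5),
         (4, 14), (4, 15), (5, 6), (5, 7), (5, 16), (6, 17), (6, 18), (7, 8), (7, 9),
         (9, 19)],
    ),
    "leucine": (
        "CCCCCNCOOHHHHHHHHHHHHH",
        [(0, 1), (0, 9), (0, 10), (0, 11), (1, 2), (1, 3), (1, 12), (2, 13), (2, 14),
         (2, 15), (3, 4), (3, 16), (3, 17), (4, 5), (4, 6), (4, 18), (5, 19), (5, 20),
         (6, 7), (6, 8), (8, 21)],
    ),
    "lysine": (
        "NCCCCCNCOOHHHHHHHHHHHHHH",
        [(0, 1), (0, 10), (0, 11), (1, 2), (1, 12), (1, 13), (2, 3), (2, 14), (2, 15),
         (3, 4), (3, 16), (3, 17), (4, 5), (4, 18), (4, 19), (5, 6), (5, 7), (5, 20),
         (6, 21), (6, 22), (7, 8), (7, 9), (9, 23)],
    ),
    "arginine": (
        "NCNNCCCCNCOOHHHHHHHHHHHHHH",
        [(0, 1), (0, 12), (0, 13), (1, 2), (1, 3), (2, 14), (3, 4), (3, 15), (4, 5),
         (4, 16), (4, 17), (5, 6), (5, 18), (5, 19), (6, 7), (6, 20), (6, 21), (7, 8),
         (7, 9), (7, 22), (8, 23), (8, 24), (9, 10), (9, 11), (11, 25)],
    ),
}

#: Canonical molecule names, in the order the property table lists them.
AMINO_ACIDS = (
    "glycine", "alanine", "serine", "aspartic acid", "isoleucine", "threonine",
    "glutamic acid", "valine", "methionine", "glutamine", "leucine", "lysine",
    "arginine",
)

_THREE_LETTER = {
    "gly": "glycine", "ala": "alanine", "ser": "serine", "asp": "aspartic acid",
    "ile": "isoleucine", "thr": "threonine", "glu": "glutamic acid",
    "val": "valine", "met": "methionine", "gln": "glutamine", "leu": "leucine",
    "lys": "lysine", "arg": "arginine",
}


def _resolve(name: str) -> str:
    key = name.strip().lower()
    if key in _RAW:
        return key
    if key in _THREE_LETTER:
        return _THREE_LETTER[key]
    raise KeyError(
        f"unknown amino acid {name!r}; valid names: {', '.join(AMINO_ACIDS)} "
        f"(3-letter codes accepted)"
    )


def amino_acid_fixture(name: str) -> MolecularGraph:
    """Hydrogen-included graph of one of the 13 amino acids.

    ``name`` is case-insensitive; 3-letter codes (``Gly``, ``Ala``, ...) are
    accepted.  Raises ``KeyError`` listing the valid names otherwise.
    """
    canonical = _resolve(name)
    elements, bonds = _RAW[canonical]
    return MolecularGraph(canonical, tuple(elements), bonds)
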