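"""Synthetic molecular graphs and property vectors with known ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`random_molecular_graph` grows a random heavy-atom *tree* under
  element valence caps and then fills the remaining valences with explicit
  hydrogens — mirroring the acyclic, hydrogen-included structure of the 13
  study molecules.  Rings are deliberately out of scope.
* :func:`simulate_property` produces a response vector from a chosen model
  form with known coefficients plus additive Gaussian noise on the scale
  the form is fitted on (log scale for the exponential form, matching the
  OLS assumptions of the regression module).

All randomness flows from one master seed through
``numpy.random.SeedSequence.spawn`` (the documented splitting rule), so a
dataset regenerates bit-identically from its recorded seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import index_table
from .molgraph import VALENCE_CAPS, MolecularGraph
from .regression import CURVE_FORMS

__all__ = [
    "SyntheticDataset",
    "random_molecular_graph",
    "simulate_property",
    "make_dataset",
    "recovery_experiment",
]

#: Heavy-element draw weights: carbon-dominated organic composition.
ELEMENT_WEIGHTS = {"C": 0.70, "N": 0.10, "O": 0.15, "S": 0.05}

#: Coefficient-vector length per form (intercept included).
_N_COEF = {"linear": 2, "quadratic": 3, "cubic": 4, "logarithmic": 2, "exponential": 2}


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated graphs, their index table, and a response with known truth."""

    graphs: tuple[MolecularGraph, ...]
    index_table: pd.DataFrame
    index_id: str
    property: np.ndarray
    form: str
    coefficients: tuple[float, ...]
    noise_sd: float
    seed: int


def random_molecular_graph(n_heavy: int, seed) -> MolecularGraph:
    """Random valence-respecting tree of ``n_heavy`` heavy atoms plus hydrogens.

    The first atom is a carbon root; each subsequent heavy atom attaches to
    a uniformly chosen atom with spare valence.  Hydrogens then fill every
    remaining valence slot, so heavy-atom degrees equal their caps minus
    nothing — e.g. ``n_heavy=1`` always yields methane (5 atoms, 4 bonds).
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n_heavy < 1:
        raise ValueError(f"n_heavy must be >= 1, got {n_heavy}")
    rng = np.random.default_rng(seed)
    symbols = list(ELEMENT_WEIGHTS)
    weights = np.array(list(ELEMENT_WEIGHTS.values()))
    atoms = ["C"]
    bonds: list[tuple[int, int]] = []
    free = [VALENCE_CAPS["C"]]  # spare valence per heavy atom
    for _ in range(n_heavy - 1):
        open_sites = [i for i, f in enumerate(free) if f > 0]
        if not open_sites:  # cannot happen for trees of C/N/O/S, kept as a guard
            break
        parent = int(rng.choice(open_sites))
        element = str(rng.choice(symbols, p=weights))
        atoms.append(element)
        free.append(VALENCE_CAPS[element] - 1)
        free[parent] -= 1
        bonds.append((parent, len(atoms) - 1))
    for i in range(n_heavy):  # hydrogen fill
        for _ in range(free[i]):
            atoms.append("H")
            bonds.append((i, len(atoms) - 1))
    return MolecularGraph(f"random-{n_heavy}", atoms, bonds)


def _model_mean(x: np.ndarray, form: str, coefficients) -> np.ndarray:
    c = list(coefficients)
    if len(c) != _N_COEF[form]:
        raise ValueError(
            f"{form} form takes {_N_COEF[form]} coefficients (intercept first), got {len(c)}"
        )
    if form == "linear":
        return c[0] + c[1] * x
    if form == "quadratic":
        return c[0] + c[1] * x + c[2] * x ** 2
    if form == "cubic":
        return c[0] + c[1] * x + c[2] * x ** 2 + c[3] * x ** 3
    if form == "logarithmic":
        return c[0] + c[1] * np.log(x)
    if form == "exponential":
        return c[0] * np.exp(c[1] * x)
    raise ValueError(f"unknown form {form!r}; expected one of {CURVE_FORMS}")


def simulate_property(index_values, form: str, coefficients, noise_sd: float, seed) -> np.ndarray:
    """Response vector from ``form`` with known coefficients plus Gaussian noise.

    Noise is additive on the form's fitted scale: ``y = f(x) + eps`` for
    the polynomial and logarithmic forms, and multiplicative
    ``y = a * exp(b x) * exp(eps)`` for the exponential form (additive in
    log-response).  ``noise_sd`` must be >= 0.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    x = np.asarray(index_values, dtype=float)
    rng = np.random.default_rng(seed)
    mean = _model_mean(x, form, coefficients)
    eps = rng.normal(0.0, noise_sd, size=x.shape)
    if form == "exponential":
        return mean * np.exp(eps)
    return mean + eps


def make_dataset(n_molecules: int, form: str, coefficients, noise_sd: float,
                 seed: int, index_id: str = "GO1", heavy_range=(2, 9)) -> SyntheticDataset:
    """Random graphs + index table + simulated response, fully reproducible.

    The master ``seed`` is split into one child seed per graph plus one for
    the noise draw via ``SeedSequence.spawn``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_molecules + 1)
    rng_sizes = np.random.default_rng(children[0])
    graphs = []
    for i in range(n_molecules):
        n_heavy = int(rng_sizes.integers(heavy_range[0], heavy_range[1] + 1))
        g = random_molecular_graph(n_heavy, np.random.default_rng(children[i + 1]))
        graphs.append(MolecularGraph(f"mol{i:04d}", g.atoms, g.bonds))
    table = index_table(graphs)
    x = table[index_id].to_numpy(dtype=float)
    y = simulate_property(x, form, coefficients, noise_sd, children[0].spawn(1)[0])
    return SyntheticDataset(tuple(graphs), table, index_id, y, form,
                            tuple(map(float, coefficients)), float(noise_sd), seed)


def recovery_experiment(form: str, coefficients, noise_grid, n_grid,
                        replicates: int, seed: int,
                        x_range=(25.0, 300.0)) -> pd.DataFrame:
    """Monte-Carlo coefficient recovery across noise levels and sample sizes.

    For each (noise_sd, n) cell, ``replicates`` datasets are generated
    (predictors uniform on ``x_range``, spanning realistic index
    magnitudes), the generating form is refitted, and per-coefficient mean
    bias and RMSE are tabulated.  Returns a long-format frame with one row
    per (noise_sd, n, coefficient).
    """
    from .regression import fit_curve

    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    truth = np.asarray(coefficients, dtype=float)
    _model_mean(np.array([x_range[0]]), form, truth)  # validates form/length
    master = np.random.SeedSequence(seed)
    rows = []
    for noise_sd in noise_grid:
        for n in n_grid:
            errors = np.empty((replicates, len(truth)))
            for rep, child in enumerate(master.spawn(replicates)):
                rng = np.random.default_rng(child)
                x = rng.uniform(x_range[0], x_range[1], size=n)
                y = simulate_property(x, form, truth, noise_sd, rng)
                fit = fit_curve(x, y, form)
                errors[rep] = np.array([fit.intercept, *fit.coefficients]) - truth
            for j in range(len(truth)):
                rows.append({
                    "form": form, "noise_sd": float(noise_sd), "n": int(n),
                    "coefficient": f"c{j}", "truth": truth[j],
                    "bias": float(errors[:, j].mean()),
                    "rmse": float(np.sqrt((errors[:, j] ** 2).mean())),
                    "replicates": replicates,
                })
    return pd.DataFrame(rows)
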