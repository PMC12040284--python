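"""End-to-end QSPR study: audit the index table, fit the model grid.

The study couples the eight Gourava-family indices of 13 amino acids to 11
physicochemical properties through five curvilinear forms plus an
eight-predictor multiple linear model.  Three index tables are available as
regression input:

``printed``
    The published eight-column table, verbatim.
``computed``
    Recomputed from the built-in hydrogen-included graphs.
``regression`` (default)
    The printed table with the three misprinted cells that the published
    regression statistics themselves pin down replaced by their recomputed
    values (glycine GO1, glutamic-acid GO1, lysine AGO1).  With this input
    the published per-index statistics for GO1 and the multiple-regression
    R/R^2 values are reproduced at printed precision.  See
    ``docs/methods.md`` for the reconstruction.

The audit (:func:`verify_table2`) always compares printed against
recomputed values cell by cell and reports every disagreement; nothing is
silently overwritten.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .aminoacids import AMINO_ACIDS, amino_acid_fixture
from .indices import GOURAVA_INDICES, index_table
from .regression import (
    CURVE_FORMS,
    DomainError,
    RegressionFit,
    fit_curve,
    fit_multiple,
    format_p,
)

__all__ = [
    "PROPERTY_COLUMNS",
    "DEFAULT_GRID_PROPERTIES",
    "REGRESSION_CORRECTIONS",
    "load_property_table",
    "load_printed_index_table",
    "computed_index_table",
    "regression_index_table",
    "verify_table2",
    "run_model_grid",
    "run_multiple_grid",
    "select_best",
    "full_report",
    "load_config",
]

logger = logging.getLogger(__name__)

#: The 11 property columns: molar mass (g/mol), melting point (degC),
#: isoelectric point, the two acid dissociation constants, hydropathy
#: index, side-chain volume (A^3), logP, density (g/cm^3), frequency of
#: occurrence in proteins, and solution pH descriptor.
PROPERTY_COLUMNS = ("Da", "MP", "Pl", "pKa1", "pKa2", "HI", "A3", "LogP", "D", "FP", "pH")

#: Properties the published curvilinear tables report; the multiple stage
#: always runs all 11.
DEFAULT_GRID_PROPERTIES = ("Da", "Pl", "A3")

#: (molecule, index) -> recomputed value.  The three printed cells that the
#: published regression statistics demonstrably contradict; applied by the
#: "regression" table variant.
REGRESSION_CORRECTIONS = {
    ("glycine", "GO1"): 93,
    ("glutamic acid", "GO1"): 210,
    ("lysine", "AGO1"): 583,
}


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("gourava_qspr.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, index_col="molecule")


def load_property_table(path=None) -> pd.DataFrame:
    """The 11-property table for the 13 amino acids (rows indexed by name)."""
    df = pd.read_csv(path, index_col="molecule") if path else _read_packaged_csv("properties.csv")
    missing = set(PROPERTY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"property table is missing columns: {sorted(missing)}")
    if df.isna().any().any():
        raise ValueError("property table contains missing cells")
    return df


def load_printed_index_table(path=None) -> pd.DataFrame:
    """The published eight-column index table, verbatim."""
    df = pd.read_csv(path, index_col="molecule") if path else _read_packaged_csv("indices_printed.csv")
    missing = set(GOURAVA_INDICES) - set(df.columns)
    if missing:
        raise ValueError(f"index table is missing columns: {sorted(missing)}")
    return df


def computed_index_table() -> pd.DataFrame:
    """Index table recomputed from the built-in amino-acid graphs."""
    return index_table(amino_acid_fixture(n) for n in AMINO_ACIDS)


def regression_index_table(variant: str = "regression") -> pd.DataFrame:
    """Index table used as regression input (see module docstring)."""
    if variant == "computed":
        return computed_index_table()
    table = load_printed_index_table()
    if variant == "printed":
        return table
    if variant == "regression":
        table = table.copy()
        for (molecule, index_id), value in REGRESSION_CORRECTIONS.items():
            table.loc[molecule, index_id] = value
        return table
    raise ValueError(
        f"unknown table variant {variant!r}; expected 'printed', 'computed' or 'regression'"
    )


# -- audit -------------------------------------------------------------------


def verify_table2(graphs=None, printed: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cell-by-cell audit of the printed index table against recomputation.

    Returns a long-format report with one row per (molecule, index):
    printed value, recomputed value, match flag (exact integer equality)
    and absolute difference.  Mismatches are reported, never corrected.
    """
    if printed is None:
        printed = load_printed_index_table()
    if graphs is None:
        graphs = [amino_acid_fixture(n) for n in AMINO_ACIDS]
    computed = index_table(graphs)
    missing = set(printed.index) - set(computed.index)
    if missing:
        raise KeyError(f"no fixture for printed molecules: {sorted(missing)}")
    rows = []
    for molecule in printed.index:
        for index_id in GOURAVA_INDICES:
            p = int(printed.loc[molecule, index_id])
            c = int(computed.loc[molecule, index_id])
            rows.append(
                {"molecule": molecule, "index": index_id, "printed": p,
                 "computed": c, "match": p == c, "abs_diff": abs(p - c)}
            )
    return pd.DataFrame(rows)


# -- model grid ----------------------------------------------------------------


def _fit_row(fit: RegressionFit, index_id: str, prop: str) -> dict:
    coefs = fit.coefficients + (np.nan,) * (3 - len(fit.coefficients))
    return {
        "index_id": index_id, "property": prop, "form": fit.form,
        "a": fit.intercept, "b1": coefs[0], "b2": coefs[1], "b3": coefs[2],
        "R": fit.r, "R2": fit.r2, "adj_R2": fit.adj_r2, "SEE": fit.see,
        "F": fit.f, "p": fit.p, "p_formatted": format_p(fit.p),
        "n": fit.n, "k": fit.k, "status": "ok", "fit": fit,
    }


def _skipped_row(index_id: str, prop: str, form: str, reason: str) -> dict:
    return {
        "index_id": index_id, "property": prop, "form": form,
        "a": np.nan, "b1": np.nan, "b2": np.nan, "b3": np.nan,
        "R": np.nan, "R2": np.nan, "adj_R2": np.nan, "SEE": np.nan,
        "F": np.nan, "p": np.nan, "p_formatted": "",
        "n": np.nan, "k": np.nan, "status": f"skipped: {reason}", "fit": None,
    }


def _check_keys(indices: pd.DataFrame, properties: pd.DataFrame) -> None:
    if set(indices.index) != set(properties.index):
        diff = set(indices.index) ^ set(properties.index)
        raise KeyError(f"molecule keys of index and property tables differ: {sorted(diff)}")


def run_model_grid(indices: pd.DataFrame, properties: pd.DataFrame,
                   forms=CURVE_FORMS, dependent_subset=DEFAULT_GRID_PROPERTIES,
                   index_subset=GOURAVA_INDICES) -> pd.DataFrame:
    """One record per (index, property, form), in long format.

    A form whose domain constraint fails for a given pair (e.g. the
    exponential form on a response with non-positive values) contributes a
    placeholder record with ``status`` explaining the skip and NaN
    statistics, so the grid cardinality is always
    ``len(index_subset) * len(dependent_subset) * len(forms)``.
    """
    _check_keys(indices, properties)
    properties = properties.loc[indices.index]  # align row order
    rows = []
    for index_id in index_subset:
        x = indices[index_id].to_numpy(dtype=float)
        for prop in dependent_subset:
            y = properties[prop].to_numpy(dtype=float)
            for form in forms:
                try:
                    fit = fit_curve(x, y, form)
                except DomainError as exc:
                    logger.warning("skipping %s ~ %s (%s): %s", prop, index_id, form, exc)
                    rows.append(_skipped_row(index_id, prop, form, str(exc)))
                    continue
                rows.append(_fit_row(fit, index_id, prop))
    return pd.DataFrame(rows)


def run_multiple_grid(indices: pd.DataFrame, properties: pd.DataFrame,
                      dependent_subset=PROPERTY_COLUMNS) -> pd.DataFrame:
    """One eight-predictor multiple fit per property, in long format."""
    _check_keys(indices, properties)
    properties = properties.loc[indices.index]
    X = indices[list(GOURAVA_INDICES)].to_numpy(dtype=float)
    rows = []
    for prop in dependent_subset:
        fit = fit_multiple(X, properties[prop].to_numpy(dtype=float))
        row = _fit_row(fit, "+".join(GOURAVA_INDICES), prop)
        row["form"] = "multiple"
        for name, b in zip(GOURAVA_INDICES, fit.coefficients):
            row[f"b_{name}"] = b
        rows.append(row)
    return pd.DataFrame(rows)


def select_best(grid: pd.DataFrame, criterion: str = "R") -> pd.DataFrame:
    """Best form per (index, property): max R (default) or min SEE.

    Ties are broken in favour of the form with fewer parameters.
    """
    if len(grid) == 0:
        raise ValueError("empty model grid")
    if criterion not in ("R", "SEE"):
        raise ValueError(f"criterion must be 'R' or 'SEE', got {criterion!r}")
    ascending = criterion == "SEE"
    ordered = grid.sort_values(
        ["index_id", "property", criterion, "k"],
        ascending=[True, True, ascending, True],
        na_position="last",
    )
    return ordered.drop_duplicates(["index_id", "property"]).reset_index(drop=True)


# -- reporting ---------------------------------------------------------------


def load_config(path) -> dict:
    """YAML run configuration: dependent subset, forms, criterion, figures."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - {"properties", "forms", "criterion", "table_variant", "figures"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def full_report(outdir, properties: pd.DataFrame | None = None,
                indices: pd.DataFrame | None = None,
                dependent_subset=DEFAULT_GRID_PROPERTIES, forms=CURVE_FORMS,
                criterion: str = "R", table_variant: str = "regression",
                figures: bool = False) -> dict:
    """Run the whole study and write its tables (and optional figures).

    Writes ``grid.csv``, ``multiple.csv``, ``audit.csv`` and
    ``best_models.md`` under ``outdir`` and returns the in-memory frames.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if properties is None:
        properties = load_property_table()
    if indices is None:
        indices = regression_index_table(table_variant)

    audit = verify_table2()
    grid = run_model_grid(indices, properties, forms=forms, dependent_subset=dependent_subset)
    multiple = run_multiple_grid(indices, properties)

    audit.to_csv(outdir / "audit.csv", index=False)
    grid.drop(columns="fit").to_csv(outdir / "grid.csv", index=False)
    multiple.drop(columns="fit").to_csv(outdir / "multiple.csv", index=False)

    best = select_best(grid, criterion=criterion)
    lines = ["# Best model per (index, property)", "",
             f"Criterion: {'max R' if criterion == 'R' else 'min SEE'}; ties broken "
             "by fewer parameters.", "",
             "| index | property | form | R | SEE | p |", "|---|---|---|---|---|---|"]
    for _, row in best.iterrows():
        lines.append(
            f"| {row['index_id']} | {row['property']} | {row['form']} | {row['R']:.3f} "
            f"| {row['SEE']:.3f} | {row['p_formatted']} |"
        )
    (outdir / "best_models.md").write_text("\n".join(lines) + "\n")

    if figures:
        import matplotlib.pyplot as plt

        from . import plots

        figdir = outdir / "figures"
        figdir.mkdir(exist_ok=True)
        for index_id in GOURAVA_INDICES:
            for prop in dependent_subset:
                fig = plots.plot_curve_family(indices, properties, index_id, prop, forms=forms)
                fig.savefig(figdir / f"curves_{index_id}_{prop}.png", dpi=120)
                plt.close(fig)
        for _, row in multiple.iterrows():
            fig = plots.plot_observed_vs_predicted(
                row["fit"], indices[list(GOURAVA_INDICES)], properties[row["property"]]
            )
            fig.savefig(figdir / f"multiple_{row['property']}.png", dpi=120)
            plt.close(fig)

    return {"audit": audit, "grid": grid, "multiple": multiple, "best": best}
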