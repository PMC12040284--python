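"""Best-effort study figures: fitted-curve overlays and observed-vs-predicted."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless by default; callers save to file
import matplotlib.pyplot as plt

from .regression import CURVE_FORMS, DomainError, fit_curve

__all__ = ["plot_curve_family", "plot_observed_vs_predicted"]


def plot_curve_family(indices, properties, index_id, prop, forms=CURVE_FORMS, ax=None):
    """Scatter of one property against one index with fitted curves overlaid."""
    x = indices[index_id].to_numpy(dtype=float)
    y = properties.loc[indices.index, prop].to_numpy(dtype=float)
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4.5))
    else:
        fig = ax.figure
    ax.scatter(x, y, color="black", zorder=3, label="observed")
    xs = np.linspace(x.min(), x.max(), 200)
    for form in forms:
        try:
            fit = fit_curve(x, y, form)
        except DomainError:
            continue
        ax.plot(xs, fit.predict(xs), label=f"{form} (R={fit.r:.3f})")
    ax.set_xlabel(index_id)
    ax.set_ylabel(prop)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_observed_vs_predicted(fit, X, y, ax=None):
    """Observed vs predicted scatter for a multiple-regression fit."""
    yhat = fit.predict(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    ax.scatter(yhat, y, color="tab:blue")
    lo, hi = min(yhat.min(), y.min()), max(yhat.max(), y.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel("predicted")
    ax.set_ylabel("observed")
    ax.set_title(f"R = {fit.r:.3f}")
    fig.tight_layout()
    return fig
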