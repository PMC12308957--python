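"""Plots: fitted parameter trajectories and residual Q-Q panels."""

from __future__ import annotations

import numpy as np

_GROUP_COLORS = {1: "#1f77b4", 2: "#d62728", 3: "#2ca02c", 4: "#9467bd"}


def plot_curves(fit, parameters=("rho", "p1", "p2"), n_grid: int = 100,
                out=None, axes=None):
    """Fitted curves with 95% bands per group, one panel per parameter.

    ``out`` saves the figure (vector formats like .pdf/.svg recommended);
    returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .estimation import predict_curves

    design = fit.copula_fit.design
    groups = sorted(set(design.group.tolist()))
    if axes is None:
        fig, axes = plt.subplots(1, len(parameters),
                                 figsize=(4 * len(parameters), 3.2),
                                 squeeze=False)
        axes = axes[0]
    else:
        fig = axes[0].figure
    for ax, p in zip(axes, parameters):
        for g in groups:
            zg = design.z[design.group == g]
            grid = np.linspace(zg.min(), zg.max(), n_grid)
            c = predict_curves(fit, grid, group=g, parameters=[p])[p]
            color = _GROUP_COLORS.get(g, "k")
            ax.plot(grid, c["value"], color=color, label=f"group {g}")
            ax.fill_between(grid, c["lower"], c["upper"], alpha=0.2,
                            color=color, linewidth=0)
        ax.set_xlabel("pseudotime")
        ax.set_ylabel(p)
        if p == "rho":
            ax.axhline(0.0, color="gray", linewidth=0.5)
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out)
    return fig


def plot_qq(residuals, out=None, ax=None):
    """Normal Q-Q plot of a :class:`~dynacor.diagnostics.ResidualSet`."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .diagnostics import qq_points

    theo, emp, dev = qq_points(residuals)
    if ax is None:
        fig, ax = plt.subplots(figsize=(3.5, 3.5))
    else:
        fig = ax.figure
    ax.plot(theo, emp, ".", markersize=2, color="#1f77b4")
    lims = [min(theo[0], emp[0]), max(theo[-1], emp[-1])]
    ax.plot(lims, lims, color="gray", linewidth=0.8)
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("empirical quantile")
    ax.set_title(f"max deviation {dev:.2f}", fontsize=9)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out)
    return fig
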