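"""Plotting helpers for fit results and the comparison/screen tables."""

from __future__ import annotations

import numpy as np

from .hierarchy import PosteriorDraws


def plot_posterior(draws: PosteriorDraws, parameters=None, ax=None):
    """Histogram of constrained-scale population-mean draws per parameter."""
    import matplotlib.pyplot as plt

    parameters = list(parameters or draws.param_names)
    if ax is None:
        _, axes = plt.subplots(1, len(parameters), figsize=(3 * len(parameters), 2.5))
    else:
        axes = np.atleast_1d(ax)
    axes = np.atleast_1d(axes)
    for a, name in zip(axes, parameters):
        m = draws.population_mean_draws(name)
        a.hist(m, bins=40, density=True, alpha=0.8)
        a.set_title(name)
    return axes


def plot_comparison(rows, ax=None):
    """ELPD differences with +/- 1 SE bars, best model at zero."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    labels = [str(r.model_id) for r in rows]
    diffs = [r.elpd_diff for r in rows]
    errs = [r.se_diff for r in rows]
    ax.errorbar(diffs, range(len(rows)), xerr=errs, fmt="o")
    ax.set_yticks(range(len(rows)), labels)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("ELPD difference vs best")
    ax.set_ylabel("model")
    return ax
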