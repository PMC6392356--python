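"""Diagnostic figures: standardized-difference forest plot for the null
model, and replicate histograms for the sensitivity analysis."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .subset_nullmodel import NullModelResult
from .subset_sensitivity import SensitivityResult


def plot_null_model(result: NullModelResult, ax=None):
    """Standardized difference (null mean - observed)/null SD per
    characteristic, with significance stars; positive bars mean random
    subsets exceed the focal subset."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    t = result.table
    ypos = np.arange(len(t))[::-1]
    ax.barh(ypos, t["z"], color=np.where(t["significant"], "#c0504d", "#7f9db9"))
    ax.set_yticks(ypos, t.index)
    ax.axvline(0.0, color="k", lw=0.8)
    for y, (z, sig) in zip(ypos, zip(t["z"], t["significant"])):
        if sig:
            ax.text(z, y, " *", va="center", ha="left" if z >= 0 else "right")
    ax.set_xlabel("standardized difference (null mean − focal) / null SD")
    return ax


def plot_sensitivity_histograms(
    sens: SensitivityResult,
    focal_table: pd.DataFrame | None = None,
    value: str = "effects",
    coefficients: list[str] | None = None,
):
    """Histogram grid of replicate effect sizes (or p-values), with
    markers for the complete-data value (black) and, when a focal effects
    table is given, the focal-subset value (red)."""
    import matplotlib.pyplot as plt

    data = sens.effects if value == "effects" else sens.p_values
    coefs = coefficients or [c for c in data.columns if c != "intercept"]
    ncol = 3
    nrow = int(np.ceil(len(coefs) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.6 * nrow), squeeze=False)
    comp = sens.complete.effects.table
    col = "estimate" if value == "effects" else "p"
    for ax, c in zip(axes.ravel(), coefs):
        ax.hist(data[c].dropna(), bins=30, color="#b0b0b0")
        ax.axvline(comp.loc[c, col], color="k", lw=1.5)
        if focal_table is not None and c in focal_table.index:
            ax.axvline(focal_table.loc[c, col], color="r", lw=1.5)
        ax.set_title(c, fontsize=9)
    for ax in axes.ravel()[len(coefs):]:
        ax.set_visible(False)
    fig.tight_layout()
    return fig
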