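"""Diagnostic plots: per-unit cusum traces and population regressions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .peristimulus import CusumTrace, ReflexEstimate, detect_reflex_auto, error_box

__all__ = ["plot_cusum", "plot_regression"]


def plot_cusum(c: CusumTrace, estimate: ReflexEstimate | None = None, ax=None):
    """Cusum with its error box and, if detected, the reflex onset/end."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    edges = c.data.bin_edges_ms[1:]
    ax.plot(edges, c.values, lw=1.0, label=f"{c.data.method} cusum")
    box = error_box(c)
    ax.axhspan(-box, box, color="0.85", label="error box")
    ax.axvline(0.0, color="k", lw=0.8)
    est = estimate or detect_reflex_auto(c)
    if est.significant and np.isfinite(est.onset_ms):
        ax.axvline(est.onset_ms, color="tab:red", ls="--", label="onset")
        ax.axvline(est.end_ms, color="tab:red", ls=":", label="end")
    ax.set_xlabel("time relative to stimulus (ms)")
    ax.set_ylabel("cusum")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_regression(x, y, result, xlabel="background DR (Hz)", ax=None):
    """Scatter with fitted line and annotated R^2, p and slope."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    x = np.asarray(x, float)
    ax.scatter(x, y, s=12, alpha=0.7)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, result.intercept + result.slope * grid, color="tab:red")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("standardized reflex amplitude")
    ax.set_title(
        f"R²={result.r_squared:.2f}, p={result.p_value:.3g}, "
        f"slope={result.slope:.3f}",
        fontsize=9,
    )
    return ax
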