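"""Static diagnostic figures: ecometric space, anomaly maps, null
distributions, sensitivity curves. All functions take/return matplotlib
axes and never call ``show()``."""

from __future__ import annotations

import numpy as np

from .model import EcometricResults
from .validation import NullDistribution, SensitivityResult

__all__ = [
    "plot_ecometric_space",
    "plot_anomaly_map",
    "plot_null_distribution",
    "plot_sensitivity",
]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_ecometric_space(results: EcometricResults, ax=None, cmap="viridis"):
    """Heatmap of per-bin maximum-likelihood environment estimates over
    trait mean (x) by trait SD (y)."""
    ax = _get_ax(ax)
    sp = results.space
    im = ax.pcolormesh(
        sp.mean_edges, sp.sd_edges, results.peaks.T, cmap=cmap, shading="flat"
    )
    ax.set_xlabel("community trait mean")
    ax.set_ylabel("community trait SD")
    label = "MAT (degC)" if results.model.env == "MAT" else "ln AP (mm)"
    ax.figure.colorbar(im, ax=ax, label=f"ML estimate: {label}")
    return ax


def plot_anomaly_map(results: EcometricResults, ax=None, cmap="RdBu"):
    """Geographic scatter of estimate-minus-observation anomalies
    (positive = overestimate, i.e. modelled wetter/warmer than observed)."""
    ax = _get_ax(ax)
    summ = results.model.summaries
    a = results.anomalies
    lim = float(np.max(np.abs(a))) or 1.0
    sc = ax.scatter(summ["x"], summ["y"], c=a, cmap=cmap, vmin=-lim, vmax=lim, s=6)
    unit = "degC" if results.model.env == "MAT" else "mm"
    ax.figure.colorbar(sc, ax=ax, label=f"anomaly ({unit})")
    ax.set_aspect("equal")
    return ax


def plot_null_distribution(null: NullDistribution, ax=None):
    ax = _get_ax(ax)
    ax.hist(null.null_r2, bins=20, color="0.7", edgecolor="0.4")
    ax.axvline(null.observed_r2, color="crimson", label="observed $R^2$")
    ax.set_xlabel("$R^2$")
    ax.set_title(f"{null.procedure} null (p = {null.exceedance:.3f})")
    ax.legend()
    return ax


def plot_sensitivity(result: SensitivityResult, ax=None):
    ax = _get_ax(ax)
    med = result.median_by_size()
    grouped = result.table.groupby("size")["r2_test"]
    lo, hi = grouped.quantile(0.1), grouped.quantile(0.9)
    ax.fill_between(med.index, lo, hi, alpha=0.3)
    ax.plot(med.index, med.values, marker="o")
    ax.set_xlabel("communities sampled")
    ax.set_ylabel("test-set $R^2$")
    return ax
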