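"""Chart output: calibration plots, SMR funnels, EWMA control charts."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import calibration_table  # noqa: E402
from .monitor import EwmaSeries, FunnelChart  # noqa: E402


def calibration_plot(pred, died, path=None, groups: int = 10, title: str | None = None):
    """Decile calibration plot with a lowess-smoothed curve and rug.

    Observed mortality against predicted mortality; the diagonal marks
    perfect calibration.
    """
    import statsmodels.api as sm

    pred = np.asarray(pred, dtype=float)
    died = np.asarray(died, dtype=float)
    tab = calibration_table(pred, died, groups=groups)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], color="red", lw=1, label="perfect calibration")
    sm_curve = sm.nonparametric.lowess(died, pred, frac=0.3)
    ax.plot(sm_curve[:, 0], sm_curve[:, 1], color="C0", label="smoothed")
    ax.scatter(tab["mean_pred"], tab["observed"], color="black", zorder=3,
               s=20, label="deciles")
    rug = np.random.default_rng(0).choice(pred, size=min(2000, pred.size),
                                          replace=False)
    ax.plot(rug, np.full_like(rug, -0.01), "|", color="gray", ms=4, alpha=0.3)
    ax.set_xlabel("predicted mortality")
    ax.set_ylabel("observed mortality")
    ax.set_xlim(-0.02, 1)
    ax.set_ylim(-0.02, 1)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def funnel_plot(chart: FunnelChart, path=None, title: str | None = None):
    """SMR funnel: per-unit points, center line and 2/3-SD limit curves."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    e_grid = np.linspace(
        max(0.5, chart.units["expected"].min() * 0.8),
        chart.units["expected"].max() * 1.1,
        200,
    )
    styles = {2.0: ("lightgreen", "2 SD"), 3.0: ("darkgreen", "3 SD")}
    for z in chart.z_levels:
        lo, hi = chart.limits(e_grid, z)
        color, label = styles.get(z, ("gray", f"{z:g} SD"))
        ax.plot(e_grid, lo, "--", color=color, lw=1, label=label)
        ax.plot(e_grid, hi, "--", color=color, lw=1)
    ax.axhline(chart.center, color="black", lw=1)
    ax.scatter(chart.units["expected"], chart.units["smr"], color="red", s=18,
               zorder=3)
    ax.set_xlabel("expected deaths")
    ax.set_ylabel("SMR")
    if title:
        ax.set_title(f"{title}  (phi = {chart.phi:.2f})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def ewma_plot(series: EwmaSeries, path=None, title: str | None = None):
    """EWMA mortality chart with center line and 2/3-SD control limits."""
    fig, ax = plt.subplots(figsize=(7, 4))
    t = np.arange(1, series.n + 1)
    ax.plot(t, series.z, color="red", lw=1, label="EWMA mortality")
    ax.plot(t, series.center, color="black", lw=0.8, label="expected")
    styles = {2.0: "lightgreen", 3.0: "darkgreen"}
    for k in series.k_levels:
        lo, hi = series.limits(k)
        ax.plot(t, lo, color=styles.get(k, "gray"), lw=0.8,
                label=f"{k:g} SD limits")
        ax.plot(t, hi, color=styles.get(k, "gray"), lw=0.8)
    ax.set_xlabel("sequential admissions")
    ax.set_ylabel("mortality")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
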