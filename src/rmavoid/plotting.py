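"""Plots mirroring the standard views of a site-avoidance analysis:
Kr histograms per dataset, Y(f) excess-avoidance curves, and stacked
representation bars per stratum."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_kr_histogram", "plot_excess_avoidance", "plot_stacked_fractions"]


def _get_ax(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(7, 4))
    return ax


def plot_kr_histogram(histograms: dict[str, pd.DataFrame], ax=None, cfg=None):
    """Overlay Kr histograms (as from cohorts.kr_histogram), one line per cohort."""
    ax = _get_ax(ax)
    for label, hist in histograms.items():
        body = hist[hist["bin_right"] != float("inf")]
        centers = (body["bin_left"] + body["bin_right"]) / 2
        ax.plot(centers, body["percent"], label=label)
    if cfg is not None:
        ax.axvline(cfg.t_under, color="k", lw=0.8)
        ax.axvline(cfg.t_over, color="k", lw=0.8)
    ax.set_xlabel("Kr")
    ax.set_ylabel("% of site-genome pairs")
    ax.legend()
    return ax


def plot_excess_avoidance(curves: dict[str, pd.DataFrame], ax=None):
    """Y(f) curves: excess fraction of avoided actual pairs over the FPR f."""
    ax = _get_ax(ax)
    for label, curve in curves.items():
        ax.plot(100 * curve["f"], 100 * curve["y"], marker=".", label=label)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("false positive rate f (%)")
    ax.set_ylabel("Y(f) (%)")
    ax.legend()
    return ax


def plot_stacked_fractions(table: pd.DataFrame, stratum_col: str, ax=None):
    """Stacked under/normal/over bars per stratum (fraction-table layout)."""
    ax = _get_ax(ax)
    strata = table[stratum_col].astype(str)
    under = 100 * table["fraction_under"]
    normal = 100 * table["fraction_normal"]
    over = 100 * table["fraction_over"]
    ax.bar(strata, under, label="under", color="tab:blue")
    ax.bar(strata, normal, bottom=under, label="normal", color="white", edgecolor="k")
    ax.bar(strata, over, bottom=under + normal, label="over", color="tab:grey")
    ax.set_ylabel("% of pairs")
    ax.legend()
    return ax
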