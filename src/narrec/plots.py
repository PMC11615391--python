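"""Basic matplotlib figures for the validation analyses."""

from __future__ import annotations

import numpy as np

from .list_learning import CRPCurve, PFRCurve
from .recall_scoring import RecallCurve
from .semantic_network import SemanticNetwork


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_recall_curve(curve: RecallCurve, ax=None, title: str = ""):
    ax = _ax(ax)
    x = np.arange(curve.prob.size) + 1
    ax.fill_between(x, curve.ci_low, curve.ci_high, alpha=0.3)
    ax.plot(x, curve.prob, marker="o")
    if curve.sig_threshold is not None:
        ax.axhline(curve.sig_threshold, ls=":", color="gray", label="97.5th pct null")
        ax.legend()
    ax.set(xlabel="story event", ylabel="probability of recall", title=title)
    return ax


def plot_pfr(pfr: PFRCurve, ax=None, title: str = ""):
    ax = _ax(ax)
    x = np.arange(pfr.pfr.size) + 1
    ax.fill_between(x, pfr.ci_low, pfr.ci_high, alpha=0.3)
    ax.plot(x, pfr.pfr, marker="o")
    ax.set(xlabel="serial position", ylabel="probability of first recall", title=title)
    return ax


def plot_crp(crp: CRPCurve, ax=None, title: str = "", max_lag: int | None = None):
    ax = _ax(ax)
    lags, vals, lo, hi = crp.lags, crp.crp, crp.ci_low, crp.ci_high
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        lags, vals, lo, hi = lags[keep], vals[keep], lo[keep], hi[keep]
    neg, pos = lags < 0, lags > 0
    for side in (neg, pos):
        ax.fill_between(lags[side], lo[side], hi[side], alpha=0.3, color="C0")
        ax.plot(lags[side], vals[side], marker="o", color="C0")
    ax.set(xlabel="lag", ylabel="conditional response probability", title=title)
    return ax


def plot_network(net: SemanticNetwork, ax=None, title: str = ""):
    """Circular layout; edge thickness proportional to cosine weight,
    node size to semantic centrality."""
    ax = _ax(ax)
    E = net.centrality.size
    theta = 2 * np.pi * np.arange(E) / E
    xy = np.c_[np.cos(theta), np.sin(theta)]
    for i, j, w in net.edges:
        ax.plot(*zip(xy[i], xy[j]), color="gray", lw=3 * w, alpha=0.6, zorder=1)
    c = net.centrality - net.centrality.min()
    size = 100 + 900 * (c / c.max() if c.max() > 0 else c)
    ax.scatter(xy[:, 0], xy[:, 1], s=size, zorder=2)
    for e in range(E):
        ax.annotate(str(e + 1), xy[e], ha="center", va="center", zorder=3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    return ax
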