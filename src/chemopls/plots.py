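"""Score and loadings plots mirroring the usual chemometric report figures:
a per-class strip plot of cross-validated scores and a w* bar plot coloured
by direction of elevation."""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def tcv_scores_plot(tcv, labels, component: int = 1, ax=None, title: str = ""):
    """Strip plot of one cross-validated predictive score per class."""
    tcv = np.asarray(tcv)
    if tcv.ndim == 1:
        tcv = tcv[:, None]
    scores = tcv[:, component - 1]
    labels = list(labels)
    classes = sorted(set(labels))
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 3.2))
    for i, cls in enumerate(classes):
        y = [s for s, lab in zip(scores, labels) if lab == cls]
        x = np.linspace(i - 0.15, i + 0.15, len(y))
        ax.plot(x, y, "o", label=cls)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xticks(range(len(classes)), classes, rotation=20, ha="right")
    ax.set_ylabel(f"tcv[{component}]")
    if title:
        ax.set_title(title)
    return ax


def wstar_barplot(w_star, names, retained=None, ax=None, title: str = ""):
    """Bar plot of per-metabolite w* (first predictive component); discarded
    metabolites, if flagged, are drawn hollow."""
    w = np.asarray(w_star)
    if w.ndim == 2:
        w = w[:, 0]
    order = np.argsort(w)
    if ax is None:
        _fig, ax = plt.subplots(figsize=(max(4, 0.18 * len(w)), 3.2))
    kept = np.ones(len(w), dtype=bool) if retained is None else np.asarray(retained)
    for rank, j in enumerate(order):
        colour = "0.3" if w[j] >= 0 else "0.7"
        ax.bar(rank, w[j], color=colour if kept[j] else "none",
               edgecolor=colour, linewidth=0.8)
    ax.set_xticks(range(len(w)), [names[j] for j in order], rotation=90, fontsize=6)
    ax.set_ylabel("w*")
    if title:
        ax.set_title(title)
    return ax
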