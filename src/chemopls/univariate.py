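"""Per-metabolite Mann-Whitney validation with direction calls and fold
changes — the tabular companion to the multivariate model.

The U statistic is computed from midranks and reported as min(U1, U2).  The
p-value path is exact (full null enumeration) for small, tie-free samples
and a tie- and continuity-corrected normal approximation otherwise.  Raw
p-values are what the main table carries; a Benjamini-Hochberg column is
appended as a clearly-labelled extension.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, UsageError
from .tables import MetaboliteTable

_EXACT_LIMIT = 20  # n1 + n2 at or below which the tie-free exact null is used


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (min(U1, U2), p).

    Exact enumeration of the null when n1 + n2 <= 20 and the pooled sample
    is tie-free; otherwise the normal approximation with midrank tie
    correction and a 0.5 continuity correction.  Completely symmetric input
    (identical pooled distributions by construction, sigma = 0) yields p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 1 or n2 < 1:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < n1 + n2

    ranks = scipy.stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    if not has_ties and n1 + n2 <= _EXACT_LIMIT:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return u, float(res.pvalue)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _unique, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0  # all observations identical
    z = max(abs(u1 - mu) - 0.5, 0.0) / np.sqrt(var)
    p = min(2.0 * float(scipy.stats.norm.sf(z)), 1.0)
    return u, p


def tabulate(table: MetaboliteTable, positive_class: str) -> pd.DataFrame:
    """Per-metabolite U, p, direction and fold change for a two-class table.

    Direction (up/down/flat) is the sign of median(positive) -
    median(negative), 'up' meaning elevated in ``positive_class``.  Fold
    change is mean(positive)/mean(negative) on the unscaled (possibly
    media-subtracted) intensities, flagged NaN when the negative-class mean
    is not positive.  Columns: pathway, metabolite, direction, U, p, q_bh
    (Benjamini-Hochberg extension), fold_change, n_pos, n_neg.
    """
    labels = table.sample_meta["class_label"]
    present = sorted({c for c in labels if c is not None and not pd.isna(c)})
    if len(present) != 2:
        raise UsageError(
            f"tabulate needs exactly two classes, found {present}; run one "
            "contrast at a time"
        )
    if positive_class not in present:
        raise UsageError(f"positive_class {positive_class!r} not in {present}")
    negative_class = [c for c in present if c != positive_class][0]
    pos_mask = (labels == positive_class).to_numpy()
    neg_mask = (labels == negative_class).to_numpy()

    rows = []
    for mid in table.metabolite_ids:
        col = table.values[mid].to_numpy(dtype=float)
        a, b = col[pos_mask], col[neg_mask]
        u, p = mann_whitney(a, b)
        med_diff = float(np.median(a) - np.median(b))
        direction = "up" if med_diff > 0 else ("down" if med_diff < 0 else "flat")
        mean_neg = float(b.mean())
        fc = float(a.mean() / mean_neg) if mean_neg > 0 else np.nan
        meta = table.metabolite_meta.loc[mid]
        rows.append(
            {
                "pathway": meta["pathway"],
                "metabolite": meta["display_name"],
                "direction": direction,
                "U": u,
                "p": p,
                "fold_change": fc,
                "fold_change_defined": mean_neg > 0,
                "n_pos": int(len(a)),
                "n_neg": int(len(b)),
            }
        )
    out = pd.DataFrame(rows, index=pd.Index(table.metabolite_ids, name="metabolite_id"))
    out["q_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out[
        ["pathway", "metabolite", "direction", "U", "p", "q_bh",
         "fold_change", "fold_change_defined", "n_pos", "n_neg"]
    ]
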