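"""Metabolite-set over-representation analysis.

An open hypergeometric test of overlap between the selected (model-retained
or significantly changed) metabolites and named pathway sets: for each
pathway, with universe size M (all metabolites observed in the stratum),
pathway size K (members intersected with the universe), selection size n and
overlap k, p = P(X >= k) under the hypergeometric null.  One-sided
over-representation only; Benjamini-Hochberg q across the tested pathways.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError
from .tables import PathwayDB


def enrich(selected, universe, db: PathwayDB) -> pd.DataFrame:
    """Over-representation of ``selected`` within ``universe`` per pathway.

    Returns a DataFrame sorted by p ascending (ties by pathway name) with
    columns pathway, set_size, universe_size, selected_size, overlap, p,
    q_bh, overlap_members.  Pathways with no member in the universe are not
    tested.
    """
    selected = set(selected)
    universe = set(universe)
    if not universe:
        raise ConsistencyError("universe must be non-empty")
    extra = selected - universe
    if extra:
        raise ConsistencyError(
            f"selected metabolites outside the universe: {sorted(extra)[:5]}"
        )
    m = len(universe)
    n = len(selected)
    rows = []
    for name, members in db.sets.items():
        in_universe = members & universe
        big_k = len(in_universe)
        if big_k == 0:
            continue
        overlap = in_universe & selected
        k = len(overlap)
        # P(X >= k); k = 0 gives exactly 1
        p = float(scipy.stats.hypergeom.sf(k - 1, m, big_k, n))
        rows.append(
            {
                "pathway": name,
                "set_size": big_k,
                "universe_size": m,
                "selected_size": n,
                "overlap": k,
                "p": min(p, 1.0),
                "overlap_members": ";".join(sorted(overlap)),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["pathway", "set_size", "universe_size", "selected_size",
                     "overlap", "p", "q_bh", "overlap_members"]
        )
    out = pd.DataFrame(rows)
    out["q_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
    return out[["pathway", "set_size", "universe_size", "selected_size",
                "overlap", "p", "q_bh", "overlap_members"]]


def build_fixture_db(metabolite_meta: pd.DataFrame, source: str = "stratum metadata"
                     ) -> PathwayDB:
    """Group display names by their pathway label into a PathwayDB.

    Accepts any frame with ``display_name`` and ``pathway`` columns (a
    metabolite-metadata frame or a univariate results table); metabolites
    with a null pathway are assigned to no set.
    """
    sets: dict[str, set[str]] = {}
    for _, row in metabolite_meta.iterrows():
        pw = row["pathway"]
        if pw is None or (isinstance(pw, float) and np.isnan(pw)):
            continue
        name = row.get("display_name", row.get("metabolite"))
        sets.setdefault(str(pw), set()).add(str(name))
    return PathwayDB(sets=sets, source=source)
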