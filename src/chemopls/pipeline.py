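"""End-to-end driver: strata -> preprocessing -> OPLS-DA -> |w*| selection
-> univariate tables -> over-representation, with a machine-readable run
summary.

Each (platform, fraction) stratum is modelled independently; a failure in
one stratum is recorded and does not abort the others.  All randomness flows
from the single run seed, and outputs are written deterministically (stable
ordering, fixed float formatting), so identical configurations give
byte-identical artifacts.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import simulate
from .enrichment import build_fixture_db, enrich
from .errors import ChemoplsError, ConfigError
from .opls import choose_orthogonal, cross_validate, select_variables
from .preprocess import normalize_internal_standard, subtract_media
from .tables import MetaboliteTable, read_table, split_strata, write_table
from .univariate import tabulate

_TSV_KW = dict(sep="\t", float_format="%.17g", lineterminator="\n", encoding="utf-8")


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration: either synthetic generation or TSV inputs."""

    synthetic: Optional[simulate.SyntheticConfig] = None
    input_paths: list[str] = dataclasses.field(default_factory=list)
    positive_class: str = simulate.CLASS_POSITIVE
    n_pred: int = 1
    n_ortho: Union[int, str] = "auto"  # int or "auto"
    max_ortho: int = 3
    n_folds: int = 7
    tau: float = 0.05
    scaling: str = "unit_variance"
    log_transform: bool = False
    clip_at_zero: bool = False
    seed: int = 0
    outdir: Optional[str] = None

    def validate(self) -> None:
        if self.tau < 0:
            raise ConfigError("tau must be >= 0")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.synthetic is None and not self.input_paths:
            raise ConfigError("provide either a synthetic config or input paths")


def _load_tables(config: RunConfig) -> list[MetaboliteTable]:
    if config.synthetic is not None:
        cfg = dataclasses.replace(config.synthetic, seed=config.seed)
        sup, pel, _truth = simulate.generate(cfg)
        return [sup, pel]
    return [read_table(p) for p in config.input_paths]


def preprocess_stratum(table: MetaboliteTable, clip_at_zero: bool = False
                       ) -> MetaboliteTable:
    """IS normalization (when an IS channel is flagged), then media
    subtraction (supernatant strata with control wells); returns the
    cell-samples-only table on the intensity scale."""
    if table.metabolite_meta["is_internal_standard"].astype(bool).any():
        table = normalize_internal_standard(table)
    fractions = set(table.sample_meta["fraction"])
    has_controls = table.sample_meta["is_media_control"].astype(bool).any()
    if fractions == {"supernatant"} and has_controls:
        table = subtract_media(table, clip_at_zero=clip_at_zero)
    elif has_controls:
        keep = ~table.sample_meta["is_media_control"].astype(bool)
        table = table.subset_samples(table.sample_meta.index[keep])
    return table


def _analyse_stratum(table: MetaboliteTable, config: RunConfig) -> dict:
    prepped = preprocess_stratum(table, clip_at_zero=config.clip_at_zero)
    X = prepped.matrix()
    labels = list(prepped.sample_meta["class_label"])
    if config.n_ortho == "auto":
        n_ortho = choose_orthogonal(
            X, labels, n_pred=config.n_pred, max_ortho=config.max_ortho,
            n_folds=config.n_folds, seed=config.seed, mode=config.scaling,
            log_transform=config.log_transform,
        )
    else:
        n_ortho = int(config.n_ortho)
    selection = select_variables(
        X, labels, metabolite_ids=prepped.metabolite_ids, tau=config.tau,
        n_pred=config.n_pred, n_ortho=n_ortho, n_folds=config.n_folds,
        seed=config.seed, mode=config.scaling, log_transform=config.log_transform,
    )
    uni = tabulate(prepped, config.positive_class)
    db = build_fixture_db(prepped.metabolite_meta)
    universe = list(prepped.metabolite_meta["display_name"])
    selected_names = list(
        prepped.metabolite_meta.loc[selection.retained, "display_name"]
    )
    enr = enrich(selected_names, universe, db) if len(db.sets) else None
    return {
        "table": prepped,
        "n_ortho": n_ortho,
        "selection": selection,
        "univariate": uni,
        "enrichment": enr,
    }


def _score_frame(selection, table: MetaboliteTable) -> pd.DataFrame:
    cv = selection.final_cv
    cols = {f"tcv[{a + 1}]": cv.tcv[:, a] for a in range(cv.tcv.shape[1])}
    df = pd.DataFrame(cols, index=pd.Index(table.sample_ids, name="sample_id"))
    df["class_label"] = list(table.sample_meta["class_label"])
    df["fold"] = cv.folds
    return df


def _wstar_frame(selection, table: MetaboliteTable) -> pd.DataFrame:
    ids = table.metabolite_ids
    w = selection.initial_model.w_star
    cols = {f"w_star[{a + 1}]": w[:, a] for a in range(w.shape[1])}
    df = pd.DataFrame(cols, index=pd.Index(ids, name="metabolite_id"))
    df["abs_w_star"] = selection.w_abs
    df["retained"] = [mid in set(selection.retained) for mid in ids]
    df["display_name"] = list(table.metabolite_meta["display_name"])
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Run every stratum end to end; optionally write artifacts to
    ``config.outdir``; return the run report.

    The report maps each stratum key ('platform/fraction') to its retained
    count, Q2 and CV-ANOVA record, mirroring the per-stratum "p = ..., (n
    metabolites)" reporting style, plus an audit block of every defaulted
    parameter.
    """
    config.validate()
    tables = _load_tables(config)
    strata: list[tuple[str, str, MetaboliteTable]] = []
    for t in tables:
        strata.extend(split_strata(t))

    summary: dict = {"strata": {}, "parameters": {
        "n_pred": config.n_pred,
        "n_ortho": config.n_ortho if config.n_ortho == "auto" else int(config.n_ortho),
        "max_ortho": config.max_ortho,
        "n_folds": config.n_folds,
        "tau": config.tau,
        "scaling": config.scaling,
        "log_transform": config.log_transform,
        "clip_at_zero": config.clip_at_zero,
        "positive_class": config.positive_class,
        "seed": config.seed,
    }}
    results: dict = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    for platform, fraction, sub in strata:
        key = f"{platform}/{fraction}"
        try:
            res = _analyse_stratum(sub, config)
        except ChemoplsError as exc:
            summary["strata"][key] = {"error": f"{type(exc).__name__}: {exc}"}
            continue
        sel = res["selection"]
        cv = sel.final_cv
        summary["strata"][key] = {
            "n_samples": res["table"].n_samples,
            "n_metabolites": res["table"].n_metabolites,
            "n_retained": len(sel.retained),
            "n_ortho": res["n_ortho"],
            "initial_q2": round(sel.initial_cv.q2, 10),
            "q2": round(cv.q2, 10),
            "r2y": round(sel.final_model.r2y, 10),
            "f": round(cv.f, 10) if np.isfinite(cv.f) else "inf",
            "df1": cv.df1,
            "df2": cv.df2,
            "p": cv.p,
        }
        results[key] = res
        if outdir is not None:
            stem = key.replace("/", "_")
            write_table(res["table"], outdir / f"{stem}.preprocessed.tsv")
            _score_frame(sel, res["table"]).to_csv(
                outdir / f"{stem}.tcv.tsv", **_TSV_KW)
            _wstar_frame(sel, res["table"]).to_csv(
                outdir / f"{stem}.wstar.tsv", **_TSV_KW)
            res["univariate"].to_csv(outdir / f"{stem}.univariate.tsv", **_TSV_KW)
            if res["enrichment"] is not None:
                res["enrichment"].to_csv(
                    outdir / f"{stem}.enrichment.tsv", index=False, **_TSV_KW)

    if outdir is not None:
        with open(outdir / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return {"summary": summary, "results": results}


# ---------------------------------------------------------------------------
# treatment scenario
# ---------------------------------------------------------------------------

def treatment_scenario(config: RunConfig) -> dict:
    """Six-group arginine-deprivation scenario on the supernatant stratum.

    Three cell populations x (untreated, treated) are modelled as six
    classes in one OPLS-DA; the report carries each group's mean
    cross-validated score per predictive component and the standardized
    treated-vs-untreated gap per population, the quantity that singles out
    the responder.
    """
    config.validate()
    if config.synthetic is None or config.synthetic.treatment_design is None:
        raise ConfigError("treatment_scenario requires a synthetic config with "
                          "a treatment_design")
    cfg = dataclasses.replace(config.synthetic, seed=config.seed)
    sup, _pel, truth = simulate.generate(cfg)
    prepped = preprocess_stratum(sup, clip_at_zero=config.clip_at_zero)

    groups = prepped.sample_meta["class_label"]
    cond = prepped.sample_meta["treatment"].map(
        lambda v: "untreated" if v is None or pd.isna(v) else "treated"
    )
    labels = [f"{g}|{c}" for g, c in zip(groups, cond)]
    n_classes = len(set(labels))
    # up to K-1 predictive components; the treated-vs-untreated contrast of a
    # single population typically loads on a later component than the
    # population baselines, so the full set is fitted unless overridden
    n_pred = (n_classes - 1 if config.n_pred <= 1
              else min(config.n_pred, n_classes - 1))

    X = prepped.matrix()
    if config.n_ortho == "auto":
        n_ortho = choose_orthogonal(X, labels, n_pred=n_pred,
                                    max_ortho=config.max_ortho,
                                    n_folds=config.n_folds, seed=config.seed,
                                    mode=config.scaling,
                                    log_transform=config.log_transform)
    else:
        n_ortho = int(config.n_ortho)
    cv = cross_validate(X, labels, n_pred=n_pred, n_ortho=n_ortho,
                        n_folds=config.n_folds, seed=config.seed,
                        mode=config.scaling, log_transform=config.log_transform)

    pop_names = [name for name, _r in cfg.treatment_design.groups]
    responder = [name for name, r in cfg.treatment_design.groups if r]
    group_means: dict = {}
    gaps: dict = {}
    for name in pop_names:
        t_mask = np.array([g == name and c == "treated"
                           for g, c in zip(groups, cond)])
        u_mask = np.array([g == name and c == "untreated"
                           for g, c in zip(groups, cond)])
        mt, mu_ = cv.tcv[t_mask], cv.tcv[u_mask]
        group_means[f"{name}|treated"] = mt.mean(axis=0).tolist()
        group_means[f"{name}|untreated"] = mu_.mean(axis=0).tolist()
        se = np.sqrt(mt.var(axis=0, ddof=1) / mt.shape[0]
                     + mu_.var(axis=0, ddof=1) / mu_.shape[0])
        se = np.where(se == 0, np.nan, se)
        gaps[name] = (np.abs(mt.mean(axis=0) - mu_.mean(axis=0)) / se).tolist()

    # does the responder beat every non-responder on some component?
    responder_wins = False
    best_component = None
    if responder:
        g_r = np.asarray(gaps[responder[0]])
        others = np.vstack([gaps[n] for n in pop_names if n not in responder])
        wins = g_r > others.max(axis=0)
        if wins.any():
            responder_wins = True
            best_component = int(np.argmax(np.where(wins, g_r, -np.inf))) + 1

    report = {
        "n_groups": n_classes,
        "n_pred": n_pred,
        "n_ortho": n_ortho,
        "q2": round(cv.q2, 10),
        "p": cv.p,
        "group_mean_tcv": group_means,
        "standardized_gap": gaps,
        "responder": responder[0] if responder else None,
        "responder_wins": bool(responder_wins),
        "best_component": best_component,
        "treatment_effect_metabolites": [m for m, _d in truth.treatment_effect],
    }
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "treatment_scenario.json", "w", encoding="utf-8",
                  newline="\n") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        scores = pd.DataFrame(
            {f"tcv[{a + 1}]": cv.tcv[:, a] for a in range(cv.tcv.shape[1])},
            index=pd.Index(prepped.sample_ids, name="sample_id"),
        )
        scores["group"] = labels
        scores.to_csv(outdir / "treatment_scenario.tcv.tsv", **_TSV_KW)
    return report
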