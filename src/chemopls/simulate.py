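"""Synthetic cell-culture footprint/extract metabolomics generator.

Emulates the study design the analysis assumes: a small panel of cell lines
(two classes, e.g. ASS1-positive vs ASS1-negative) grown in replicate wells,
measured in two fractions (supernatant = footprint, pellet = extract) on one
platform, with media-only control wells, an internal-standard channel, a
pathway-coherent planted class effect, and a shared class-independent latent
factor producing exactly the correlated orthogonal variation OPLS-DA is
designed to strip.

Generative model (per fraction), on the log scale:

    log x_ij = mu_j + c_i * delta_j + gamma * g_i * b_j + e_ij

with c_i = +1/2 for the positive class and -1/2 for the negative class,
g_i ~ N(0,1) independent of class, b a fixed unit-norm loading vector,
and e_ij mean-zero Gaussian noise with SD ``sigma_log`` and equicorrelation
``rho`` inside declared pathway blocks.  Intensities are exp(log x) scaled
by a per-sample multiplicative load s_i (pipetting/biomass variation).
Supernatant samples additionally receive an additive media background
m_j*(1+eps) on the intensity scale, and media-only control wells (background
only) are appended.  One internal-standard channel IS0*s_i*(1+eta) is added
per table.

All draws flow from one seed through fixed named substreams, so e.g.
changing the number of media controls never perturbs cell-sample values.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tables import FRACTIONS, MetaboliteTable

# display names for the planted, pathway-coherent block: the arginine
# biosynthetic pathway members an ASS1-proficient line over-secretes
ARGININE_PATHWAY = "Urea Cycle. Arginine and Proline Metabolism"
_ARGININE_METABOLITES = [
    "Arginine",
    "Ornithine",
    "Citrulline",
    "Proline",
    "Urea",
    "Argininosuccinate",
    "Glutamic Acid",
    "Aspartic Acid",
    "Glutamine",
    "Creatinine",
]

CLASS_NEGATIVE = "ASS1_negative"
CLASS_POSITIVE = "ASS1_positive"
IS_NAME = "Norvaline"

# substream indices off the master SeedSequence; order is part of the contract
_STREAMS = {
    "structure": 0,
    "noise_supernatant": 1,
    "noise_pellet": 2,
    "media_cells": 3,
    "media_controls": 4,
    "internal_standard": 5,
    "treatment": 6,
}


@dataclasses.dataclass
class TreatmentDesign:
    """Three cell populations x (untreated, treated), one responder.

    ``groups`` maps group name -> responds flag; exactly the responder's
    treated samples are shifted by ``effect`` (log scale) per metabolite.
    """

    groups: list[tuple[str, bool]] = dataclasses.field(
        default_factory=lambda: [
            ("astrocyte", False),
            (CLASS_NEGATIVE, True),
            (CLASS_POSITIVE, False),
        ]
    )
    effect: dict[int, float] = dataclasses.field(
        default_factory=lambda: {j: 2.0 for j in range(10)}
    )
    n_reps: int = 12  # replicate wells per group x condition
    group_baseline_sd: float = 0.5  # per-group metabolic baseline spread (log)


@dataclasses.dataclass
class SyntheticConfig:
    """Generator configuration; defaults mirror the emulated study design:
    3 cell lines per class x 6 replicate wells, 6 media-control wells, and a
    GC-sized panel of metabolites with a 10-metabolite planted arginine-
    pathway block."""

    n_lines_per_class: int = 3
    n_reps_per_line: int = 6
    n_media_controls: int = 6
    n_metabolites: int = 400
    # metabolite index -> class effect delta (log scale, units of sigma_log)
    planted_effects: dict[int, float] = dataclasses.field(
        default_factory=lambda: {j: 1.5 for j in range(10)}
    )
    # (pathway name, member indices, equicorrelation rho)
    pathway_blocks: list[tuple[str, Sequence[int], float]] = dataclasses.field(
        default_factory=lambda: [(ARGININE_PATHWAY, tuple(range(10)), 0.3)]
    )
    orthogonal_strength: float = 1.0
    # 'sample': g_i drawn per well; 'line': g shared by all replicate wells
    # of a cell line (line-to-line metabolic individuality, the dominant
    # class-unrelated structure in replicated cell-line panels)
    orthogonal_level: str = "sample"
    sigma_log: float = 1.0
    media_background: Optional[np.ndarray] = None  # per-metabolite means; drawn if None
    media_cv: float = 0.05
    is_cv: float = 0.05
    is_level: float = 1000.0
    sample_load_cv: float = 0.1
    mu_log_range: tuple[float, float] = (np.log(50.0), np.log(500.0))
    platform: str = "1D-GC-TOFMS"
    treatment_design: Optional[TreatmentDesign] = None
    seed: int = 0

    def validate(self) -> None:
        m = self.n_metabolites
        if m < 1:
            raise ConfigError("n_metabolites must be >= 1")
        if self.planted_effects and max(self.planted_effects) >= m:
            raise ConfigError("planted metabolite index exceeds n_metabolites")
        for name, members, rho in self.pathway_blocks:
            if not (0.0 <= rho < 1.0):
                raise ConfigError(f"block {name!r}: rho must be in [0, 1)")
            if members and max(members) >= m:
                raise ConfigError(f"block {name!r}: member index exceeds n_metabolites")
        for label, cv in (("media_cv", self.media_cv), ("is_cv", self.is_cv),
                          ("sample_load_cv", self.sample_load_cv)):
            if cv < 0:
                raise ConfigError(f"{label} must be >= 0")
        if self.sigma_log < 0 or self.orthogonal_strength < 0:
            raise ConfigError("sigma_log and orthogonal_strength must be >= 0")
        if min(self.n_lines_per_class, self.n_reps_per_line) < 1:
            raise ConfigError("need >= 1 line per class and >= 1 replicate per line")
        if self.n_media_controls < 0:
            raise ConfigError("n_media_controls must be >= 0")
        if self.orthogonal_level not in ("sample", "line"):
            raise ConfigError("orthogonal_level must be 'sample' or 'line'")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of one generate() call, for recovery tests."""

    planted: list[tuple[str, float]]  # (metabolite id, delta on log scale)
    latent_g: dict[str, float]  # class-independent factor per sample
    loads: dict[str, float]  # multiplicative per-sample load s_i
    treatment_effect: list[tuple[str, float]] = dataclasses.field(default_factory=list)


def planted_truth(truth: SyntheticTruth) -> list[tuple[str, int]]:
    """Project the truth onto (metabolite id, sign of planted effect)."""
    return [(mid, int(np.sign(d))) for mid, d in truth.planted]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


def _metabolite_ids(cfg: SyntheticConfig) -> list[str]:
    planted = sorted(cfg.planted_effects)
    named: dict[int, str] = {}
    for k, j in enumerate(planted):
        if k < len(_ARGININE_METABOLITES):
            named[j] = _ARGININE_METABOLITES[k]
    width = len(str(max(cfg.n_metabolites, 1)))
    return [named.get(j, f"M{j + 1:0{width}d}") for j in range(cfg.n_metabolites)]


def _pathway_of(cfg: SyntheticConfig) -> list[Optional[str]]:
    out: list[Optional[str]] = [None] * cfg.n_metabolites
    for name, members, _rho in cfg.pathway_blocks:
        for j in members:
            out[j] = name
    return out


def _block_noise(rng, n, cfg: SyntheticConfig) -> np.ndarray:
    """Residual noise, equicorrelated within pathway blocks, SD sigma_log."""
    m = cfg.n_metabolites
    e = rng.standard_normal((n, m))
    for _name, members, rho in cfg.pathway_blocks:
        if rho > 0 and len(members) > 1:
            shared = rng.standard_normal((n, 1))
            idx = np.asarray(list(members))
            e[:, idx] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * e[:, idx]
    return cfg.sigma_log * e


def _loads(rng, n, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.standard_normal(n) * sigma - 0.5 * sigma**2)


def _assemble(values, sample_ids, meta_rows, met_ids, pathways) -> MetaboliteTable:
    cols = met_ids + [IS_NAME]
    vdf = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                       columns=pd.Index(cols, name="metabolite_id"))
    smeta = pd.DataFrame(meta_rows, index=vdf.index)
    mmeta = pd.DataFrame(
        {
            "display_name": cols,
            "pathway": pathways + [None],
            "is_internal_standard": [False] * len(met_ids) + [True],
        },
        index=pd.Index(cols, name="metabolite_id"),
    )
    return MetaboliteTable(vdf, smeta, mmeta)


def generate(cfg: SyntheticConfig):
    """Generate (supernatant, pellet, truth); bitwise reproducible per seed."""
    cfg.validate()
    if cfg.treatment_design is not None:
        return _generate_treatment(cfg)

    m = cfg.n_metabolites
    met_ids = _metabolite_ids(cfg)
    pathways = _pathway_of(cfg)

    struct = _rng(cfg.seed, "structure")
    mu = struct.uniform(*cfg.mu_log_range, size=m)
    b = struct.standard_normal(m)
    b /= np.linalg.norm(b)
    media_mu = cfg.media_background
    if media_mu is None:
        media_mu = struct.uniform(0.5, 1.5, size=m) * np.exp(mu)
    media_mu = np.asarray(media_mu, dtype=float)
    if media_mu.shape != (m,):
        raise ConfigError("media_background must have one mean per metabolite")

    delta = np.zeros(m)
    for j, d in cfg.planted_effects.items():
        delta[j] = d

    lines = [(CLASS_NEGATIVE, f"neg{i + 1}") for i in range(cfg.n_lines_per_class)]
    lines += [(CLASS_POSITIVE, f"pos{i + 1}") for i in range(cfg.n_lines_per_class)]
    cells = [
        (cls, line, r + 1)
        for cls, line in lines
        for r in range(cfg.n_reps_per_line)
    ]
    n_cells = len(cells)
    c = np.array([0.5 if cls == CLASS_POSITIVE else -0.5 for cls, _l, _r in cells])

    is_rng = _rng(cfg.seed, "internal_standard")
    media_cells_rng = _rng(cfg.seed, "media_cells")
    media_ctrl_rng = _rng(cfg.seed, "media_controls")

    truth = SyntheticTruth(
        planted=[(met_ids[j], cfg.planted_effects[j]) for j in sorted(cfg.planted_effects)],
        latent_g={},
        loads={},
    )

    tables = {}
    for fraction in FRACTIONS:
        rng = _rng(cfg.seed, f"noise_{fraction}")
        g = rng.standard_normal(n_cells)
        if cfg.orthogonal_level == "line":
            g_line = {line: rng.standard_normal() for _cls, line in lines}
            g = np.array([g_line[line] for _cls, line, _r in cells])
        e = _block_noise(rng, n_cells, cfg)
        s = _loads(rng, n_cells, cfg.sample_load_cv)
        logx = (
            mu[None, :]
            + c[:, None] * delta[None, :]
            + cfg.orthogonal_strength * np.outer(g, b)
            + e
        )
        x = np.exp(logx) * s[:, None]

        suffix = "sup" if fraction == "supernatant" else "pel"
        sample_ids = [f"{line}_r{r}_{suffix}" for _cls, line, r in cells]
        meta_rows = {
            "class_label": [cls for cls, _l, _r in cells],
            "fraction": fraction,
            "platform": cfg.platform,
            "cell_line": [line for _c, line, _r in cells],
            "is_media_control": False,
            "treatment": None,
        }
        if fraction == "supernatant":
            eps = media_cells_rng.standard_normal((n_cells, m)) * cfg.media_cv
            x = x + media_mu[None, :] * (1.0 + eps)

        is_col = cfg.is_level * s * (1.0 + is_rng.standard_normal(n_cells) * cfg.is_cv)
        values = np.column_stack([x, is_col])
        meta = pd.DataFrame(meta_rows, index=sample_ids)

        if fraction == "supernatant" and cfg.n_media_controls > 0:
            k = cfg.n_media_controls
            eps = media_ctrl_rng.standard_normal((k, m)) * cfg.media_cv
            ctrl = media_mu[None, :] * (1.0 + eps)
            ctrl_is = cfg.is_level * (
                1.0 + media_ctrl_rng.standard_normal(k) * cfg.is_cv
            )
            ctrl_ids = [f"media_ctrl_{i + 1}_{suffix}" for i in range(k)]
            values = np.vstack([values, np.column_stack([ctrl, ctrl_is])])
            ctrl_meta = pd.DataFrame(
                {
                    "class_label": None,
                    "fraction": fraction,
                    "platform": cfg.platform,
                    "cell_line": "media",
                    "is_media_control": True,
                    "treatment": None,
                },
                index=ctrl_ids,
            )
            meta = pd.concat([meta, ctrl_meta])
            sample_ids = sample_ids + ctrl_ids

        for sid, gi, si in zip(sample_ids[:n_cells], g, s):
            truth.latent_g[sid] = float(gi)
            truth.loads[sid] = float(si)

        tables[fraction] = _assemble(
            values, sample_ids, meta.to_dict(orient="list"), met_ids, pathways
        )

    return tables["supernatant"], tables["pellet"], truth


def _generate_treatment(cfg: SyntheticConfig):
    """Treated/untreated x 3 populations design (arginine-deprivation assay).

    Class structure comes from per-group metabolic baselines; the responder
    group's treated wells are additionally shifted by the treatment effect.
    """
    td = cfg.treatment_design
    m = cfg.n_metabolites
    met_ids = _metabolite_ids(cfg)
    pathways = _pathway_of(cfg)

    struct = _rng(cfg.seed, "structure")
    mu = struct.uniform(*cfg.mu_log_range, size=m)
    b = struct.standard_normal(m)
    b /= np.linalg.norm(b)
    media_mu = cfg.media_background
    if media_mu is None:
        media_mu = struct.uniform(0.5, 1.5, size=m) * np.exp(mu)
    media_mu = np.asarray(media_mu, dtype=float)

    trt = _rng(cfg.seed, "treatment")
    baselines = {
        name: trt.standard_normal(m) * td.group_baseline_sd
        for name, _responds in td.groups
    }
    effect = np.zeros(m)
    for j, d in td.effect.items():
        if j >= m:
            raise ConfigError("treatment effect index exceeds n_metabolites")
        effect[j] = d

    wells = [
        (name, responds, cond, r + 1)
        for name, responds in td.groups
        for cond in ("untreated", "treated")
        for r in range(td.n_reps)
    ]
    n_cells = len(wells)

    is_rng = _rng(cfg.seed, "internal_standard")
    media_cells_rng = _rng(cfg.seed, "media_cells")
    media_ctrl_rng = _rng(cfg.seed, "media_controls")

    truth = SyntheticTruth(
        planted=[],
        latent_g={},
        loads={},
        treatment_effect=[(met_ids[j], d) for j, d in sorted(td.effect.items())],
    )

    tables = {}
    for fraction in FRACTIONS:
        rng = _rng(cfg.seed, f"noise_{fraction}")
        g = rng.standard_normal(n_cells)
        e = _block_noise(rng, n_cells, cfg)
        s = _loads(rng, n_cells, cfg.sample_load_cv)
        logx = mu[None, :] + cfg.orthogonal_strength * np.outer(g, b) + e
        for i, (name, responds, cond, _r) in enumerate(wells):
            logx[i] += baselines[name]
            if responds and cond == "treated":
                logx[i] += effect
        x = np.exp(logx) * s[:, None]

        suffix = "sup" if fraction == "supernatant" else "pel"
        sample_ids = [f"{name}_{cond}_r{r}_{suffix}" for name, _re, cond, r in wells]
        if fraction == "supernatant":
            eps = media_cells_rng.standard_normal((n_cells, m)) * cfg.media_cv
            x = x + media_mu[None, :] * (1.0 + eps)
        is_col = cfg.is_level * s * (1.0 + is_rng.standard_normal(n_cells) * cfg.is_cv)
        values = np.column_stack([x, is_col])
        meta = pd.DataFrame(
            {
                "class_label": [name for name, _re, _c, _r in wells],
                "fraction": fraction,
                "platform": cfg.platform,
                "cell_line": [name for name, _re, _c, _r in wells],
                "is_media_control": False,
                "treatment": [
                    "ADI-PEG20" if cond == "treated" else None
                    for _n, _re, cond, _r in wells
                ],
            },
            index=sample_ids,
        )
        if fraction == "supernatant" and cfg.n_media_controls > 0:
            k = cfg.n_media_controls
            eps = media_ctrl_rng.standard_normal((k, m)) * cfg.media_cv
            ctrl = media_mu[None, :] * (1.0 + eps)
            ctrl_is = cfg.is_level * (
                1.0 + media_ctrl_rng.standard_normal(k) * cfg.is_cv
            )
            ctrl_ids = [f"media_ctrl_{i + 1}_{suffix}" for i in range(k)]
            values = np.vstack([values, np.column_stack([ctrl, ctrl_is])])
            ctrl_meta = pd.DataFrame(
                {
                    "class_label": None,
                    "fraction": fraction,
                    "platform": cfg.platform,
                    "cell_line": "media",
                    "is_media_control": True,
                    "treatment": None,
                },
                index=ctrl_ids,
            )
            meta = pd.concat([meta, ctrl_meta])
            sample_ids = sample_ids + ctrl_ids

        for sid, gi, si in zip(sample_ids[:n_cells], g, s):
            truth.latent_g[sid] = float(gi)
            truth.loads[sid] = float(si)

        tables[fraction] = _assemble(
            values, sample_ids, meta.to_dict(orient="list"), met_ids, pathways
        )

    return tables["supernatant"], tables["pellet"], truth
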