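"""Preprocessing: internal-standard normalization, media-background
subtraction, and centring/scaling.

Contract order, enforced by the pipeline driver: IS normalization first
(ratio to the spiked reference compound, per sample), then media subtraction
(supernatant strata only, on the intensity scale), then centring/scaling of
the matrix handed to the projection models.  Default scaling is unit
variance; pareto (divide by sqrt(SD)) and none are selectable.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import DataError, UsageError
from .tables import MetaboliteTable

SCALING_MODES = ("unit_variance", "pareto", "none")


@dataclasses.dataclass
class ScalingParams:
    """Column transform learned on training data: optional log, centre by
    ``center``, divide by ``divisor`` (> 0)."""

    center: np.ndarray
    divisor: np.ndarray
    mode: str
    log_transform: bool
    metabolite_ids: list[str] | None = None
    degenerate: list[int] = dataclasses.field(default_factory=list)

    def apply(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.log_transform:
            if np.any(X <= 0):
                raise DataError("log transform requires strictly positive values")
            X = np.log(X)
        return (X - self.center) / self.divisor

    def inverse(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float) * self.divisor + self.center
        if self.log_transform:
            X = np.exp(X)
        return X

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "divisor": self.divisor.tolist(),
            "mode": self.mode,
            "log_transform": self.log_transform,
            "metabolite_ids": self.metabolite_ids,
            "degenerate": list(self.degenerate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            center=np.asarray(d["center"], dtype=float),
            divisor=np.asarray(d["divisor"], dtype=float),
            mode=d["mode"],
            log_transform=bool(d["log_transform"]),
            metabolite_ids=d.get("metabolite_ids"),
            degenerate=list(d.get("degenerate", [])),
        )


def normalize_internal_standard(table: MetaboliteTable) -> MetaboliteTable:
    """Divide every intensity by the sample's internal-standard intensity.

    Requires exactly one metabolite flagged ``is_internal_standard`` with
    strictly positive values; the IS column is removed from the output.
    """
    flags = table.metabolite_meta["is_internal_standard"].astype(bool)
    is_ids = list(table.metabolite_meta.index[flags])
    if len(is_ids) != 1:
        raise DataError(
            f"expected exactly one internal-standard metabolite, found {len(is_ids)}"
        )
    is_id = is_ids[0]
    is_values = table.values[is_id]
    bad = is_values[is_values <= 0]
    if len(bad):
        raise DataError(
            f"non-positive internal-standard value for sample(s) {list(bad.index)}"
        )
    keep = [m for m in table.metabolite_ids if m != is_id]
    values = table.values[keep].div(is_values, axis=0)
    return MetaboliteTable(values, table.sample_meta.copy(),
                           table.metabolite_meta.loc[keep].copy())


def subtract_media(table: MetaboliteTable, clip_at_zero: bool = False) -> MetaboliteTable:
    """Subtract the mean media-control intensity per metabolite, then drop
    the control wells.

    Applies to supernatant (footprint) strata only.  Values may go negative
    — net consumption from the medium — and are kept signed unless
    ``clip_at_zero`` is set; rank-based downstream tests use that sign
    information.
    """
    fractions = set(table.sample_meta["fraction"])
    if fractions != {"supernatant"}:
        raise UsageError(
            f"media subtraction applies to supernatant strata only, got {sorted(fractions)}"
        )
    ctrl_mask = table.sample_meta["is_media_control"].astype(bool)
    if not ctrl_mask.any():
        raise DataError("no media-control samples present; cannot subtract background")
    background = table.values.loc[ctrl_mask.values].mean(axis=0)
    cells = table.values.loc[~ctrl_mask.values].sub(background, axis=1)
    if clip_at_zero:
        cells = cells.clip(lower=0.0)
    return MetaboliteTable(
        cells,
        table.sample_meta.loc[~ctrl_mask.values].copy(),
        table.metabolite_meta.copy(),
    )


def fit_scaling(X, mode: str = "unit_variance", log_transform: bool = False,
                metabolite_ids=None) -> ScalingParams:
    """Learn centre/divisor on a (training) matrix."""
    if mode not in SCALING_MODES:
        raise UsageError(f"unknown scaling mode {mode!r}; choose from {SCALING_MODES}")
    X = np.asarray(X, dtype=float)
    if log_transform:
        if np.any(X <= 0):
            raise DataError("log transform requires strictly positive values")
        X = np.log(X)
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    degenerate = list(np.flatnonzero(sd == 0.0))
    if mode == "none":
        divisor = np.ones(X.shape[1])
    else:
        safe = np.where(sd == 0.0, 1.0, sd)
        divisor = safe if mode == "unit_variance" else np.sqrt(safe)
        if degenerate and mode != "none":
            warnings.warn(
                f"{len(degenerate)} zero-variance column(s) left unscaled",
                stacklevel=2,
            )
    return ScalingParams(
        center=center,
        divisor=np.asarray(divisor, dtype=float),
        mode=mode,
        log_transform=log_transform,
        metabolite_ids=list(metabolite_ids) if metabolite_ids is not None else None,
        degenerate=degenerate,
    )


def transform_scale(table, mode: str = "unit_variance", log_transform: bool = False):
    """Centre/scale a table (or matrix); returns (X, ScalingParams).

    The returned parameters reapply the identical transform to held-out
    samples (``params.apply``) and invert it (``params.inverse``).
    """
    if isinstance(table, MetaboliteTable):
        X0 = table.matrix()
        ids = table.metabolite_ids
    else:
        X0 = np.asarray(table, dtype=float)
        ids = None
    params = fit_scaling(X0, mode=mode, log_transform=log_transform, metabolite_ids=ids)
    return params.apply(X0), params
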