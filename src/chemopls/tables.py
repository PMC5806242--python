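"""Core data model and file I/O.

The universal interchange object is :class:`MetaboliteTable`: a samples x
metabolites peak-area matrix with a per-sample and a per-metabolite metadata
frame.  Tables are read and written as wide TSV (samples in rows) with TSV
metadata sidecars; metabolite sets come in as standard GMT.

Peak areas are in arbitrary instrument units and non-negative on input;
media-background subtraction may legitimately turn supernatant values
negative (net consumption from the medium), so the matrix is merely required
to be finite, not positive.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, TableFormatError, TableParseError

SAMPLE_META_COLUMNS = [
    "class_label",
    "fraction",
    "platform",
    "cell_line",
    "is_media_control",
    "treatment",
]
METABOLITE_META_COLUMNS = ["display_name", "pathway", "is_internal_standard"]
FRACTIONS = ("supernatant", "pellet")

# full round-trip precision for IEEE doubles
_FLOAT_FMT = "%.17g"


@dataclasses.dataclass
class MetaboliteTable:
    """Samples x metabolites intensity matrix plus metadata.

    Attributes
    ----------
    values : DataFrame
        Peak areas, index = sample ids, columns = metabolite ids.
    sample_meta : DataFrame
        Indexed by sample id with columns ``class_label`` (None for media
        controls), ``fraction`` ('supernatant' or 'pellet'), ``platform``,
        ``cell_line``, ``is_media_control`` (bool), ``treatment`` (None when
        untreated / not applicable).
    metabolite_meta : DataFrame
        Indexed by metabolite id with columns ``display_name``, ``pathway``
        (None when unmapped) and ``is_internal_standard`` (bool; at most one
        metabolite per table).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    metabolite_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].tolist()
            raise TableFormatError(f"duplicated sample ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].tolist()
            raise TableFormatError(f"duplicated metabolite ids: {dup}")
        if not idx.equals(self.sample_meta.index):
            missing = sorted(set(idx) ^ set(self.sample_meta.index))
            raise ConsistencyError(
                f"sample ids in values and sample metadata differ: {missing}"
            )
        if not cols.equals(self.metabolite_meta.index):
            missing = sorted(set(cols) ^ set(self.metabolite_meta.index))
            raise ConsistencyError(
                f"metabolite ids in values and metabolite metadata differ: {missing}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableParseError("non-numeric values in intensity matrix")
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise TableParseError(
                f"non-finite value at sample {idx[i]!r}, metabolite {cols[j]!r}"
            )
        ctrl = self.sample_meta["is_media_control"].astype(bool)
        bad = self.sample_meta.loc[ctrl & self.sample_meta["class_label"].notna()]
        if len(bad):
            raise ConsistencyError(
                f"media-control samples must have null class_label: {list(bad.index)}"
            )
        n_is = int(self.metabolite_meta["is_internal_standard"].astype(bool).sum())
        if n_is > 1:
            raise ConsistencyError(
                f"at most one internal standard per table, found {n_is}"
            )

    # -- manipulation ----------------------------------------------------
    def copy(self) -> "MetaboliteTable":
        return MetaboliteTable(
            self.values.copy(), self.sample_meta.copy(), self.metabolite_meta.copy()
        )

    def subset_samples(self, sample_ids) -> "MetaboliteTable":
        ids = list(sample_ids)
        return MetaboliteTable(
            self.values.loc[ids],
            self.sample_meta.loc[ids],
            self.metabolite_meta.copy(),
        )

    def subset_metabolites(self, metabolite_ids) -> "MetaboliteTable":
        ids = list(metabolite_ids)
        return MetaboliteTable(
            self.values[ids], self.sample_meta.copy(), self.metabolite_meta.loc[ids]
        )

    def equals(self, other: "MetaboliteTable") -> bool:
        return (
            self.values.equals(other.values)
            and self.sample_meta.equals(other.sample_meta)
            and self.metabolite_meta.equals(other.metabolite_meta)
        )


def default_metabolite_meta(metabolite_ids) -> pd.DataFrame:
    """Metabolite metadata defaults: display name = id, no pathway, not IS."""
    ids = list(metabolite_ids)
    return pd.DataFrame(
        {
            "display_name": ids,
            "pathway": [None] * len(ids),
            "is_internal_standard": [False] * len(ids),
        },
        index=pd.Index(ids, name="metabolite_id"),
    )


@dataclasses.dataclass
class PathwayDB:
    """Named metabolite sets (display-name space), e.g. read from GMT."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise TableFormatError(f"pathway {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def sidecar_paths(path) -> tuple[Path, Path]:
    """Default sample / metabolite metadata sidecar paths for a values TSV."""
    p = Path(path)
    return (
        p.with_name(p.stem + ".samples.tsv"),
        p.with_name(p.stem + ".metabolites.tsv"),
    )


def _parse_values(path, transposed: bool) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if transposed:
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.index.name = "sample_id"
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].tolist()
        raise TableFormatError(f"duplicated sample ids in {path}: {dup}")
    # pandas mangles duplicate headers; detect them from the raw header line
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    names = list(raw.columns if transposed else header)
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise TableFormatError(f"duplicated metabolite ids in {path}: {dup}")
    out = {}
    for col in raw.columns:
        try:
            # numpy's strtod is correctly rounded; pd.to_numeric is not
            out[col] = raw[col].astype(float)
        except (ValueError, TypeError):
            for row, cell in raw[col].items():
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise TableParseError(
                        f"non-numeric value {cell!r} at sample {row!r}, "
                        f"metabolite {col!r} in {path}"
                    ) from None
            raise
    df = pd.DataFrame(out, index=raw.index)
    df.columns.name = "metabolite_id"
    return df.astype(float)


def _none_where_empty(s: pd.Series) -> pd.Series:
    return s.map(lambda v: None if (isinstance(v, str) and v == "") else v)


def _read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise TableFormatError(f"sample metadata {path} lacks columns {missing}")
    meta = meta[SAMPLE_META_COLUMNS].copy()
    for col in ("class_label", "treatment", "fraction", "platform", "cell_line"):
        meta[col] = _none_where_empty(meta[col])
    meta["is_media_control"] = meta["is_media_control"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    if meta["is_media_control"].isna().any():
        raise TableParseError(f"unparseable is_media_control flag in {path}")
    return meta


def _read_metabolite_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    meta.index = meta.index.astype(str)
    meta.index.name = "metabolite_id"
    missing = [c for c in METABOLITE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise TableFormatError(f"metabolite metadata {path} lacks columns {missing}")
    meta = meta[METABOLITE_META_COLUMNS].copy()
    meta["pathway"] = _none_where_empty(meta["pathway"])
    meta["is_internal_standard"] = meta["is_internal_standard"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    if meta["is_internal_standard"].isna().any():
        raise TableParseError(f"unparseable is_internal_standard flag in {path}")
    return meta


def read_table(path, meta_path=None, metabolite_meta_path=None,
               transposed: bool = False) -> MetaboliteTable:
    """Read a wide TSV peak table plus its metadata sidecar(s).

    ``meta_path`` defaults to ``<stem>.samples.tsv`` next to the values file;
    a metabolite sidecar (``<stem>.metabolites.tsv``) is used when present,
    otherwise defaults are applied (no pathway, not an internal standard).
    Set ``transposed`` for tables exported metabolites-in-rows.
    """
    default_smeta, default_mmeta = sidecar_paths(path)
    if meta_path is None:
        meta_path = default_smeta
    values = _parse_values(path, transposed)
    sample_meta = _read_sample_meta(meta_path)
    missing = [s for s in values.index if s not in sample_meta.index]
    if missing:
        raise ConsistencyError(
            f"samples present in {path} but absent from {meta_path}: {missing}"
        )
    sample_meta = sample_meta.loc[values.index]
    if metabolite_meta_path is None and default_mmeta.exists():
        metabolite_meta_path = default_mmeta
    if metabolite_meta_path is not None:
        mmeta = _read_metabolite_meta(metabolite_meta_path)
        missing = [m for m in values.columns if m not in mmeta.index]
        if missing:
            raise ConsistencyError(
                f"metabolites absent from {metabolite_meta_path}: {missing}"
            )
        mmeta = mmeta.loc[values.columns]
    else:
        mmeta = default_metabolite_meta(values.columns)
    return MetaboliteTable(values, sample_meta, mmeta)


def _meta_out(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool or col.startswith("is_"):
            out[col] = out[col].map(lambda v: "True" if bool(v) else "False")
        else:
            out[col] = out[col].map(lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v))
    return out


def write_table(table: MetaboliteTable, path) -> None:
    """Write the values TSV (17 significant digits) and metadata sidecars.

    Deterministic: column order is the table's own, line endings LF, UTF-8.
    """
    table.validate()
    p = Path(path)
    smeta_path, mmeta_path = sidecar_paths(p)
    table.values.to_csv(
        p, sep="\t", float_format=_FLOAT_FMT, lineterminator="\n", encoding="utf-8"
    )
    _meta_out(table.sample_meta).to_csv(
        smeta_path, sep="\t", lineterminator="\n", encoding="utf-8"
    )
    _meta_out(table.metabolite_meta).to_csv(
        mmeta_path, sep="\t", lineterminator="\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> PathwayDB:
    """Parse a GMT metabolite-set file: name <tab> description <tab> members."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >=3"
                )
            name = fields[0].strip()
            members = {m.strip() for m in fields[2:] if m.strip()}
            if name in sets:
                raise TableFormatError(
                    f"{path}: duplicate pathway name {name!r} at line {lineno}"
                )
            if not members:
                raise TableFormatError(
                    f"{path}: pathway {name!r} at line {lineno} has no members"
                )
            sets[name] = members
    return PathwayDB(sets=sets, source=str(path))


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(db.sets):
            members = "\t".join(sorted(db.sets[name]))
            fh.write(f"{name}\t{db.source or 'chemopls'}\t{members}\n")


# ---------------------------------------------------------------------------
# Strata
# ---------------------------------------------------------------------------

def split_strata(table: MetaboliteTable) -> list[tuple[str, str, MetaboliteTable]]:
    """Partition into one sub-table per observed (platform, fraction) pair.

    The per-platform/per-fraction data are modelled separately throughout the
    pipeline; media controls stay inside their stratum so background
    subtraction remains possible downstream.
    """
    table.validate()
    keys = (
        table.sample_meta[["platform", "fraction"]]
        .apply(lambda r: (r["platform"], r["fraction"]), axis=1)
        .tolist()
    )
    out = []
    for key in sorted(set(keys)):
        ids = [s for s, k in zip(table.sample_ids, keys) if k == key]
        out.append((key[0], key[1], table.subset_samples(ids)))
    return out
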