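"""Data containers and file I/O for the methylation-cohort pipeline.

The pipeline moves five kinds of data around, each with a standard plain-text
carrier format:

* :class:`BetaMatrix` — samples x CpGs methylation fractions, TSV
* :class:`SampleTable` — per-sample clinical metadata and survival triple, CSV
* :class:`PromoterMap` — CpG-to-promoter assignments, BED6
* :class:`GeneSetCollection` — named gene sets, GMT
* :class:`ClockModel` — epigenetic-clock weights, JSON

All readers validate invariants up front and raise typed errors from
:mod:`graftage.errors`; nothing is silently coerced.  Every reader/writer
pair round-trips losslessly (ids bitwise, numerics to ~1e-12).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    BetaRangeError,
    CoordinateError,
    FormatError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "BetaMatrix",
    "SampleTable",
    "PromoterMap",
    "GeneSetCollection",
    "ClockModel",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_promoter_map",
    "write_promoter_map",
    "serialize_clock",
    "load_clock",
    "REQUIRED_SAMPLE_COLUMNS",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Methylation beta values, samples as rows and CpG probes as columns.

    ``values`` is a float DataFrame indexed by sample id with CpG-id columns.
    Betas are methylation fractions in [0, 1]; missing measurements are NaN
    (never 0 — a zero beta is a real, fully unmethylated measurement).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].tolist()
            raise FormatError(f"duplicate CpG ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise BetaRangeError(
                f"beta value {arr[i, j]!r} outside [0, 1] at sample "
                f"{v.index[i]!r}, probe {v.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(sample_ids)].copy())


#: columns a sample sheet must provide, in canonical order
REQUIRED_SAMPLE_COLUMNS = [
    "sample_id",
    "donor_age",
    "recipient_age",
    "pgd",
    "batch",
    "entry_time",
    "event_time",
    "event",
]

#: optional, typed if present
OPTIONAL_SAMPLE_COLUMNS = [
    "donor_sex",
    "recipient_sex",
    "donor_bmi",
    "recipient_bmi",
    "donor_white",
    "recipient_white",
    "cmv_group",
    "indication",
]

_BOOL_COLUMNS = {"pgd", "event", "donor_white", "recipient_white"}
_FLOAT_COLUMNS = {"donor_age", "recipient_age", "donor_bmi", "recipient_bmi",
                  "entry_time", "event_time"}


@dataclass
class SampleTable:
    """Per-sample metadata: ages, PGD exposure, batch, covariates, survival.

    * ``donor_age`` is graft chronologic age in years at the airway brush
      (brush date minus donor birthdate); ``recipient_age`` likewise for the
      recipient.
    * ``pgd`` marks severe primary graft dysfunction (grade 3) vs grade <= 1.
    * ``entry_time``/``event_time`` are days post-transplant of the brush and
      of CLAD-or-death (or censoring); subjects are only under observation
      from ``entry_time`` on, so survival models left-truncate there.

    Unknown columns are carried through untouched as extra covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"sample table missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id values in sample table")
        df = df.copy()
        for c in df.columns:
            if c in _BOOL_COLUMNS:
                df[c] = _coerce_bool(df[c], c)
            elif c in _FLOAT_COLUMNS:
                df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        for c in ("donor_age", "recipient_age"):
            if (df[c] <= 0).any():
                raise ValidationError(f"{c} must be positive")
        if (df["entry_time"] <= 0).any():
            raise ValidationError("entry_time must be positive (days post-transplant)")
        if (df["event_time"] < df["entry_time"]).any():
            bad = df.loc[df["event_time"] < df["entry_time"], "sample_id"].tolist()
            raise ValidationError(
                f"event_time earlier than entry_time for samples {bad}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def n(self) -> int:
        return len(self.data)

    def aligned_to(self, sample_ids: Iterable[str]) -> "SampleTable":
        """Reorder rows to match ``sample_ids`` (e.g. a BetaMatrix's rows)."""
        idx = self.data.set_index("sample_id")
        wanted = list(sample_ids)
        missing = [s for s in wanted if s not in idx.index]
        if missing:
            raise ValidationError(f"samples absent from table: {missing[:5]}")
        return SampleTable(idx.loc[wanted].reset_index())


@dataclass
class PromoterMap:
    """CpG -> promoter assignments with 0-based half-open BED coordinates.

    One row per (cpg_id, gene) pair; a CpG inside two overlapping promoter
    windows appears twice and contributes to both promoters downstream.
    """

    entries: pd.DataFrame  # columns: cpg_id, gene, chrom, start, end, strand

    COLUMNS = ["cpg_id", "gene", "chrom", "start", "end", "strand"]

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"promoter map missing columns: {missing}")
        df = df[self.COLUMNS].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] < 0).any():
            raise CoordinateError("negative start coordinate")
        if (df["start"] >= df["end"]).any():
            row = df[df["start"] >= df["end"]].iloc[0]
            raise CoordinateError(
                f"start >= end for {row['gene']} ({row['start']} >= {row['end']})"
            )
        if not df["strand"].isin(["+", "-", "."]).all():
            raise FormatError("strand must be one of '+', '-', '.'")
        self.entries = df.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries["gene"].unique())

    def cpgs_for_gene(self, gene: str) -> list[str]:
        return self.entries.loc[self.entries["gene"] == gene, "cpg_id"].tolist()


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> de-duplicated symbols."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            seen: set[str] = set()
            deduped = [g for g in genes if not (g in seen or seen.add(g))]
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClockModel:
    """A linear epigenetic clock on the calibrated age scale.

    Predicted age is ``inverse_transform(intercept + weights . betas)`` where
    the transform is the piecewise log/linear age calibration anchored at
    ``adult_age`` (see :mod:`graftage.clock`).  ``training_meta`` is free-form
    provenance; when produced by :func:`graftage.clock.train_clock` it carries
    per-CpG training means used to impute probes missing at prediction time.
    """

    cpg_ids: list[str]
    weights: np.ndarray
    intercept: float
    adult_age: float
    training_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or len(self.weights) != len(self.cpg_ids):
            raise SchemaError(
                f"clock has {len(self.cpg_ids)} CpGs but "
                f"{self.weights.size} weights"
            )
        if not self.adult_age > 0:
            raise ValidationError("adult_age must be positive")

    @property
    def n_nonzero(self) -> int:
        """Number of CpGs with nonzero weight (the clock's effective size)."""
        return int(np.count_nonzero(self.weights))

    def training_means(self) -> np.ndarray | None:
        means = self.training_meta.get("cpg_means")
        if means is None:
            return None
        return np.asarray(means, dtype=float)


# ---------------------------------------------------------------------------
# beta matrix TSV
# ---------------------------------------------------------------------------


def read_beta_matrix(path: str | Path, *, sep: str = "\t",
                     transposed: bool = False) -> BetaMatrix:
    """Read a beta matrix from TSV.

    Layout: header row of CpG ids, first column of sample ids.  With
    ``transposed=True`` the file has samples in columns (CpGs x samples),
    the common layout for array exports, and is flipped on read.  Empty cells
    and ``NA``/``NaN`` become missing values.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    if transposed:
        df = df.T
    values = pd.DataFrame(index=df.index.astype(str),
                          columns=df.columns.astype(str), dtype=float)
    for j, col in enumerate(df.columns):
        raw = df.iloc[:, j]
        cleaned = raw.where(~raw.isin(["", "NA", "NaN", "nan"]), np.nan)
        try:
            values.iloc[:, j] = cleaned.astype(float)
        except ValueError:
            for i, cell in enumerate(cleaned):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric beta {cell!r} at sample "
                        f"{df.index[i]!r}, probe {col!r}"
                    ) from None
            raise
    return BetaMatrix(values)


def write_beta_matrix(bm: BetaMatrix, path: str | Path, *,
                      sep: str = "\t") -> None:
    bm.values.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# sample sheet CSV
# ---------------------------------------------------------------------------


def _coerce_bool(s: pd.Series, name: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    out = []
    for v in s:
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        elif isinstance(v, (int, np.integer)) and v in (0, 1):
            out.append(bool(v))
        else:
            key = str(v).strip().lower()
            if key not in mapping:
                raise ValidationError(f"column {name!r}: not a boolean: {v!r}")
            out.append(mapping[key])
    return pd.Series(out, index=s.index, dtype=bool)


def read_sample_table(path: str | Path) -> SampleTable:
    """Read the sample sheet CSV; unknown columns ride along as covariates."""
    df = pd.read_csv(path)
    df.columns = [str(c) for c in df.columns]
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].astype(str)
    if "batch" in df.columns:
        df["batch"] = df["batch"].astype(str)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gene sets GMT
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in genes if g]
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            desc = coll.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# promoter map BED6
# ---------------------------------------------------------------------------


def read_promoter_map(path: str | Path) -> PromoterMap:
    """Read BED6 rows ``chrom start end gene cpg_id strand``.

    BED's name field carries the gene symbol and the score field the CpG id
    (scores are meaningless for promoter windows).  Coordinates are 0-based
    half-open, as in any BED file.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: BED6 needs 6 fields, got {len(fields)}"
                )
            chrom, start, end, gene, cpg_id, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start!r}/{end!r}"
                ) from None
            rows.append((cpg_id, gene, chrom, start_i, end_i, strand))
    df = pd.DataFrame(rows, columns=PromoterMap.COLUMNS)
    return PromoterMap(df)


def write_promoter_map(pmap: PromoterMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in pmap.entries.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene}\t"
                     f"{row.cpg_id}\t{row.strand}\n")


# ---------------------------------------------------------------------------
# clock model JSON
# ---------------------------------------------------------------------------

_CLOCK_KEYS = {"cpg_ids", "weights", "intercept", "adult_age", "training_meta"}


def serialize_clock(model: ClockModel, path: str | Path) -> None:
    doc = {
        "cpg_ids": list(model.cpg_ids),
        "weights": [float(w) for w in model.weights],
        "intercept": float(model.intercept),
        "adult_age": float(model.adult_age),
        "training_meta": _jsonable(model.training_meta),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_clock(path: str | Path) -> ClockModel:
    with open(path) as fh:
        doc = json.load(fh)
    missing = _CLOCK_KEYS - set(doc)
    if missing:
        raise SchemaError(f"clock JSON missing keys: {sorted(missing)}")
    return ClockModel(
        cpg_ids=[str(c) for c in doc["cpg_ids"]],
        weights=np.asarray(doc["weights"], dtype=float),
        intercept=float(doc["intercept"]),
        adult_age=float(doc["adult_age"]),
        training_meta=doc["training_meta"] or {},
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
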