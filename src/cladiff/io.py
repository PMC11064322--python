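"""Taxa tables and label vectors: validated containers plus CSV/TSV round-trip.

The two in-memory containers mirror what every downstream step consumes:

* :class:`TaxaTable` — a samples x features abundance matrix (pandas
  DataFrame) whose columns are :class:`~cladiff.taxonomy.RankPath` objects,
  tagged with a ``value_kind`` recording how far it has been processed.
* :class:`LabelVector` — one number per sample, binary (0/1) or continuous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import RankPath, parse_taxonomy_string

log = logging.getLogger(__name__)

VALUE_KINDS = ("raw", "relative", "log_processed")


class ValidationError(ValueError):
    """Raised when an input table or metadata file violates an invariant."""


@dataclass
class TaxaTable:
    """Samples x taxonomic-features abundance matrix.

    Parameters
    ----------
    data : DataFrame
        index = sample ids (unique strings), columns = RankPath (unique).
    value_kind : {"raw", "relative", "log_processed"}
        Raw counts / relative abundances straight from a file are "raw";
        normalisation updates the tag.
    """

    data: pd.DataFrame
    value_kind: str = "raw"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        idx = self.data.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        cols = self.data.columns
        if cols.has_duplicates:
            raise ValidationError("duplicate feature paths")
        for c in cols:
            if not isinstance(c, RankPath):
                raise ValidationError(f"feature {c!r} is not a RankPath")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("non-numeric values in taxa table")
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite values in taxa table")
        if self.value_kind == "raw" and (vals < 0).any():
            bad = self.data.columns[(vals < 0).any(axis=0)][0]
            raise ValidationError(f"negative abundance in feature {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[RankPath]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values_for(self, path: RankPath) -> np.ndarray:
        return self.data[path].to_numpy(dtype=float)

    def write(self, path: str | Path, orientation: str = "samples_rows") -> None:
        """Write as TSV/CSV (by extension) with full float precision."""
        df = self.data.copy()
        df.columns = [str(c) for c in df.columns]
        df.index.name = "sample_id"
        if orientation == "features_rows":
            df = df.T
            df.index.name = "taxonomy"
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df.to_csv(path, sep=sep, float_format="%.17g")


@dataclass
class LabelVector:
    """Per-sample label, binary (0/1) or continuous."""

    series: pd.Series
    kind: str = "binary"
    mapping: dict | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValidationError(f"unknown label kind {self.kind!r}")
        if self.series.isna().any():
            bad = self.series.index[self.series.isna()].tolist()
            raise ValidationError(f"missing labels for samples: {bad}")
        if self.kind == "binary":
            uniq = set(pd.unique(self.series))
            if not uniq <= {0, 1}:
                raise ValidationError(f"binary labels must be 0/1, got {sorted(uniq)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.series.index)

    @property
    def values(self) -> np.ndarray:
        return self.series.to_numpy(dtype=float)

    def require_both_classes(self) -> None:
        if self.kind == "binary":
            uniq = set(pd.unique(self.series))
            if uniq != {0, 1}:
                raise ValidationError("binary label needs both classes present")


def read_taxa_table(
    path: str | Path,
    orientation: str = "samples_rows",
    dialect: str = "greengenes",
    sep: str | None = None,
    value_kind: str = "raw",
) -> TaxaTable:
    """Read a CSV/TSV abundance table.

    Parameters
    ----------
    orientation : {"samples_rows", "features_rows"}
        Which axis carries sample ids.  The other axis must be taxonomy
        strings.
    sep : str, optional
        Field delimiter; inferred from the extension when omitted
        (``.tsv``/``.txt`` -> tab, else comma).
    value_kind : {"raw", "relative", "log_processed"}
        Declare already-processed values (e.g. simulated Gaussian
        fixtures) to skip the non-negativity check and preprocessing.
    """
    if orientation not in ("samples_rows", "features_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if orientation == "features_rows":
        df = df.T
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in {path}: {dups}")
    cols = [parse_taxonomy_string(str(c), dialect=dialect) for c in df.columns]
    df.columns = cols
    return TaxaTable(df, value_kind=value_kind)


def read_metadata(
    path: str | Path,
    label_col: str,
    sample_col: str | None = None,
    mapping: dict | None = None,
    sep: str | None = None,
) -> LabelVector:
    """Read per-sample metadata and extract one label column.

    Exactly two distinct values -> binary, mapped to 0/1 by sorted order
    (lexicographically smaller -> 0) unless an explicit ``mapping`` is
    given; otherwise the column must be numeric and is kept continuous.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if sample_col is None:
        sample_col = df.columns[0]
    if label_col not in df.columns:
        raise ValidationError(f"label column {label_col!r} not in {path}")
    df = df.set_index(df[sample_col].astype(str))
    ser = df[label_col]
    if ser.isna().any():
        bad = ser.index[ser.isna()].tolist()
        raise ValidationError(f"missing values in {label_col!r} for samples: {bad}")
    uniq = pd.unique(ser)
    if mapping is not None:
        ser = ser.map(mapping)
        if ser.isna().any():
            raise ValidationError("label mapping does not cover all values")
        return LabelVector(ser.astype(int), kind="binary", mapping=dict(mapping))
    if len(uniq) == 2:
        lo, hi = sorted(uniq, key=str)
        mapped = ser.map({lo: 0, hi: 1}).astype(int)
        return LabelVector(mapped, kind="binary", mapping={lo: 0, hi: 1})
    try:
        ser = ser.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"label column {label_col!r} has {len(uniq)} non-numeric values; "
            "expected 2 (binary) or numeric (continuous)"
        ) from exc
    return LabelVector(ser, kind="continuous")


def join_samples(table: TaxaTable, labels: LabelVector) -> tuple[TaxaTable, LabelVector]:
    """Align a table and labels on their common samples (table order kept).

    Samples present in only one input are dropped with a warning, not an
    error — metadata mismatches are routine.
    """
    common = [s for s in table.sample_ids if s in set(labels.sample_ids)]
    n_drop = (len(table.sample_ids) - len(common)) + (len(labels.sample_ids) - len(common))
    if n_drop:
        msg = f"dropping {n_drop} samples present in only one input"
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not common:
        raise ValidationError("no samples shared between table and labels")
    t = TaxaTable(table.data.loc[common], value_kind=table.value_kind)
    lab = LabelVector(labels.series.loc[common], kind=labels.kind, mapping=labels.mapping)
    return t, lab
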