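"""Tables, metadata and basic preparation steps.

The pipeline's central container is :class:`GenusAbundanceTable`, a thin
wrapper around a samples x genera :class:`pandas.DataFrame` that tracks
whether values are raw counts or relative abundances.  Everything downstream
(diversity, co-abundance analysis, subject clustering) consumes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenusAbundanceTable",
    "TableParseError",
    "read_table",
    "write_table",
    "read_metadata",
    "write_metadata",
    "to_relative",
    "assign_age_group",
    "AGE_GROUP_LABELS",
    "prevalence",
    "filter_by_prevalence",
    "zscore_table",
]

#: The 14 age-group labels: three weaning-defined infant groups, one
#: pre-adolescent group, then decade bins, with everyone >= 100 pooled.
AGE_GROUP_LABELS = (
    "1", "2", "3", "4", "10", "20", "30", "40", "50",
    "60", "70", "80", "90", "100",
)

_REL_TOL = 1e-6


class TableParseError(ValueError):
    """Raised when an abundance table violates its contract."""


@dataclass
class GenusAbundanceTable:
    """Samples x genus-level taxa abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample identifiers as the index and taxon
        identifiers as columns.  Values must be nonnegative.
    mode:
        ``"counts"`` for (possibly copy-number-corrected) counts,
        ``"relative"`` when every row sums to 1.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise TableParseError(f"duplicate sample id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise TableParseError(f"duplicate taxon id {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            i, j = np.argwhere(vals < 0)[0]
            raise TableParseError(
                f"negative value at sample {idx[i]!r}, taxon {cols[j]!r}"
            )
        if np.isnan(vals).any():
            i, j = np.argwhere(np.isnan(vals))[0]
            raise TableParseError(
                f"missing value at sample {idx[i]!r}, taxon {cols[j]!r}"
            )
        if self.mode == "relative" and len(idx):
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 1.0) > _REL_TOL
            if bad.any():
                raise TableParseError(
                    f"relative-mode row {idx[int(np.argmax(bad))]!r} sums to "
                    f"{sums[bad][0]:.6g}, expected 1"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "GenusAbundanceTable":
        return GenusAbundanceTable(self.data.copy(), self.mode)


def _detect_mode(df: pd.DataFrame) -> str:
    sums = df.to_numpy(dtype=float).sum(axis=1)
    if len(sums) and np.all(np.abs(sums - 1.0) <= _REL_TOL):
        return "relative"
    return "counts"


def read_table(
    path: str | Path,
    mode: str | None = None,
    drop_empty_taxa: bool = True,
) -> GenusAbundanceTable:
    """Read a TSV abundance table (rows samples, header row of taxon ids).

    Mode is auto-detected when not given: if every row sums to ~1 the table
    is taken as relative abundances, otherwise as counts.  Taxa that are
    zero in every sample are dropped with a warning (they carry no signal
    and break correlation-based steps).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise TableParseError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise TableParseError(f"non-numeric values in taxon column {col!r}")
    table = GenusAbundanceTable(df, mode or _detect_mode(df))
    if drop_empty_taxa:
        empty = [t for t in df.columns if (df[t] == 0).all()]
        if empty:
            warnings.warn(
                f"dropping {len(empty)} taxa absent from every sample: "
                f"{empty[:5]}{'...' if len(empty) > 5 else ''}",
                stacklevel=2,
            )
            table = GenusAbundanceTable(df.drop(columns=empty), table.mode)
    return table


def write_table(table: GenusAbundanceTable, path: str | Path) -> None:
    """Write a table as TSV; float repr round-trips to full precision."""
    table.data.to_csv(path, sep="\t", index_label="sample_id")


_METADATA_COLS = ["age_years", "sex", "feeding_stage", "age_group"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata TSV (sample_id, age_years, sex, ...)."""
    md = pd.read_csv(
        path, sep="\t", index_col=0, dtype={"age_group": str}
    )
    missing = [c for c in ("age_years", "sex") if c not in md.columns]
    if missing:
        raise TableParseError(f"metadata lacks required columns {missing}")
    if (md["age_years"] < 0).any():
        bad = md.index[md["age_years"] < 0][0]
        raise TableParseError(f"negative age for sample {bad!r}")
    return md


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def to_relative(table: GenusAbundanceTable) -> GenusAbundanceTable:
    """Convert a counts table to per-sample relative abundances."""
    if table.mode != "counts":
        raise ValueError("table is already in relative mode")
    sums = table.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total abundance")
    return GenusAbundanceTable(table.data.div(sums, axis=0), "relative")


def assign_age_group(age_years: float, feeding_stage: str | None = None) -> str:
    """Map an age (and, for infants, a feeding stage) to its group label.

    Children under 4 are segmented by weaning status rather than age:
    preweaning -> "1", weaning -> "2", weaned -> "3".  From there, ages 4-9
    form group "4", each later decade its own group, and everyone 100 or
    older is pooled into "100".
    """
    if age_years < 0:
        raise ValueError("age must be nonnegative")
    if age_years < 4:
        stage = (feeding_stage or "").lower()
        if stage == "preweaning":
            return "1"
        if stage == "weaning":
            return "2"
        if stage == "weaned":
            return "3"
        raise ValueError(
            f"feeding stage required for age {age_years} < 4 "
            f"(got {feeding_stage!r})"
        )
    if age_years < 10:
        return "4"
    if age_years >= 100:
        return "100"
    return str(int(age_years // 10) * 10)


def prevalence(table: GenusAbundanceTable) -> pd.Series:
    """Per-taxon fraction of samples in which the taxon is present (>0)."""
    return (table.data > 0).mean(axis=0)


def filter_by_prevalence(
    table: GenusAbundanceTable,
    threshold: float,
    scope: str = "overall",
    partition: pd.Series | None = None,
) -> GenusAbundanceTable:
    """Keep taxa by prevalence, overall or within any cluster.

    ``overall`` keeps taxa whose cohort-wide prevalence strictly exceeds
    ``threshold`` ("more than" semantics).  ``any_cluster`` keeps taxa whose
    prevalence reaches ``>= threshold`` in at least one cluster of
    ``partition`` (a sample -> cluster Series).  Taxon order is preserved.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if scope == "overall":
        keep = prevalence(table) > threshold
    elif scope == "any_cluster":
        if partition is None:
            raise ValueError("any_cluster scope requires a partition")
        present = table.data > 0
        keep = pd.Series(False, index=table.data.columns)
        for _, members in partition.groupby(partition):
            keep |= present.loc[members.index].mean(axis=0) >= threshold
    else:
        raise ValueError(f"unknown scope {scope!r}")
    kept = table.data.loc[:, keep.to_numpy()]
    if kept.shape[1] == 0:
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
    return GenusAbundanceTable(kept, table.mode)


def zscore_table(table: GenusAbundanceTable) -> pd.DataFrame:
    """Z-score each taxon across samples (sample sd, n-1 denominator).

    Constant taxa become all-zero columns; a warning records them.  The
    result intentionally carries mode "relative" semantics no longer, so it
    is returned as a bare DataFrame.
    """
    if table.mode != "relative":
        raise ValueError("z-scoring expects a relative-abundance table")
    if table.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mean = table.data.mean(axis=0)
    sd = table.data.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa z-scored to 0: "
            f"{list(table.data.columns[constant])[:5]}",
            stacklevel=2,
        )
    safe_sd = sd.replace(0, 1.0)
    z = (table.data - mean) / safe_sd
    z.loc[:, constant] = 0.0
    return z
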