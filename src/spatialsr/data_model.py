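"""Cell-map data model and tabular I/O.

The universal input is a per-cell coordinate table: one row per segmented
nucleus with its sample of origin, planar position in micrometers and a
phenotype drawn from a closed seven-class vocabulary (six marker-defined
classes plus ``negative`` for cells negative on every antibody of the
panel). Coordinates are treated as abstract planar positions; only
pairwise distances matter downstream, so origin and axis orientation are
irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed phenotype vocabulary. ``negative`` collects stromal cells and
#: immune cells not covered by the antibody panel.
CELL_TYPES: tuple[str, ...] = (
    "cancer",
    "cd8_t",
    "foxp3_t",
    "t_helper",
    "b_cell",
    "macrophage",
    "negative",
)

#: Canonical column names; a mapping may rename platform-specific exports.
CANONICAL_COLUMNS = ("sample_id", "x", "y", "cell_type")

RESPONSE_LABELS = ("responder", "non_responder")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class VocabularyError(ValueError):
    """A cell-type label is outside the closed vocabulary."""


class CoordinateParseError(ValueError):
    """A coordinate could not be parsed as a finite number."""


@dataclass
class CellTable:
    """Validated per-cell records for one or more tissue slides.

    Wraps a :class:`pandas.DataFrame` with columns ``sample_id``, ``x``,
    ``y`` (μm), ``cell_type``, ``focus_id`` (−2 until focus splitting has
    run, −1 for noise cells) and ``compartment`` (``unassigned`` until
    segmentation has run).
    """

    df: pd.DataFrame = field(repr=False)

    UNASSIGNED_FOCUS: int = -2

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CellTable":
        """Validate a raw dataframe into a :class:`CellTable`.

        Validation is idempotent: validating an already-valid table is a
        no-op apart from copying.
        """
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        out = df.copy()

        for col in ("x", "y"):
            coerced = pd.to_numeric(out[col], errors="coerce")
            bad = coerced.isna() | ~np.isfinite(coerced)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CoordinateParseError(
                    f"non-numeric or non-finite {col!r} at row {row}: "
                    f"{out[col].iloc[row]!r}"
                )
            out[col] = coerced.astype(float)

        out["sample_id"] = out["sample_id"].astype(str)
        out["cell_type"] = out["cell_type"].astype(str)
        unknown = sorted(set(out["cell_type"]) - set(CELL_TYPES))
        if unknown:
            raise VocabularyError(
                f"unknown cell_type label(s): {unknown}; "
                f"allowed: {list(CELL_TYPES)}"
            )

        n_before = len(out)
        out = out.drop_duplicates(subset=["sample_id", "x", "y", "cell_type"])
        n_dropped = n_before - len(out)
        if n_dropped:
            logger.warning("dropped %d exact duplicate cell row(s)", n_dropped)

        if "focus_id" not in out.columns:
            out["focus_id"] = cls.UNASSIGNED_FOCUS
        out["focus_id"] = out["focus_id"].astype(int)
        if "compartment" not in out.columns:
            out["compartment"] = "unassigned"
        allowed_comp = {"tumor", "stroma", "unassigned"}
        bad_comp = sorted(set(out["compartment"]) - allowed_comp)
        if bad_comp:
            raise VocabularyError(f"unknown compartment label(s): {bad_comp}")

        return cls(df=out.reset_index(drop=True))

    # -- convenience -----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample_id"]))

    def for_sample(self, sample_id: str) -> "CellTable":
        sub = self.df[self.df["sample_id"] == sample_id]
        return CellTable(df=sub.reset_index(drop=True))

    def coords(self, cell_type: str | None = None) -> np.ndarray:
        """(n, 2) array of positions, optionally restricted to one type."""
        df = self.df
        if cell_type is not None:
            df = df[df["cell_type"] == cell_type]
        return df[["x", "y"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CohortLabels:
    """Binary response labels, one per sample."""

    df: pd.DataFrame = field(repr=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortLabels":
        missing = [c for c in ("sample_id", "response") if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        out = df[["sample_id", "response"]].copy()
        out["sample_id"] = out["sample_id"].astype(str)
        bad = sorted(set(out["response"]) - set(RESPONSE_LABELS))
        if bad:
            raise VocabularyError(
                f"unknown response label(s): {bad}; allowed: {list(RESPONSE_LABELS)}"
            )
        if out["sample_id"].duplicated().any():
            raise SchemaError("duplicated sample_id in labels")
        return cls(df=out.reset_index(drop=True))

    def check_against(self, cells: CellTable) -> None:
        """Every labeled sample must exist in the cohort's cell tables."""
        known = set(cells.sample_ids)
        orphan = sorted(set(self.df["sample_id"]) - known)
        if orphan:
            raise SchemaError(f"labels reference unknown sample(s): {orphan}")

    def as_series(self) -> pd.Series:
        return self.df.set_index("sample_id")["response"]


def read_cell_table(
    path,
    dialect: str | None = None,
    column_map: dict[str, str] | None = None,
) -> CellTable:
    """Read a per-cell CSV/TSV into a validated :class:`CellTable`.

    Parameters
    ----------
    path
        File with a header row and one row per cell.
    dialect
        ``"csv"`` or ``"tsv"``; inferred from the file extension when
        omitted.
    column_map
        Optional mapping from the file's column names to the canonical
        names (``sample_id``, ``x``, ``y``, ``cell_type``), so exports
        from common image-analysis platforms load without editing.
    """
    sep = _separator(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    return CellTable.from_dataframe(df)


def read_labels(path, dialect: str | None = None) -> CohortLabels:
    """Read a two-column (sample_id, response) label file."""
    sep = _separator(path, dialect)
    return CohortLabels.from_dataframe(pd.read_csv(path, sep=sep, dtype=str))


def write_cell_table(ct: CellTable, path, dialect: str | None = None) -> None:
    ct.df.to_csv(path, sep=_separator(path, dialect), index=False)


def write_metrics(table: pd.DataFrame, path) -> None:
    """Write a per-sample metrics matrix as TSV.

    One row per sample, columns in their existing (deterministic) order;
    round-trips losslessly through :func:`read_metrics`.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty metrics matrix")
    out = table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    return df


def _separator(path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".tab", ".txt")) else "csv"
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","
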