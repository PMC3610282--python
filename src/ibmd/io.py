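"""Reading and writing rating tables.

Two CSV dialects, both strict RFC-4180-style with period decimals:

* wide — header row; first column the case identifier, every remaining
  column one observer; an empty cell is a missing observation (never zero —
  an explicit ``0`` is a legal reading on a non-negative ratio scale).
* long — columns ``case_id``, ``observer_id``, ``value``; one row per
  observation; (case, observer) pairs must be unique.

Either dialect may carry an extra grouping column (for example a rulebook or
labor-phase label) named via ``group_column``; reading with a group column
returns one table per group label.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import DataError, NoComparablePairsError, RatingsTable

__all__ = ["read_table", "write_table"]

_LONG_COLUMNS = ("case_id", "observer_id", "value")


def _parse_cell(raw: str, row_number: int, column: str) -> float | None:
    """Strict numeric cell: blank is missing, comma decimals are rejected."""
    text = raw.strip()
    if not text:
        return None
    if "," in text:
        raise DataError(
            f"row {row_number}, column {column!r}: {raw!r} — decimal commas "
            "are not accepted; use a period decimal separator"
        )
    try:
        value = float(text)
    except ValueError:
        raise DataError(
            f"row {row_number}, column {column!r}: {raw!r} is not a number"
        ) from None
    if not value == value or value in (float("inf"), float("-inf")):
        raise DataError(f"row {row_number}, column {column!r}: non-finite value")
    if value < 0:
        raise DataError(
            f"row {row_number}, column {column!r}: negative value {text} "
            "(observations must be on a non-negative ratio scale)"
        )
    return value


def _read_csv_strict(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame


def read_table(
    path: str | Path,
    format: str = "wide",
    group_column: str | None = None,
):
    """Parse a ratings CSV into one :class:`RatingsTable`, or one per group.

    With ``group_column`` the rows are split by that column's label,
    preserving case order, and a ``{label: RatingsTable}`` dict is returned.
    Raises :class:`NoComparablePairsError` when no case in the file has at
    least two observations.
    """
    path = Path(path)
    if format not in ("wide", "long"):
        raise ValueError(f"format must be 'wide' or 'long', got {format!r}")
    frame = _read_csv_strict(path)

    if format == "wide":
        table = _parse_wide(frame, group_column)
    else:
        table = _parse_long(frame, group_column)

    if all(c.n_observations < 2 for c in table):
        raise NoComparablePairsError(
            f"{path.name}: no comparable pairs — no case has two or more observations"
        )
    if group_column is None:
        return table
    return table.split_groups()


def _parse_wide(frame: pd.DataFrame, group_column: str | None) -> RatingsTable:
    from .core import CaseRecord
    import numpy as np

    case_column = frame.columns[0]
    if group_column is not None and group_column not in frame.columns:
        raise DataError(f"group column {group_column!r} not found in header")
    observer_cols = [
        c for c in frame.columns[1:] if c != group_column
    ]
    if not observer_cols:
        raise DataError("wide file has no observer columns")
    cases = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        row_number = pos + 2  # header occupies line 1
        record = dict(zip(frame.columns, row))
        vals, obs = [], []
        for col in observer_cols:
            value = _parse_cell(record[col], row_number, col)
            if value is None:
                continue
            vals.append(value)
            obs.append(col)
        cases.append(
            CaseRecord(
                case_id=str(record[case_column]).strip(),
                values=np.asarray(vals, dtype=float),
                observers=tuple(obs),
                group=None
                if group_column is None
                else str(record[group_column]).strip(),
            )
        )
    return RatingsTable(cases)


def _parse_long(frame: pd.DataFrame, group_column: str | None) -> RatingsTable:
    missing = [c for c in _LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"long file lacks required column(s) {missing}")
    if group_column is not None and group_column not in frame.columns:
        raise DataError(f"group column {group_column!r} not found in header")
    values = [
        _parse_cell(raw, pos + 2, "value")
        for pos, raw in enumerate(frame["value"])
    ]
    if any(v is None for v in values):
        pos = values.index(None)
        raise DataError(f"row {pos + 2}: blank value in long format")
    parsed = frame.assign(value=values)
    return RatingsTable.from_long(parsed, group_column=group_column)


def write_table(
    table: RatingsTable,
    path: str | Path,
    format: str = "wide",
) -> None:
    """Serialize a table to the wide or long CSV dialect (round-trip safe)."""
    if format == "wide":
        frame = table.to_wide()
    elif format == "long":
        frame = table.to_long()
    else:
        raise ValueError(f"format must be 'wide' or 'long', got {format!r}")
    frame.to_csv(path, index=False)
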