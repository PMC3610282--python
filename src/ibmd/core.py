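"""Information-based measure of disagreement (IBMD) for ragged multi-observer data.

A rating study collects, for each of N cases (subjects), a vector of
measurements on a non-negative ratio scale made by M_i observers; M_i may
vary across cases because some observers miss some cases.  The disagreement
between one pair of observations (x, y) is the information-style kernel

    d(x, y) = log2(|x - y| / max(x, y) + 1)        d(0, 0) = 0

which is 0 for identical readings and reaches 1 when one observer reports 0
and the other does not.  The IBMD of a table is the mean of d over every
within-case observer pair:

    IBMD = (1 / sum_i C(M_i, 2)) * sum_i sum_{j<k} d(x_ij, x_ik)

Because the kernel depends only on the ratio of the two readings, IBMD is
invariant to rescaling of the measurement units, which is what makes it
comparable across populations with different trait variance — unlike
reliability coefficients such as the ICC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "DataError",
    "NoComparablePairsError",
    "CaseRecord",
    "RatingsTable",
    "DisagreementEstimate",
    "pair_disagreement",
    "ibmd",
    "ibmd_two_observer",
]

logger = logging.getLogger("ibmd")


class DataError(ValueError):
    """Invalid rating data (negative values, duplicate observers, ...)."""


class NoComparablePairsError(DataError):
    """No case carries at least two observations, so no pair can be formed."""


def _validate_values(values: np.ndarray, context: str = "") -> None:
    if values.ndim != 1:
        raise DataError(f"observations must be one-dimensional{context}")
    if values.size and not np.all(np.isfinite(values)):
        raise DataError(f"non-finite observation value{context}")
    if values.size and np.any(values < 0):
        bad = float(values[values < 0][0])
        raise DataError(
            f"negative observation value {bad!r}{context}; "
            "the disagreement kernel is defined on a non-negative ratio scale"
        )


@dataclass(frozen=True)
class CaseRecord:
    """One case: an identifier and the observations made on it.

    ``observers``, when present, labels each observation and must be unique
    within the case (one reading per observer).  ``group`` is an optional
    population label used to split a table for two-population comparisons.
    """

    case_id: str
    values: np.ndarray
    observers: tuple[str, ...] | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        _validate_values(values, f" in case {self.case_id!r}")
        if self.observers is not None:
            obs = tuple(str(o) for o in self.observers)
            object.__setattr__(self, "observers", obs)
            if len(obs) != values.size:
                raise DataError(
                    f"case {self.case_id!r}: {len(obs)} observer labels "
                    f"for {values.size} observations"
                )
            if len(set(obs)) != len(obs):
                raise DataError(
                    f"case {self.case_id!r}: duplicate observer label; "
                    "the measure has no provision for replicates per observer"
                )

    @property
    def n_observations(self) -> int:
        return int(self.values.size)

    @property
    def n_pairs(self) -> int:
        m = self.values.size
        return m * (m - 1) // 2


class RatingsTable:
    """Ordered, possibly ragged collection of :class:`CaseRecord`.

    Construct directly from records, or from tidy pandas frames via
    :meth:`from_wide` / :meth:`from_long` (see :mod:`ibmd.io` for the file
    dialects).
    """

    def __init__(self, cases: Iterable[CaseRecord]):
        self.cases: tuple[CaseRecord, ...] = tuple(cases)
        if not self.cases:
            raise DataError("a ratings table needs at least one case")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self) -> Iterator[CaseRecord]:
        return iter(self.cases)

    def __repr__(self) -> str:
        return (
            f"RatingsTable(n_cases={len(self)}, "
            f"n_observations={self.n_observations})"
        )

    # -- basic summaries ----------------------------------------------------
    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(c.case_id for c in self.cases)

    @property
    def n_observations(self) -> int:
        return sum(c.n_observations for c in self.cases)

    @property
    def n_pairs(self) -> int:
        return sum(c.n_pairs for c in self.cases)

    @property
    def groups(self) -> tuple[str, ...]:
        """Distinct group labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.cases:
            if c.group is not None:
                seen.setdefault(c.group, None)
        return tuple(seen)

    def split_groups(self) -> dict[str, "RatingsTable"]:
        """Per-group sub-tables, preserving case order within each group."""
        out: dict[str, list[CaseRecord]] = {}
        for c in self.cases:
            key = c.group if c.group is not None else ""
            out.setdefault(key, []).append(c)
        return {k: RatingsTable(v) for k, v in out.items()}

    def drop_sparse_cases(self) -> tuple["RatingsTable", int]:
        """Remove cases with fewer than two observations.

        Such cases contribute no pair to numerator or denominator; they are
        removed up front so that every bootstrap resample of the remaining
        cases is well defined.  Returns the reduced table and the count
        removed.
        """
        kept = [c for c in self.cases if c.n_observations >= 2]
        dropped = len(self.cases) - len(kept)
        if not kept:
            raise NoComparablePairsError(
                "no comparable pairs: every case has fewer than two observations"
            )
        if dropped:
            logger.warning(
                "dropped %d case(s) with fewer than two observations", dropped
            )
        return RatingsTable(kept), dropped

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_rows(
        cls,
        rows: Sequence[Sequence[float]],
        case_ids: Sequence[str] | None = None,
        groups: Sequence[str] | None = None,
    ) -> "RatingsTable":
        """Build a table from plain per-case value sequences (test-friendly)."""
        cases = []
        for i, row in enumerate(rows):
            cases.append(
                CaseRecord(
                    case_id=str(case_ids[i]) if case_ids is not None else str(i + 1),
                    values=np.asarray(list(row), dtype=float),
                    group=None if groups is None else str(groups[i]),
                )
            )
        return cls(cases)

    @classmethod
    def from_wide(
        cls,
        frame,
        case_column: str | None = None,
        group_column: str | None = None,
    ) -> "RatingsTable":
        """From a wide DataFrame: one row per case, one column per observer.

        ``case_column`` defaults to the first column; remaining columns are
        observers; NaN cells are missing observations (never zero).
        """
        import pandas as pd  # local: keep numpy-only paths light

        frame = pd.DataFrame(frame)
        case_column = case_column or frame.columns[0]
        observer_cols = [
            c for c in frame.columns if c not in (case_column, group_column)
        ]
        cases = []
        for _, row in frame.iterrows():
            vals, obs = [], []
            for col in observer_cols:
                v = row[col]
                if pd.isna(v):
                    continue
                vals.append(float(v))
                obs.append(str(col))
            cases.append(
                CaseRecord(
                    case_id=str(row[case_column]),
                    values=np.asarray(vals, dtype=float),
                    observers=tuple(obs),
                    group=None if group_column is None else str(row[group_column]),
                )
            )
        return cls(cases)

    @classmethod
    def from_long(
        cls,
        frame,
        case_column: str = "case_id",
        observer_column: str = "observer_id",
        value_column: str = "value",
        group_column: str | None = None,
    ) -> "RatingsTable":
        """From a long DataFrame: one row per (case, observer, value)."""
        import pandas as pd

        frame = pd.DataFrame(frame)
        dup = frame.duplicated(subset=[case_column, observer_column])
        if dup.any():
            row = frame[dup].iloc[0]
            raise DataError(
                f"duplicate (case, observer) pair "
                f"({row[case_column]!r}, {row[observer_column]!r})"
            )
        cases = []
        for cid, sub in frame.groupby(case_column, sort=False):
            group = None
            if group_column is not None:
                labels = set(sub[group_column].astype(str))
                if len(labels) > 1:
                    raise DataError(
                        f"case {cid!r} carries conflicting group labels {sorted(labels)}"
                    )
                group = labels.pop()
            cases.append(
                CaseRecord(
                    case_id=str(cid),
                    values=sub[value_column].to_numpy(dtype=float),
                    observers=tuple(sub[observer_column].astype(str)),
                    group=group,
                )
            )
        return cls(cases)

    # -- export -------------------------------------------------------------
    def to_wide(self):
        """Wide DataFrame; observers become columns, missing cells NaN."""
        import pandas as pd

        all_obs: dict[str, None] = {}
        for c in self.cases:
            labels = c.observers or tuple(
                f"obs_{j + 1}" for j in range(c.n_observations)
            )
            for o in labels:
                all_obs.setdefault(o, None)
        has_groups = any(c.group is not None for c in self.cases)
        rows = []
        for c in self.cases:
            labels = c.observers or tuple(
                f"obs_{j + 1}" for j in range(c.n_observations)
            )
            row: dict[str, object] = {"case_id": c.case_id}
            if has_groups:
                row["group"] = c.group
            row.update(dict(zip(labels, c.values)))
            rows.append(row)
        cols = ["case_id"] + (["group"] if has_groups else []) + list(all_obs)
        return pd.DataFrame(rows, columns=cols)

    def to_long(self):
        """Long DataFrame with columns case_id, observer_id, value (+ group)."""
        import pandas as pd

        has_groups = any(c.group is not None for c in self.cases)
        rows = []
        for c in self.cases:
            labels = c.observers or tuple(
                f"obs_{j + 1}" for j in range(c.n_observations)
            )
            for o, v in zip(labels, c.values):
                row = {"case_id": c.case_id, "observer_id": o, "value": v}
                if has_groups:
                    row["group"] = c.group
                rows.append(row)
        cols = ["case_id", "observer_id", "value"] + (
            ["group"] if has_groups else []
        )
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class DisagreementEstimate:
    """IBMD point estimate with optional bootstrap confidence interval."""

    ibmd: float
    n_cases_used: int
    n_pairs_total: int
    n_cases_dropped: int = 0
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float | None = None
    n_boot: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ibmd <= 1.0:
            raise ValueError(f"IBMD out of range: {self.ibmd}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("confidence interval needs both endpoints")
        if self.ci_low is not None:
            if not 0.0 <= self.ci_low <= self.ci_high <= 1.0:
                raise ValueError(
                    f"invalid confidence interval [{self.ci_low}, {self.ci_high}]"
                )

    @property
    def ci(self) -> tuple[float, float] | None:
        if self.ci_low is None:
            return None
        return (self.ci_low, self.ci_high)


def pair_disagreement(x: float, y: float) -> float:
    """Disagreement kernel for one observation pair.

    ``log2(|x - y| / max(x, y) + 1)``, with the convention that two zero
    readings disagree by 0.  Symmetric; 0 iff x == y; 1 iff exactly one of
    the two readings is zero.
    """
    if x < 0 or y < 0:
        bad = x if x < 0 else y
        raise DataError(
            f"negative observation value {bad!r}; "
            "the disagreement kernel is defined on a non-negative ratio scale"
        )
    if x == y:
        # covers the 0/0 convention and avoids 0-division for x == y == 0
        return 0.0
    m = x if x > y else y
    return math.log2(abs(x - y) / m + 1.0)


def _case_kernel_terms(values: np.ndarray) -> np.ndarray:
    """Kernel values for every unordered observation pair of one case."""
    m = values.size
    if m < 2:
        return np.empty(0)
    i, j = np.triu_indices(m, k=1)
    x, y = values[i], values[j]
    hi = np.maximum(x, y)
    diff = np.abs(x - y)
    # hi == 0 implies x == y == 0: the convention sets the ratio to 0
    ratio = np.divide(diff, hi, out=np.zeros_like(diff), where=hi > 0)
    return np.log2(ratio + 1.0)


def case_pair_statistics(table: RatingsTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-case sufficient statistics: (sum of kernel terms, pair count).

    Case-level resampling only ever re-weights whole cases, so these two
    arrays are all the bootstrap needs.
    """
    sums = np.empty(len(table))
    counts = np.empty(len(table), dtype=np.int64)
    for idx, case in enumerate(table):
        terms = _case_kernel_terms(case.values)
        sums[idx] = math.fsum(terms.tolist())
        counts[idx] = terms.size
    return sums, counts


def ibmd(table: RatingsTable) -> DisagreementEstimate:
    """Generalized IBMD point estimate over all within-case observer pairs.

    Cases with fewer than two observations are dropped (they contribute no
    pair) and reported in ``n_cases_dropped``.  The sum of kernel terms is
    accumulated with exact summation (``math.fsum``), so the estimate is
    bit-for-bit invariant to case order and to observation order within a
    case.
    """
    usable, dropped = table.drop_sparse_cases()
    terms: list[float] = []
    n_pairs = 0
    for case in usable:
        t = _case_kernel_terms(case.values)
        terms.extend(t.tolist())
        n_pairs += t.size
    value = math.fsum(terms) / n_pairs
    return DisagreementEstimate(
        ibmd=value,
        n_cases_used=len(usable),
        n_pairs_total=n_pairs,
        n_cases_dropped=dropped,
    )


def ibmd_two_observer(pairs: Sequence[tuple[float, float]]) -> float:
    """Original two-observer IBMD: mean kernel over N paired readings.

    Algebraically the generalized estimator restricted to M_i = 2; kept as a
    separate code path and tested for exact equality against :func:`ibmd`.
    """
    pairs = list(pairs)
    if not pairs:
        raise DataError("no observation pairs supplied")
    return math.fsum(pair_disagreement(x, y) for x, y in pairs) / len(pairs)
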