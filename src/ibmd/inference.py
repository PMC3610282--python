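"""Nonparametric bootstrap inference for IBMD.

The sampling unit is the case: a bootstrap replicate redraws N cases with
replacement (each case carrying its whole observation vector — observers are
never resampled) and recomputes IBMD.  The reported interval is the
percentile CI, i.e. the empirical (alpha/2, 1 - alpha/2) quantiles of the B
replicate values, with linear interpolation between order statistics.  The
point estimate is always the IBMD of the original table, never a bootstrap
mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DisagreementEstimate,
    RatingsTable,
    case_pair_statistics,
    ibmd,
)

__all__ = [
    "BootstrapSettings",
    "GroupComparison",
    "bootstrap_ci",
    "bootstrap_replicates",
    "compare_groups",
]


@dataclass(frozen=True)
class BootstrapSettings:
    """Replication count B, confidence level, and root seed.

    B defaults to 1000, adequate for 90–95% percentile intervals.  A ``None``
    seed draws fresh OS entropy and is therefore not reproducible.
    """

    n_boot: int = 1000
    seed: int | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError(f"n_boot must be >= 1, got {self.n_boot}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")


@dataclass(frozen=True)
class GroupComparison:
    """Two independent-group estimates plus the CI-overlap verdict.

    ``ci_overlap`` is the criterion used to call a significant difference in
    disagreement: disjoint 95% CIs mean significantly different disagreement.
    ``diff_ci_low/high`` is a percentile CI for IBMD_b − IBMD_a formed by
    pairing replicate r of each group's bootstrap — an additional diagnostic
    beyond the overlap verdict.
    """

    estimate_a: DisagreementEstimate
    estimate_b: DisagreementEstimate
    ci_overlap: bool
    diff_ci_low: float
    diff_ci_high: float

    @property
    def significant_difference(self) -> bool:
        return not self.ci_overlap


def bootstrap_replicates(
    table: RatingsTable,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """IBMD values of ``n_boot`` case-level resamples of ``table``.

    ``table`` must already contain only usable (M_i >= 2) cases.  A replicate
    whose resampled cases are all internally constant legally yields 0.
    """
    sums, counts = case_pair_statistics(table)
    n = len(table)
    idx = rng.integers(0, n, size=(n_boot, n))
    return sums[idx].sum(axis=1) / counts[idx].sum(axis=1)


def _percentile_ci(values: np.ndarray, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def bootstrap_ci(
    table: RatingsTable,
    settings: BootstrapSettings | None = None,
    *,
    _rng: np.random.Generator | None = None,
) -> DisagreementEstimate:
    """Point estimate plus percentile bootstrap CI for a single table.

    Identical seed and table give a bit-identical interval.  ``_rng`` lets a
    caller (e.g. :func:`compare_groups`) supply a pre-spawned stream so each
    group's interval is unaffected by the other group.
    """
    settings = settings or BootstrapSettings()
    usable, dropped = table.drop_sparse_cases()
    point = ibmd(usable)
    rng = _rng if _rng is not None else np.random.default_rng(settings.seed)
    reps = bootstrap_replicates(usable, settings.n_boot, rng)
    lo, hi = _percentile_ci(reps, settings.ci_level)
    return DisagreementEstimate(
        ibmd=point.ibmd,
        n_cases_used=point.n_cases_used,
        n_pairs_total=point.n_pairs_total,
        n_cases_dropped=dropped,
        ci_low=lo,
        ci_high=hi,
        ci_level=settings.ci_level,
        n_boot=settings.n_boot,
        seed=settings.seed,
    )


def compare_groups(
    table_a: RatingsTable,
    table_b: RatingsTable,
    settings: BootstrapSettings | None = None,
) -> GroupComparison:
    """Compare observer disagreement between two independent populations.

    Each group is bootstrapped on its own child stream spawned from the one
    root seed, so a group's CI does not depend on the other group's size.
    The difference CI pairs replicate r of group b with replicate r of group
    a and takes percentiles of the B differences.
    """
    settings = settings or BootstrapSettings()
    usable_a, dropped_a = table_a.drop_sparse_cases()
    usable_b, dropped_b = table_b.drop_sparse_cases()
    ratio = len(usable_a) / len(usable_b)
    if ratio > 10 or ratio < 0.1:
        warnings.warn(
            f"group sizes differ by more than an order of magnitude "
            f"({len(usable_a)} vs {len(usable_b)} cases)",
            stacklevel=2,
        )

    child_a, child_b = np.random.SeedSequence(settings.seed).spawn(2)
    rng_a = np.random.default_rng(child_a)
    rng_b = np.random.default_rng(child_b)

    point_a, point_b = ibmd(usable_a), ibmd(usable_b)
    reps_a = bootstrap_replicates(usable_a, settings.n_boot, rng_a)
    reps_b = bootstrap_replicates(usable_b, settings.n_boot, rng_b)

    def _estimate(point, dropped, reps):
        lo, hi = _percentile_ci(reps, settings.ci_level)
        return DisagreementEstimate(
            ibmd=point.ibmd,
            n_cases_used=point.n_cases_used,
            n_pairs_total=point.n_pairs_total,
            n_cases_dropped=dropped,
            ci_low=lo,
            ci_high=hi,
            ci_level=settings.ci_level,
            n_boot=settings.n_boot,
            seed=settings.seed,
        )

    est_a = _estimate(point_a, dropped_a, reps_a)
    est_b = _estimate(point_b, dropped_b, reps_b)
    overlap = est_a.ci_low <= est_b.ci_high and est_b.ci_low <= est_a.ci_high

    alpha = 1.0 - settings.ci_level
    d_lo, d_hi = np.quantile(reps_b - reps_a, [alpha / 2.0, 1.0 - alpha / 2.0])
    return GroupComparison(
        estimate_a=est_a,
        estimate_b=est_b,
        ci_overlap=bool(overlap),
        diff_ci_low=float(d_lo),
        diff_ci_high=float(d_hi),
    )
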