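"""Standard agreement and reliability measures for side-by-side reports.

These are the classical companions to IBMD: the intraclass correlation
coefficient (a reliability measure, sensitive to between-subject trait
variance), Lin's concordance correlation coefficient, and Bland–Altman 95%
limits of agreement.  All three require complete rectangular data (CCC and
limits of agreement additionally require exactly two observers); IBMD is the
only measure in this package that accepts ragged tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DataError, RatingsTable

__all__ = ["ComparatorResult", "icc", "ccc", "limits_of_agreement"]


@dataclass(frozen=True)
class ComparatorResult:
    measure_name: str
    value: float
    extras: dict[str, float] = field(default_factory=dict)


def _rectangular_matrix(table: RatingsTable) -> np.ndarray:
    widths = {c.n_observations for c in table}
    if len(widths) != 1:
        raise DataError(
            "ragged table: ICC needs complete rectangular data; "
            "subset to cases rated by every observer"
        )
    k = widths.pop()
    if k < 2:
        raise DataError("ICC needs at least two observers per case")
    if len(table) < 2:
        raise DataError("ICC needs at least two cases")
    if any(c.observers is not None for c in table.cases):
        labels = {c.observers for c in table.cases}
        if len(labels) != 1:
            raise DataError(
                "cases are rated by different observer sets; "
                "subset to cases rated by every observer"
            )
    return np.vstack([c.values for c in table])


ICC_VARIANT = "ICC(A,1): two-way random effects, absolute agreement, single measures"


def icc(table: RatingsTable) -> ComparatorResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    This is the agreement-appropriate variant (raters are a random sample
    and systematic rater bias counts as disagreement).  Requires complete
    rectangular data.
    """
    data = _rectangular_matrix(table)
    n, k = data.shape

    import pandas as pd
    import pingouin as pg

    long = pd.DataFrame(
        {
            "case": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": data.ravel(),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # perfectly concordant raters zero out MSE; the F statistic divides
        # by it and warns, but the ICC value itself is well defined (1.0)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(
            data=long, targets="case", raters="rater", ratings="score"
        )
    value = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    return ComparatorResult(
        measure_name=ICC_VARIANT,
        value=value,
        extras={"n_cases": float(n), "n_observers": float(k)},
    )


def ccc(x, y) -> ComparatorResult:
    """Lin's concordance correlation coefficient for two observers.

    ``2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with biased (1/N)
    moment estimators, as in Lin's original definition.  Penalizes both
    scatter around the best-fit line and its deviation from the identity
    line through the origin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("CCC needs two equal-length one-dimensional sequences")
    if x.size < 2:
        raise DataError("CCC needs at least two paired observations")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise DataError(
            "CCC undefined: both sequences constant with equal means"
        )
    value = 2.0 * sxy / denom
    return ComparatorResult(
        measure_name="CCC (Lin's concordance correlation coefficient)",
        value=value,
        extras={"mean_x": float(mx), "mean_y": float(my)},
    )


def limits_of_agreement(x, y) -> ComparatorResult:
    """Bland–Altman bias and 95% limits of agreement for two observers.

    bias = mean(x - y); limits = bias ± 1.96 * sd(x - y) with the sample
    (n − 1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(
            "limits of agreement need two equal-length one-dimensional sequences"
        )
    if x.size < 2:
        raise DataError("limits of agreement need at least two paired observations")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return ComparatorResult(
        measure_name="Bland-Altman 95% limits of agreement",
        value=bias,
        extras={
            "bias": bias,
            "sd_diff": sd,
            "loa_low": bias - 1.96 * sd,
            "loa_high": bias + 1.96 * sd,
        },
    )
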