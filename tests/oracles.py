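"""Independently coded brute-force oracles used only by the tests.

Each oracle re-derives a quantity from its textbook definition with plain
Python loops, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_pair_kernel(a: float, b: float) -> float:
    if a == b == 0:
        return 0.0
    return math.log(abs(a - b) / max(a, b) + 1.0, 2)


def naive_ibmd(rows) -> float:
    """Double-loop IBMD over per-case value sequences."""
    num = 0.0
    den = 0
    for row in rows:
        for a, b in itertools.combinations(row, 2):
            num += naive_pair_kernel(a, b)
            den += 1
    return num / den


def naive_bootstrap_quantiles(rows, n_boot, seed, level=0.95):
    """Resample-loop percentile CI driven by the same random stream the
    package consumes (one (B, N) block of case indices)."""
    rows = [list(r) for r in rows]
    n = len(rows)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = [naive_ibmd([rows[i] for i in draw]) for draw in idx]
    alpha = 1.0 - level
    return tuple(np.quantile(reps, [alpha / 2, 1 - alpha / 2]).tolist())


def anova_icc_a1(data) -> float:
    """ICC two-way random, absolute agreement, single measures, from the
    classical mean-squares decomposition of an n x k complete table."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def moment_ccc(x, y) -> float:
    """Lin's CCC from raw 1/N moments."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)
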