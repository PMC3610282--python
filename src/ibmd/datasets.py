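"""Packaged example datasets and a synthetic rating-table generator.

Two small studies ship with the package:

* ``load_gymnasts`` — 40 gymnastics performances scored 0–10 by the same
  eight judges, 20 under an old rulebook and 20 under a new one; used to ask
  whether the new scoring system raised inter-judge disagreement.
* ``load_maternal_hr`` — maternal heart-rate baseline estimates (bpm) for 26
  one-hour cardiotocography segments (13 mothers, initial and last hour of
  labor), each read independently by three obstetricians.

The packaged CSVs carry recorded SHA-256 digests, verified at load time, so
a silent edit of the transcriptions cannot go unnoticed.

The synthetic generator draws a true value per case and multiplies
independent log-normal observer errors onto it — the natural error model for
a ratio-scale measure, and one under which the resulting table's IBMD is
invariant to the unit of measurement.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import CaseRecord, DataError, RatingsTable

__all__ = [
    "SyntheticConfig",
    "load_gymnasts",
    "load_maternal_hr",
    "simulate_ratings",
    "fixture_path",
]

_DIGESTS = {
    "gymnasts.csv": "1eaa77eeaf537dfa36bba281ecc7491a9e5667b0da9c5572665dfbfc5b4cb2c6",
    "maternal_hr.csv": "9278b72a0534e02dcfa36b5a78e564a4f0fc51a21f8f4a0ae0be5f5d74842058",
}


def fixture_path(name: str):
    """Traversable handle on a packaged dataset file."""
    if name not in _DIGESTS:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(_DIGESTS)}")
    return resources.files("ibmd.data").joinpath(name)


def _load_checked(name: str, group_column: str) -> RatingsTable:
    ref = fixture_path(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _DIGESTS[name]:
        raise DataError(
            f"packaged dataset {name} fails its integrity check "
            f"(sha256 {digest}); the transcription has been altered"
        )
    with ref.open("r") as handle:
        frame = pd.read_csv(handle)
    return RatingsTable.from_wide(frame, group_column=group_column)


def load_gymnasts() -> RatingsTable:
    """40 gymnasts x 8 judges with rulebook group labels ('old'/'new')."""
    return _load_checked("gymnasts.csv", group_column="rulebook")


def load_maternal_hr() -> RatingsTable:
    """26 labor segments x 3 obstetricians, grouped 'initial'/'last' hour."""
    return _load_checked("maternal_hr.csv", group_column="segment")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic rating-table generator.

    Defaults describe a small observer-agreement study on a physiological
    scale: 30 cases read by 3 observers, true values on the maternal
    heart-rate baseline range 60–110 bpm, and a 10% multiplicative observer
    error (log-normal with sigma = 0.1), no missingness.
    """

    n_cases: int = 30
    observers_per_case: int | tuple[int, int] = 3
    true_value_range: tuple[float, float] = (60.0, 110.0)
    noise_scale: float = 0.1
    missing_rate: float = 0.0
    seed: int | None = None
    noise_model: str = "lognormal"

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        low, high = self.true_value_range
        if not (0 < low <= high):
            raise ValueError(f"invalid true_value_range {self.true_value_range}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        m = self.observers_per_case
        lo_m = m if isinstance(m, int) else m[0]
        if lo_m < 2:
            raise ValueError("observers_per_case must allow at least 2 observers")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def simulate_ratings(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> RatingsTable:
    """Draw a synthetic ratings table from ``config``.

    Per case i a true value t_i is uniform on ``true_value_range``; observer
    j reports ``t_i * exp(eps_ij)`` with eps_ij ~ Normal(0, noise_scale^2)
    (the default log-normal model), or ``max(t_i + eps_ij, 0)`` with
    eps_ij ~ Normal(0, noise_scale^2) under the additive model used for
    comparator demonstrations.  Each observation is then dropped
    independently with probability ``missing_rate``; a case left with fewer
    than two observations is redrawn, so every generated case is usable.
    A fixed seed yields an identical table.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    low, high = config.true_value_range
    m_setting = config.observers_per_case

    cases = []
    for i in range(config.n_cases):
        while True:
            m = (
                m_setting
                if isinstance(m_setting, int)
                else int(rng.integers(m_setting[0], m_setting[1] + 1))
            )
            truth = rng.uniform(low, high)
            eps = rng.normal(0.0, config.noise_scale, size=m)
            if config.noise_model == "lognormal":
                values = truth * np.exp(eps)
            else:
                values = np.maximum(truth + eps, 0.0)
            if config.missing_rate > 0:
                keep = rng.random(m) >= config.missing_rate
                values = values[keep]
            if values.size >= 2:
                break
        cases.append(CaseRecord(case_id=str(i + 1), values=values))
    return RatingsTable(cases)
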