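"""Between-year reliability (RMSE / nRMSE) and trait-index association.

Reliability of an index is graded by the normalised root-mean-square
difference between paired per-cultivar values from two trial years:

    RMSE  = sqrt( (1/n) * sum_i (X_second,i - X_first,i)^2 )
    nRMSE = 100 * RMSE / mean_i(X_first,i)      [percent]

with the conventional agronomic grading: excellent < 10%, good 10-20%,
acceptable 20-30%, poor >= 30%. Censored failure wind speeds "> S_m" enter
as the value S_m — the only convention under which a cultivar that never
lodged in either year contributes a zero difference; note this biases RMSE
downward. Cultivars tested in only one year are excluded pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import TRAIT_CODES, TRAIT_NAMES, FWSResult, TraitRecord, ValidationError

__all__ = [
    "PairedYearTable",
    "ReliabilityReport",
    "rmse",
    "nrmse",
    "evaluate_reliability",
    "reliability_grade",
    "pearson_correlation",
    "correlation_matrix",
]

logger = logging.getLogger(__name__)

IndexValue = Union[float, FWSResult]


def _as_number(x: IndexValue) -> float:
    return x.as_number() if isinstance(x, FWSResult) else float(x)


@dataclass(frozen=True)
class PairedYearTable:
    """Per-cultivar index values paired across two years, censoring resolved.

    Build with :meth:`from_values`, which accepts plain floats or
    :class:`FWSResult` (censored results map to their machine maximum) and
    drops cultivars missing either year.
    """

    cultivars: tuple[str, ...]
    x_first: tuple[float, ...]
    x_second: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.cultivars) == len(self.x_first) == len(self.x_second)):
            raise ValidationError("paired table columns must have equal length")
        if len(self.cultivars) < 1:
            raise ValidationError("at least one complete pair is required")

    @property
    def n(self) -> int:
        return len(self.cultivars)

    @classmethod
    def from_values(
        cls,
        first: Mapping[str, IndexValue],
        second: Mapping[str, IndexValue],
    ) -> "PairedYearTable":
        common = [c for c in first if c in second]
        dropped = sorted(set(first) ^ set(second))
        if dropped:
            logger.warning("excluding cultivars missing a year: %s", dropped)
        if not common:
            raise ValidationError("no cultivar has values in both years")
        return cls(
            cultivars=tuple(common),
            x_first=tuple(_as_number(first[c]) for c in common),
            x_second=tuple(_as_number(second[c]) for c in common),
        )


@dataclass(frozen=True)
class ReliabilityReport:
    """RMSE/nRMSE of one index across two years, with its grade."""

    pairs: PairedYearTable
    rmse: float
    nrmse: float  # percent
    grade: str


def rmse(pairs: PairedYearTable) -> float:
    """Root mean squared between-year difference over the complete pairs."""
    a = np.asarray(pairs.x_first, dtype=float)
    b = np.asarray(pairs.x_second, dtype=float)
    return float(np.sqrt(np.mean((b - a) ** 2)))


def nrmse(pairs: PairedYearTable) -> float:
    """RMSE normalised by the first-year mean, in percent."""
    mean_first = float(np.mean(pairs.x_first))
    if mean_first <= 0:
        raise ValidationError(f"first-year mean must be > 0, got {mean_first}")
    return 100.0 * rmse(pairs) / mean_first


def reliability_grade(nrmse_percent: float) -> str:
    """Grade an nRMSE (percent): excellent <10, good 10-20, acceptable 20-30, poor >=30."""
    if nrmse_percent < 0:
        raise ValidationError(f"nRMSE must be >= 0, got {nrmse_percent}")
    if nrmse_percent < 10:
        return "excellent"
    if nrmse_percent < 20:
        return "good"
    if nrmse_percent < 30:
        return "acceptable"
    return "poor"


def evaluate_reliability(pairs: PairedYearTable) -> ReliabilityReport:
    value_rmse = rmse(pairs)
    value_nrmse = nrmse(pairs)
    return ReliabilityReport(
        pairs=pairs,
        rmse=value_rmse,
        nrmse=value_nrmse,
        grade=reliability_grade(value_nrmse),
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson r; requires n >= 3 and nonzero variance in both vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in an input vector")
    return float(stats.pearsonr(x, y).statistic)


def correlation_matrix(
    traits: Sequence[TraitRecord], cli: Mapping[str, float]
) -> pd.DataFrame:
    """Pairwise Pearson matrix over cultivar means for CLI and every trait.

    Cultivars missing the CLI or any trait mean are dropped with a warning.
    Rows/columns are labelled CLI plus the short trait codes (YM, MBL, ...).
    """
    complete = [
        t for t in traits
        if t.cultivar in cli and all(name in t.means for name in TRAIT_NAMES)
    ]
    dropped = [t.cultivar for t in traits if t not in complete]
    if dropped:
        logger.warning("dropping cultivars with incomplete rows: %s", dropped)
    if len(complete) < 3:
        raise ValidationError(f"need >= 3 complete cultivars, got {len(complete)}")

    data = {"CLI": [cli[t.cultivar] for t in complete]}
    for name in TRAIT_NAMES:
        data[TRAIT_CODES[name]] = [t.means[name] for t in complete]
    frame = pd.DataFrame(data, index=[t.cultivar for t in complete])
    return frame.corr(method="pearson")
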