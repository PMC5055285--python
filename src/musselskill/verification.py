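"""Categorical forecast-verification statistics for body-temperature predictions.

Daily-maximum forecast/observation pairs are binned into ordered
thermal-performance categories and tallied into a k x k contingency table
(rows = forecast category, columns = observed category). From the table we
compute per-category hit rate and false-alarm ratio and the multicategory
Heidke, Peirce and Gerrity skill scores, alongside bias / MAE / RMSE of the
raw daily maxima. All three overall scores equal 1 for a perfect forecast
and 0 for an unskilled one; the Gerrity score is equitable, so any constant
forecast scores exactly 0.

Undefined quantities (e.g. the false-alarm ratio of a never-forecast
category) are carried as NaN, never as 0, and rendered "NA" in outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import daily_max_pairs

#: Default thermal-performance category labels, coldest to hottest.
DEFAULT_LABELS = (
    "low lethal",
    "low sub-lethal",
    "low sub-optimal",
    "optimal",
    "high sub-optimal",
    "high sub-lethal",
    "high lethal",
)

#: Default category thresholds (deg C). Bins are lower-inclusive,
#: upper-exclusive: (-inf,0), [0,10), [10,17), [17,22), [22,32), [32,38), [38,inf).
DEFAULT_BOUNDS = (0.0, 10.0, 17.0, 22.0, 32.0, 38.0)


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered thermal-performance categories with temperature bounds."""

    labels: tuple = DEFAULT_LABELS
    bounds: tuple = DEFAULT_BOUNDS

    def __post_init__(self):
        b = np.asarray(self.bounds, dtype=float)
        if len(b) < 1 or not np.all(np.diff(b) > 0):
            raise ValueError("bounds must be strictly increasing")
        if len(self.labels) != len(b) + 1:
            raise ValueError("need one more label than bounds")

    @property
    def k(self) -> int:
        return len(self.labels)

    def categorize(self, temp):
        """Category index for a temperature; lower-inclusive, upper-exclusive bins."""
        arr = np.asarray(temp, dtype=float)
        if np.any(~np.isfinite(arr)):
            raise ValueError("cannot categorize non-finite temperatures")
        idx = np.searchsorted(np.asarray(self.bounds, dtype=float), arr, side="right")
        return int(idx) if np.isscalar(temp) or arr.ndim == 0 else idx


def categorize(temp, scheme: CategoryScheme):
    """Module-level alias for :meth:`CategoryScheme.categorize`."""
    return scheme.categorize(temp)


@dataclass(frozen=True)
class ContingencyTable:
    """k x k counts of daily-maximum categories: rows forecast, columns observed."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def forecast_marginal(self) -> np.ndarray:
        """n(F_i): row sums."""
        return self.counts.sum(axis=1)

    @property
    def observed_marginal(self) -> np.ndarray:
        """n(O_i): column sums."""
        return self.counts.sum(axis=0)

    def to_dataframe(self, scheme: CategoryScheme | None = None) -> pd.DataFrame:
        labels = scheme.labels if scheme is not None else list(range(self.k))
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def build_table(pairs: pd.DataFrame, scheme: CategoryScheme) -> ContingencyTable:
    """Tally daily-max pairs into a contingency table."""
    k = scheme.k
    counts = np.zeros((k, k), dtype=np.int64)
    if len(pairs):
        fi = scheme.categorize(pairs["forecast_max"].to_numpy())
        oj = scheme.categorize(pairs["observed_max"].to_numpy())
        np.add.at(counts, (fi, oj), 1)
    return ContingencyTable(counts)


def error_summaries(pairs: pd.DataFrame) -> tuple[float, float, float]:
    """(bias, MAE, RMSE) of daily maxima; bias = mean(forecast - observed)."""
    if len(pairs) == 0:
        raise ValueError("error summaries require at least one pair")
    diff = pairs["forecast_max"].to_numpy(dtype=float) - pairs["observed_max"].to_numpy(dtype=float)
    return float(diff.mean()), float(np.abs(diff).mean()), float(np.sqrt((diff**2).mean()))


def hit_rate(table: ContingencyTable, i: int) -> float:
    """Hits / (hits + misses) for category i; NaN when category i was never observed."""
    observed = table.observed_marginal[i]
    if observed == 0:
        return float("nan")
    return float(table.counts[i, i] / observed)


def false_alarm_ratio(table: ContingencyTable, i: int) -> float:
    """False alarms / (hits + false alarms) for category i; NaN when never forecast."""
    forecast = table.forecast_marginal[i]
    if forecast == 0:
        return float("nan")
    return float((forecast - table.counts[i, i]) / forecast)


def _proportions(table: ContingencyTable):
    n = table.n
    if n == 0:
        raise ValueError("skill scores require a non-empty table")
    pc = table.counts.trace() / n
    f = table.forecast_marginal / n
    o = table.observed_marginal / n
    return pc, f, o


def heidke(table: ContingencyTable) -> float:
    """Multicategory Heidke skill score.

    Proportion correct relative to the chance expectation from the forecast
    and observed marginals; 1 = perfect, 0 = no skill. NaN when the chance
    expectation is already 1 (all mass in one diagonal cell).
    """
    pc, f, o = _proportions(table)
    expected = float(np.dot(f, o))
    if expected == 1.0:
        return float("nan")
    return float((pc - expected) / (1.0 - expected))


def peirce(table: ContingencyTable) -> float:
    """Multicategory Peirce skill score (hit rate minus false-alarm rate).

    Same numerator as the Heidke score but referenced to an unbiased random
    forecast: the denominator uses the observed marginal only.
    """
    pc, f, o = _proportions(table)
    expected = float(np.dot(f, o))
    denom = 1.0 - float(np.dot(o, o))
    if denom == 0.0:
        return float("nan")
    return float((pc - expected) / denom)


@dataclass(frozen=True)
class GerrityMatrix:
    """Observed frequencies p, odds ratios a and the equitable scoring matrix s."""

    p: np.ndarray
    a: np.ndarray
    s: np.ndarray


class GerrityUndefinedError(ValueError):
    """Raised when empty observed categories make the Gerrity odds ratios undefined."""


def gerrity_matrix(table: ContingencyTable) -> GerrityMatrix:
    """Build the Gerrity equitable scoring matrix from the observed marginal.

    p_i = n(O_i)/N; a_i = (1 - sum_{r<=i} p_r) / sum_{r<=i} p_r for
    i = 1..k-1; the diagonal and off-diagonal elements of s combine partial
    sums of a and 1/a so that every row satisfies sum_j p_j s_ij = 0
    (equitability) and a perfect forecast scores 1.
    """
    _, _, p = _proportions(table)
    k = table.k
    cum = np.cumsum(p)[:-1]  # leading cumulative sums, i = 1..k-1
    if np.any(cum <= 0.0) or np.any(cum >= 1.0):
        raise GerrityUndefinedError(
            "observed categories with zero cumulative mass make the Gerrity "
            "odds ratios undefined; collapse empty leading/trailing categories "
            "before scoring"
        )
    a = (1.0 - cum) / cum
    inv = 1.0 / a
    s = np.zeros((k, k), dtype=float)
    denom = k - 1
    for i in range(k):
        for j in range(i, k):
            if i == j:
                s[i, j] = (inv[:i].sum() + a[i:].sum()) / denom
            else:
                s[i, j] = (inv[:i].sum() - (j - i) + a[j:].sum()) / denom
                s[j, i] = s[i, j]
    return GerrityMatrix(p=p, a=a, s=s)


def gerrity(table: ContingencyTable) -> float:
    """Gerrity skill score: (1/N) sum_ij n(F_i O_j) s_ij."""
    gm = gerrity_matrix(table)
    return float((table.counts * gm.s).sum() / table.n)


@dataclass
class SkillReport:
    """Error summaries and verification scores for one (forecast, observation) pairing."""

    bias: float
    mae: float
    rmse: float
    hit_rate: np.ndarray
    false_alarm_ratio: np.ndarray
    heidke: float
    peirce: float
    gerrity: float
    n_days: int
    table: ContingencyTable = field(repr=False)

    def to_row(self, scheme: CategoryScheme) -> dict:
        """Flatten to a dict suitable for a tabular report (NaN renders as NA in CSV)."""
        row = {
            "n_days": self.n_days,
            "bias": self.bias,
            "mae": self.mae,
            "rmse": self.rmse,
            "heidke": self.heidke,
            "peirce": self.peirce,
            "gerrity": self.gerrity,
        }
        for i in range(scheme.k):
            row[f"hit_rate_{i}"] = self.hit_rate[i]
            row[f"far_{i}"] = self.false_alarm_ratio[i]
        return row


def skill_report(pairs: pd.DataFrame, scheme: CategoryScheme) -> SkillReport:
    """Full skill report for a set of daily-max pairs.

    The Gerrity score is reported as NaN (not an error) when empty observed
    categories leave it undefined, matching the way such cases appear as NA
    in site-level summary tables.
    """
    bias, mae, rmse = error_summaries(pairs)
    table = build_table(pairs, scheme)
    hr = np.array([hit_rate(table, i) for i in range(scheme.k)])
    far = np.array([false_alarm_ratio(table, i) for i in range(scheme.k)])
    try:
        ger = gerrity(table)
    except GerrityUndefinedError:
        ger = float("nan")
    return SkillReport(
        bias=bias,
        mae=mae,
        rmse=rmse,
        hit_rate=hr,
        false_alarm_ratio=far,
        heidke=heidke(table),
        peirce=peirce(table),
        gerrity=ger,
        n_days=int(len(pairs)),
        table=table,
    )


def interlogger_baseline(
    loggers: dict[str, pd.Series],
    mask: pd.Series,
    scheme: CategoryScheme,
    utc_offset: float = 0.0,
) -> pd.DataFrame:
    """Score every ordered logger pair as a forecast/observation pairing.

    One logger's hourly record is treated as the "forecast" and another's as
    the "observations"; the resulting spread of scores is the field
    variability benchmark against which model skill is judged.
    """
    if len(loggers) < 2:
        raise ValueError("interlogger baseline requires at least 2 loggers")
    rows = []
    for fid, oid in itertools.permutations(sorted(loggers), 2):
        pairs = daily_max_pairs(loggers[fid], loggers[oid], mask, utc_offset)
        if len(pairs) == 0:
            continue
        report = skill_report(pairs, scheme)
        row = {"forecast_id": fid, "observed_id": oid}
        row.update(report.to_row(scheme))
        rows.append(row)
    return pd.DataFrame(rows)
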