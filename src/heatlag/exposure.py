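"""Population-weighted exposure aggregation and temperature summaries.

Multi-station daily temperature records are collapsed into a single daily
series by averaging across stations with weights proportional to the
population each station represents.  The summary derives the reference value
(the series median), the 90th/95th/99th percentiles and the series maximum,
plus the integer evaluation grid: percentiles are rounded *up* (they lie
inside the recorded range by construction) while the maximum is rounded
*down* so the integer cannot fall outside the recorded range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExposureSeries",
    "TemperatureSummary",
    "normalize_weights",
    "weighted_spatial_average",
    "summarize_temperature",
]

METRICS = ("mean", "max", "min")


@dataclass
class ExposureSeries:
    """One daily temperature value per calendar date for one metric.

    ``values`` is indexed by a gap-free daily DatetimeIndex; days where no
    station reported are explicit NaN.
    """

    metric: str
    values: pd.Series

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("ExposureSeries requires a DatetimeIndex")
        if len(idx) > 1:
            if not idx.is_monotonic_increasing or idx.has_duplicates:
                raise ValueError("dates must be strictly increasing")
            full = pd.date_range(idx[0], idx[-1], freq="D")
            if len(full) != len(idx):
                # re-index onto the gap-free daily range; missing days -> NaN
                self.values = self.values.reindex(full)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.values.index

    def dropna(self) -> np.ndarray:
        return self.values.dropna().to_numpy()

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TemperatureSummary:
    """Reference temperature, upper percentiles and integer evaluation grid."""

    metric: str
    reference: float
    p90: float
    p95: float
    p99: float
    upper_limit: float
    grid_values: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.reference <= self.p90 <= self.p95 <= self.p99 <= self.upper_limit):
            raise ValueError("percentile ordering violated")


def normalize_weights(raw: dict[str, float]) -> dict[str, float]:
    """Scale station weights (raw populations or shares) to sum to one."""
    if not raw:
        raise ValueError("no weights supplied")
    vals = np.array(list(raw.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError("weights must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    return {k: float(v) / total for k, v in raw.items()}


def weighted_spatial_average(
    stations: pd.DataFrame,
    weights: dict[str, float],
    metric: str = "mean",
) -> ExposureSeries:
    """Collapse station records into one population-weighted daily series.

    ``stations`` must have columns ``station_id``, ``date`` and ``t_<metric>``.
    On days where only a subset of stations report, the weights are
    renormalized over the reporting stations.  Days with no report at all are
    missing (NaN) in the output.
    """
    col = f"t_{metric}"
    if col not in stations.columns:
        raise KeyError(f"metric column {col!r} absent from station records")
    present = set(stations["station_id"].unique()) & set(weights)
    if not present:
        raise ValueError("no station in the weight table appears in the records")
    w = normalize_weights({k: v for k, v in weights.items() if k in present})

    df = stations.loc[stations["station_id"].isin(present), ["station_id", "date", col]].copy()
    df["date"] = pd.to_datetime(df["date"])
    if df.duplicated(["station_id", "date"]).any():
        raise ValueError("duplicate (station, date) records")
    wide = df.pivot(index="date", columns="station_id", values=col).sort_index()
    wvec = pd.Series(w).reindex(wide.columns).to_numpy()
    vals = wide.to_numpy(dtype=float)
    mask = np.isfinite(vals)
    num = np.nansum(vals * wvec, axis=1)
    den = (mask * wvec).sum(axis=1)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    series = pd.Series(out, index=wide.index, name=col)
    return ExposureSeries(metric=metric, values=series)


def summarize_temperature(series: ExposureSeries) -> TemperatureSummary:
    """Reference (median), upper percentiles, maximum and the integer grid.

    Percentiles use linear interpolation between order statistics (the
    ubiquitous "type 7" definition); the median of an even-length series is
    the mean of the two central order statistics.
    """
    x = series.dropna()
    if x.size < 2:
        raise ValueError("need at least two non-missing values")
    p90, p95, p99 = np.percentile(x, [90, 95, 99])
    summary = TemperatureSummary(
        metric=series.metric,
        reference=float(np.median(x)),
        p90=float(p90),
        p95=float(p95),
        p99=float(p99),
        upper_limit=float(x.max()),
    )
    summary.grid_values = {
        "p90": math.ceil(summary.p90),
        "p95": math.ceil(summary.p95),
        "p99": math.ceil(summary.p99),
        "upper_limit": math.floor(summary.upper_limit),
    }
    return summary
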