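"""Reading and writing the standard text tables.

All tables are comma-separated with a header row and ISO-8601 dates:

* station temperatures: ``station_id,date,t_min,t_max,t_mean``
* population weights: ``station_id,weight``
* mortality counts (long): ``date,category,count``
* fit artifacts: JSON (coefficients, covariance, metadata)
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crossbasis import CrossBasisSpec
from .exposure import ExposureSeries, TemperatureSummary
from .model import FitResult
from .mortality import MortalitySeries

__all__ = [
    "write_station_table", "read_station_table",
    "write_weights", "read_weights",
    "write_mortality", "read_mortality",
    "write_exposure", "read_exposure",
    "write_summary", "write_fit", "read_fit", "write_truth",
]

STATION_COLUMNS = ["station_id", "date", "t_min", "t_max", "t_mean"]


def write_station_table(stations: pd.DataFrame, path) -> None:
    out = stations[STATION_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.4f")


def read_station_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = set(STATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"station table missing required columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    if df.duplicated(["station_id", "date"]).any():
        raise ValueError("duplicate (station, date) rows in station table")
    # reject physically inconsistent rows but keep the run going
    bad = (df["t_min"] > df["t_mean"]) | (df["t_mean"] > df["t_max"])
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} station rows with t_min > t_mean "
                      f"or t_mean > t_max", UserWarning)
        df = df[~bad]
    return df.reset_index(drop=True)


def write_weights(weights: dict[str, float], path) -> None:
    pd.DataFrame({"station_id": list(weights), "weight": list(weights.values())}
                 ).to_csv(path, index=False)


def read_weights(path) -> dict[str, float]:
    df = pd.read_csv(path, dtype={"station_id": str})
    if not {"station_id", "weight"} <= set(df.columns):
        raise ValueError("weights table must have columns station_id, weight")
    return dict(zip(df["station_id"], df["weight"].astype(float)))


def write_mortality(series: MortalitySeries, path) -> None:
    long = series.counts.stack().rename("count").reset_index()
    long.columns = ["date", "category", "count"]
    long["date"] = long["date"].dt.strftime("%Y-%m-%d")
    long.to_csv(path, index=False)


def read_mortality(path) -> MortalitySeries:
    df = pd.read_csv(path, dtype={"category": str})
    if df.empty:
        raise ValueError("mortality table is empty")
    if not {"date", "category", "count"} <= set(df.columns):
        raise ValueError("mortality table must have columns date, category, count")
    df["date"] = pd.to_datetime(df["date"])
    wide = df.pivot(index="date", columns="category", values="count").sort_index()
    if wide.isna().any().any():
        raise ValueError("mortality table has missing (date, category) cells")
    return MortalitySeries(wide)


def write_exposure(series: ExposureSeries, path) -> None:
    out = pd.DataFrame({
        "date": series.dates.strftime("%Y-%m-%d"),
        f"t_{series.metric}": series.values.to_numpy(),
    })
    out.to_csv(path, index=False, float_format="%.4f")


def read_exposure(path, metric: str) -> ExposureSeries:
    df = pd.read_csv(path)
    col = f"t_{metric}"
    if col not in df.columns:
        raise ValueError(f"exposure table missing column {col!r}")
    values = pd.Series(df[col].to_numpy(), index=pd.to_datetime(df["date"]))
    return ExposureSeries(metric=metric, values=values)


def write_summary(summary: TemperatureSummary, path) -> None:
    data = {
        "metric": summary.metric,
        "reference": summary.reference,
        "p90": summary.p90, "p95": summary.p95, "p99": summary.p99,
        "upper_limit": summary.upper_limit,
        "grid_values": {k: int(v) for k, v in summary.grid_values.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_fit(fit: FitResult, path) -> None:
    spec = fit.spec
    data = {
        "params": {k: float(v) for k, v in fit.params.items()},
        "cov": fit.cov.to_numpy().tolist(),
        "param_names": list(fit.params.index),
        "dispersion": fit.dispersion, "loglike": fit.loglike,
        "k": fit.k, "n": fit.n, "qaic": fit.qaic, "qbic": fit.qbic,
        "converged": fit.converged, "design": fit.design, "meta": fit.meta,
        "spec": None if spec is None else {
            "max_lag": spec.max_lag, "var_df": spec.var_df,
            "var_degree": spec.var_degree, "var_knots": list(spec.var_knots),
            "var_boundary": list(spec.var_boundary), "lag_df": spec.lag_df,
            "lag_knot_spacing": spec.lag_knot_spacing,
        },
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_fit(path) -> FitResult:
    data = json.loads(Path(path).read_text())
    names = data["param_names"]
    spec = None
    if data["spec"] is not None:
        s = data["spec"]
        spec = CrossBasisSpec(max_lag=s["max_lag"], var_df=s["var_df"],
                              var_degree=s["var_degree"],
                              var_knots=tuple(s["var_knots"]),
                              var_boundary=tuple(s["var_boundary"]),
                              lag_df=s["lag_df"],
                              lag_knot_spacing=s["lag_knot_spacing"])
    return FitResult(
        params=pd.Series([data["params"][k] for k in names], index=names),
        cov=pd.DataFrame(np.array(data["cov"]), index=names, columns=names),
        dispersion=data["dispersion"], loglike=data["loglike"],
        k=data["k"], n=data["n"], qaic=data["qaic"], qbic=data["qbic"],
        converged=data["converged"], spec=spec, design=data["design"],
        meta=data["meta"],
    )


def write_truth(config, path) -> None:
    """Key-value record of the generator parameters and seed."""
    surf = config.true_surface
    data = {
        "seed": config.seed,
        "n_years": config.n_years,
        "n_stations": config.n_stations,
        "baseline_daily_deaths": config.baseline_daily_deaths,
        "dow_log_effects": list(config.dow_log_effects),
        "seasonal_log_amplitude": config.seasonal_log_amplitude,
        "overdispersion": config.overdispersion,
        "climate_mean_annual": config.climate_mean_annual,
        "climate_seasonal_amplitude": config.climate_seasonal_amplitude,
        "surface_form": surf.form,
        "surface_reference": surf.reference,
        "surface_lag_coefs": surf.lag_coefs.tolist(),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
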