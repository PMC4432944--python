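"""End-to-end study orchestration.

``run_study`` takes an :class:`AnalysisConfig`, ingests (or generates) the
three input tables, aggregates station temperatures into population-weighted
series, fits the case-crossover DLNM per metric and per ICD-10 category,
optionally runs the degrees-of-freedom grid search, predicts relative-risk
surfaces and slices, and writes every artifact as delimiter-separated text
under the output directory together with a run log of all resolved defaults.
``run_sensitivity`` refits the aggregated model under alternative maximum
lags and stratum window lengths, one factor at a time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .crossbasis import CrossBasisSpec, build_crossbasis
from .exposure import (TemperatureSummary, normalize_weights,
                       summarize_temperature, weighted_spatial_average)
from .model import (FitResult, fit_quasipoisson,
                    make_strata, select_df)
from .prediction import (cumulative_rr, lag_slice, predict_rr,
                         temperature_slice)
from .synthetic import (SyntheticConfig, simulate_mortality,
                        simulate_station_temperatures)

__all__ = ["AnalysisConfig", "run_study", "run_sensitivity", "ingest_tables"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Resolved configuration of one study run."""

    stations_path: str | None = None
    weights_path: str | None = None
    mortality_path: str | None = None
    synthetic: SyntheticConfig | None = None

    metrics: tuple[str, ...] = ("mean", "max", "min")
    categories: tuple[str, ...] | None = None  # None -> all in the table
    fit_aggregate: bool = True
    fit_categories: bool = True

    max_lag: int = 10
    var_df: int = 4
    lag_df: int = 4
    lag_knot_spacing: str = "log"
    strata_scheme: str = "calendar_month"
    dow_terms: bool = True

    run_df_selection: bool = False
    df_grid: tuple[int, ...] = (4, 5, 6)

    sensitivity_max_lags: tuple[int, ...] = (5, 15, 20)
    sensitivity_windows: tuple[int, ...] = (30, 28, 21)

    temperature_slice_lags: tuple[int, ...] = (0, 1, 2, 4)
    make_figures: bool = True
    output_dir: str = "heatlag_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError("metrics must be non-empty")
        if self.max_lag < 1 or any(l < 1 for l in self.sensitivity_max_lags):
            raise ValueError("all maximum lags must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if syn is not None:
            from .synthetic import LogRRSurface
            surf = syn.pop("true_surface", None)
            if surf is not None:
                syn["true_surface"] = LogRRSurface(
                    surf["form"], surf["reference"], np.asarray(surf["lag_coefs"]))
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


def ingest_tables(stations_path, weights_path, mortality_path):
    """Read and validate the three input tables."""
    stations = hio.read_station_table(stations_path)
    weights = normalize_weights(hio.read_weights(weights_path))
    mortality = hio.read_mortality(mortality_path)
    return stations, weights, mortality


def _evaluation_grid(summary: TemperatureSummary) -> np.ndarray:
    lo = summary.reference  # risks are reported above the reference
    hi = summary.upper_limit
    grid = np.round(np.arange(np.floor(lo * 10), np.ceil(hi * 10) + 1) / 10.0, 1)
    extra = np.array(sorted(set(summary.grid_values.values())), dtype=float)
    return np.unique(np.concatenate([grid, extra]))


def _load_inputs(config: AnalysisConfig, outdir: Path):
    if config.synthetic is not None:
        syn = config.synthetic
        stations = simulate_station_temperatures(syn)
        weights = syn.weights()
        exposure_mean = weighted_spatial_average(stations, weights, "mean")
        mortality, truth = simulate_mortality(exposure_mean, syn)
        hio.write_station_table(stations, outdir / "stations.csv")
        hio.write_weights(weights, outdir / "weights.csv")
        hio.write_mortality(mortality, outdir / "mortality.csv")
        hio.write_truth(syn, outdir / "truth.yaml")
        return stations, weights, mortality, truth
    if not (config.stations_path and config.weights_path and config.mortality_path):
        raise ValueError("either synthetic block or all three input paths required")
    stations, weights, mortality = ingest_tables(
        config.stations_path, config.weights_path, config.mortality_path)
    return stations, weights, mortality, None


def _spec(config: AnalysisConfig) -> CrossBasisSpec:
    return CrossBasisSpec(max_lag=config.max_lag, var_df=config.var_df,
                          lag_df=config.lag_df,
                          lag_knot_spacing=config.lag_knot_spacing)


def run_study(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns the artifact dictionary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stations, weights, mortality, truth = _load_inputs(config, outdir)

    categories = list(config.categories or mortality.categories)
    missing = set(categories) - set(mortality.categories)
    if missing:
        raise ValueError(f"requested categories absent from mortality table: {sorted(missing)}")

    artifacts: dict = {"config": config, "truth": truth, "mortality": mortality,
                       "fits": {}, "surfaces": {}, "summaries": {},
                       "exposures": {}, "slices": {}, "cumulative": {},
                       "df_selection": None}
    strata = make_strata(mortality.dates, config.strata_scheme)
    y_agg = mortality.aggregate

    for metric in config.metrics:
        exposure = weighted_spatial_average(stations, weights, metric)
        exposure.values = exposure.values.reindex(mortality.dates)
        summary = summarize_temperature(exposure)
        artifacts["exposures"][metric] = exposure
        artifacts["summaries"][metric] = summary
        hio.write_exposure(exposure, outdir / f"exposure_{metric}.csv")
        hio.write_summary(summary, outdir / f"summary_{metric}.yaml")

        cb = build_crossbasis(exposure, _spec(config))
        grid = _evaluation_grid(summary)

        targets = [("aggregate", y_agg)] if config.fit_aggregate else []
        if config.fit_categories and metric == "mean":
            targets += [(cat, mortality.counts[cat]) for cat in categories]

        for name, y in targets:
            fit = fit_quasipoisson(y, cb, strata, config.dow_terms)
            fit.meta["fit_id"] = f"{metric}:{name}"
            surface = predict_rr(fit, cb.spec, grid, summary.reference)
            cum = cumulative_rr(fit, cb.spec, grid, summary.reference)
            artifacts["fits"][(metric, name)] = fit
            artifacts["surfaces"][(metric, name)] = surface
            artifacts["cumulative"][(metric, name)] = cum
            tag = f"{metric}_{name.replace('-', '')}"
            hio.write_fit(fit, outdir / f"fit_{tag}.json")
            surface.frame().to_csv(outdir / f"rr_surface_{tag}.csv", index=False,
                                   float_format="%.6f")
            cum.frame().to_csv(outdir / f"rr_cumulative_{tag}.csv", index=False,
                               float_format="%.6f")
            if name == "aggregate":
                pct_temps = [float(summary.grid_values[k]) for k in ("p90", "p95", "p99")]
                pct_temps.append(float(summary.grid_values["upper_limit"]))
                lslice = lag_slice(surface, pct_temps)
                tslice = temperature_slice(surface, config.temperature_slice_lags)
                artifacts["slices"][(metric, "lag")] = lslice
                artifacts["slices"][(metric, "temperature")] = tslice
                lslice.to_csv(outdir / f"lag_slice_{metric}.csv", index=False,
                              float_format="%.6f")
                tslice.to_csv(outdir / f"temperature_slice_{metric}.csv", index=False,
                              float_format="%.6f")
                if config.make_figures:
                    from . import plots
                    plots.plot_surface_3d(surface, outdir / f"surface_{metric}.png",
                                          f"T_{metric}, aggregate")
                    plots.plot_lag_slices(surface, pct_temps,
                                          outdir / f"lag_slices_{metric}.png",
                                          f"T_{metric}, aggregate")
                    plots.plot_temperature_slices(surface, config.temperature_slice_lags,
                                                  outdir / f"temperature_slices_{metric}.png",
                                                  f"T_{metric}, aggregate")

    if config.run_df_selection:
        exposure = artifacts["exposures"]["mean"]
        best, table = select_df(y_agg, exposure, strata,
                                config.df_grid, config.df_grid,
                                base_spec=_spec(config), dow_terms=config.dow_terms)
        artifacts["df_selection"] = {"best": best, "table": table}
        table.to_csv(outdir / "df_selection.csv", index=False, float_format="%.3f")

    _write_run_log(config, artifacts, outdir)
    return artifacts


def _write_run_log(config: AnalysisConfig, artifacts: dict, outdir: Path) -> None:
    """Record every resolved default so two runs can be diffed at config level."""
    log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()
                   if k != "synthetic"},
        "synthetic_used": config.synthetic is not None,
        "seed": config.seed,
        "resolved_defaults": {
            "percentile_definition": "linear interpolation (type 7)",
            "median_even_n": "mean of central order statistics",
            "missing_station_days": "weights renormalized over reporting stations",
            "var_basis": "quadratic B-spline, no intercept, interior knots at "
                         "evenly distributed percentiles",
            "lag_basis": "natural cubic spline with intercept, boundary knots "
                         "at lag 0 and max_lag, interior knots at "
                         f"{config.lag_knot_spacing}-spaced quantiles",
            "dispersion": "Pearson chi-square / (n - k)",
            "strata_reference": "first stratum; DOW reference Monday",
            "warmup": "first max_lag days excluded from the likelihood",
            "confidence_level": 0.95,
        },
        "n_fits": len(artifacts["fits"]),
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))


def _rr_at(fit: FitResult, spec: CrossBasisSpec, temps, reference):
    surface = predict_rr(fit, spec, temps, reference)
    cum = cumulative_rr(fit, spec, temps, reference)
    rows = []
    for i, t in enumerate(np.atleast_1d(temps)):
        rows.append({"temperature": float(t),
                     "rr_lag0": surface.rr[i, 0],
                     "lo_lag0": surface.lower[i, 0], "hi_lag0": surface.upper[i, 0],
                     "rr_cum": cum.rr[i], "lo_cum": cum.lower[i],
                     "hi_cum": cum.upper[i]})
    return pd.DataFrame(rows)


def run_sensitivity(config: AnalysisConfig, artifacts: dict | None = None,
                    full_cross: bool = False) -> pd.DataFrame:
    """Refit the aggregated mean-temperature model under alternative maximum
    lags and stratum windows (one factor at a time unless ``full_cross``).

    Reports RR and 95% CI at the p90/p95/p99 grid temperatures at lag 0 and
    cumulated over lags, the delta against the base configuration, and whether
    the variant's point estimate leaves the base confidence interval.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if artifacts is None:
        base_cfg = _strip_for_base(config)
        artifacts = run_study(base_cfg)
    exposure = artifacts["exposures"]["mean"]
    summary = artifacts["summaries"]["mean"]
    if "mortality" in artifacts:
        y = artifacts["mortality"].aggregate
    elif (outdir / "mortality.csv").exists():
        y = hio.read_mortality(outdir / "mortality.csv").aggregate
    else:
        raise RuntimeError("sensitivity requires the mortality table of the base run")

    # integer grid values can coincide after rounding; evaluate each once
    temps = sorted({float(summary.grid_values[k]) for k in ("p90", "p95", "p99")})

    variants: list[tuple[str, int, str]] = [("base", config.max_lag, config.strata_scheme)]
    if full_cross:
        for L in config.sensitivity_max_lags:
            for w in config.sensitivity_windows:
                variants.append((f"lag{L}_win{w}", L, f"fixed_window:{w}"))
    for L in config.sensitivity_max_lags:
        variants.append((f"max_lag={L}", L, config.strata_scheme))
    for w in config.sensitivity_windows:
        variants.append((f"window={w}", config.max_lag, f"fixed_window:{w}"))

    base_table = None
    rows = []
    for name, L, scheme in variants:
        try:
            spec = CrossBasisSpec(max_lag=L, var_df=config.var_df,
                                  lag_df=config.lag_df,
                                  lag_knot_spacing=config.lag_knot_spacing)
            cb = build_crossbasis(exposure, spec)
            strata = make_strata(exposure.dates, scheme)
            fit = fit_quasipoisson(y, cb, strata, config.dow_terms)
            table = _rr_at(fit, cb.spec, temps, summary.reference)
        except Exception as exc:
            warnings.warn(f"sensitivity variant {name} failed: {exc}", UserWarning)
            rows.append({"variant": name, "failed": True})
            continue
        if name == "base":
            base_table = table
        for _, r in table.iterrows():
            base_row = base_table[base_table["temperature"] == r["temperature"]].iloc[0]
            rows.append({
                "variant": name, "failed": False,
                "max_lag": L, "window": scheme,
                "temperature": r["temperature"],
                "rr_lag0": r["rr_lag0"], "lo_lag0": r["lo_lag0"], "hi_lag0": r["hi_lag0"],
                "rr_cum": r["rr_cum"], "lo_cum": r["lo_cum"], "hi_cum": r["hi_cum"],
                "delta_lag0": r["rr_lag0"] - base_row["rr_lag0"],
                "outside_base_ci": bool(
                    (r["rr_lag0"] < base_row["lo_lag0"]) or
                    (r["rr_lag0"] > base_row["hi_lag0"])),
            })
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "sensitivity.csv", index=False, float_format="%.6f")
    return report


def _strip_for_base(config: AnalysisConfig) -> AnalysisConfig:
    from dataclasses import replace
    return replace(config, metrics=("mean",), fit_categories=False,
                   run_df_selection=False, make_figures=False)
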