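"""Figures: 3-D exposure-lag-response surface, lag slices and temperature
slices.  Structural reproductions, not visual facsimiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .prediction import RRSurface, lag_slice, temperature_slice  # noqa: E402

__all__ = ["plot_surface_3d", "plot_lag_slices", "plot_temperature_slices"]


def plot_surface_3d(surface: RRSurface, path, title: str = "") -> None:
    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(projection="3d")
    T, L = np.meshgrid(surface.temperatures, surface.lags, indexing="ij")
    ax.plot_surface(T, L, surface.rr, cmap="viridis", linewidth=0)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("lag (days)")
    ax.set_zlabel("RR")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_lag_slices(surface: RRSurface, temperatures, path, title: str = "") -> None:
    table = lag_slice(surface, temperatures)
    fig, ax = plt.subplots(figsize=(7, 4))
    for temp, grp in table.groupby("temperature"):
        ax.plot(grp["lag"], grp["rr"], label=f"{temp:g} °C")
        ax.fill_between(grp["lag"], grp["lower"], grp["upper"], alpha=0.15)
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("RR")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_temperature_slices(surface: RRSurface, lags, path, title: str = "") -> None:
    table = temperature_slice(surface, lags)
    lags = list(np.atleast_1d(lags))
    fig, axes = plt.subplots(len(lags), 1, figsize=(6, 2.6 * len(lags)),
                             sharex=True, squeeze=False)
    for ax, lag in zip(axes.ravel(), lags):
        grp = table[table["lag"] == lag]
        ax.plot(grp["temperature"], grp["rr"])
        ax.fill_between(grp["temperature"], grp["lower"], grp["upper"],
                        color="grey", alpha=0.3)
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_ylabel(f"RR, lag {lag}")
    axes.ravel()[-1].set_xlabel("temperature (°C)")
    if title:
        axes.ravel()[0].set_title(title)
    fig.savefig(path, dpi=100)
    plt.close(fig)
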