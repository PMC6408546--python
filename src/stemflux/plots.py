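"""Figure renderers for pipeline artifacts (PNG, matplotlib Agg)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_COLORS = {"UpperStem": "black", "LowerStem": "tab:blue", "Soil": "tab:red"}


def plot_seasonal_course(drivers: pd.DataFrame, daily: pd.DataFrame, path: Path) -> None:
    """Driver series and daily-mean fluxes per gas (seasonal-course figure)."""
    fig, axes = plt.subplots(5, 1, figsize=(9, 12), sharex=True)
    axes[0].plot(drivers.index, drivers["soil_temp_C"], lw=0.6, color="tab:orange")
    axes[0].set_ylabel("Soil temp (degC)")
    ax0b = axes[0].twinx()
    ax0b.plot(drivers.index, drivers["swc_m3m3"], lw=0.6, color="tab:blue")
    ax0b.set_ylabel("SWC (m3 m-3)")
    axes[1].plot(drivers.index, drivers["sap_flux_mm_s"], lw=0.5, color="tab:green")
    axes[1].set_ylabel("SF (mm s-1)")
    for ax, gas in zip(axes[2:], ("CO2", "CH4", "N2O")):
        for loc, grp in daily[daily.gas == gas].groupby("location"):
            ax.errorbar(grp["date"], grp["daily_mean"], yerr=grp["daily_sd"],
                        fmt=".", ms=3, lw=0.5, label=loc, color=_COLORS.get(loc))
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_ylabel(f"{gas} flux")
    axes[2].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_daily_cv(daily: pd.DataFrame, path: Path) -> None:
    """Daily coefficient of variation per gas (stems only; N2O on log10 axis)."""
    fig, axes = plt.subplots(3, 1, figsize=(9, 8), sharex=True)
    for ax, gas in zip(axes, ("CO2", "CH4", "N2O")):
        sub = daily[(daily.gas == gas) & (daily.location != "Soil")]
        for loc, grp in sub.groupby("location"):
            ax.plot(grp["date"], grp["daily_cv"], ".", ms=3, label=loc,
                    color=_COLORS.get(loc))
        if gas == "N2O":
            ax.set_yscale("log")
        ax.set_ylabel(f"|CV| {gas}")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_coherence(results: dict, path: Path) -> None:
    """Coherence heatmaps with significance contour and COI per pair."""
    n = len(results)
    fig, axes = plt.subplots((n + 1) // 2, 2, figsize=(12, 3 * ((n + 1) // 2)),
                             squeeze=False)
    for ax, (name, res) in zip(axes.ravel(), results.items()):
        t = np.arange(res.coherence.shape[1]) / 24.0
        ax.pcolormesh(t, res.periods / 24.0, res.coherence, cmap="viridis",
                      vmin=0, vmax=1, shading="auto")
        if res.significance_mask is not None:
            ax.contour(t, res.periods / 24.0, res.significance_mask.astype(float),
                       levels=[0.5], colors="yellow", linewidths=0.7)
        ax.plot(t, res.coi / 24.0, color="white", lw=0.8)
        ax.set_yscale("log")
        ax.set_ylim(res.periods[0] / 24.0, res.periods[-1] / 24.0)
        ax.invert_yaxis()
        pct = res.percent_days_significant
        ax.set_title(f"{name}" + (f" — {100 * pct:.0f}% of days" if pct == pct else ""),
                     fontsize=9)
        ax.set_ylabel("period (days)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_simple_regressions(points: pd.DataFrame, fits: pd.DataFrame, path: Path) -> None:
    """Daily flux vs driver scatter with fitted curves where significant."""
    drivers = ["Temperature", "SWC", "SF"]
    gases = ["CO2", "CH4", "N2O"]
    fig, axes = plt.subplots(3, 3, figsize=(11, 9))
    for i, gas in enumerate(gases):
        for j, drv in enumerate(drivers):
            ax = axes[i, j]
            for loc in points["location"].unique():
                sub = points[(points.gas == gas) & (points.location == loc)]
                ax.plot(sub[drv], sub["flux"], ".", ms=3, color=_COLORS.get(loc))
                frow = fits[(fits.gas == gas) & (fits.location == loc) & (fits.driver == drv)]
                if len(frow) and frow.iloc[0]["p"] < 0.05 and frow.iloc[0]["converged"]:
                    ax.set_title(f"{gas}~{drv}", fontsize=8)
            if i == 2:
                ax.set_xlabel(drv)
            if j == 0:
                ax.set_ylabel(gas)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cross_location(corr: pd.DataFrame, path: Path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, gas in zip(axes, ("CO2", "CH4", "N2O")):
        sub = corr[corr.gas == gas]
        labels = [f"{r.a[:5]}-{r.b[:5]}" for r in sub.itertuples()]
        ax.bar(labels, sub["r"], color="tab:grey")
        for x, r in enumerate(sub.itertuples()):
            ax.text(x, r.r, r.stars, ha="center", fontsize=10)
        ax.set_ylim(-1, 1)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(gas)
        ax.set_ylabel("Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sufficiency(curves: dict, path: Path) -> None:
    """Replicate-sigma boxplots vs sample size with the detected breakpoint."""
    fig, axes = plt.subplots(1, len(curves), figsize=(5 * len(curves), 4))
    if len(curves) == 1:
        axes = [axes]
    for ax, (gas, curve) in zip(axes, curves.items()):
        sigma = np.sqrt(curve.replicate_variances)
        step = max(1, len(curve.n_grid) // 40)
        ax.boxplot(sigma[::step].T, positions=curve.n_grid[::step], widths=4,
                   manage_ticks=False, flierprops={"ms": 1})
        ax.plot(curve.n_grid, curve.median_sigma, color="tab:blue", lw=1)
        if curve.breakpoint_n is not None:
            ax.axvline(curve.breakpoint_n, color="white", lw=2)
            ax.axvline(curve.breakpoint_n, color="tab:red", lw=1,
                       label=f"n_min = {curve.breakpoint_n}")
            ax.legend(fontsize=8)
        ax.set_title(gas)
        ax.set_xlabel("sample size n")
        ax.set_ylabel("sigma")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
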