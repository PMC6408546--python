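"""Daily and whole-period flux summaries.

Given the QC-filtered hourly flux table this module produces daily means,
daily coefficients of variation (absolute value, a dimensionless dispersion
measure that is undefined when the daily mean is effectively zero), period
means with normal-theory 95% confidence intervals over daily means, and
gap-filled cumulative fluxes converted to mass per area (kg CO2 m-2, g CH4
and g N2O m-2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MOLAR_MASS = {"CO2": 44.01, "CH4": 16.04, "N2O": 44.01}  # g mol-1
#: flux unit -> mol multiplier (CO2 fluxes in umol, CH4/N2O in nmol)
_MOL_PER_UNIT = {"CO2": 1e-6, "CH4": 1e-9, "N2O": 1e-9}
#: Table-style output unit per gas: kg m-2 for CO2, g m-2 for trace gases
_MASS_SCALE = {"CO2": 1e-3, "CH4": 1.0, "N2O": 1.0}

MEAN_EPS = 1e-12
MIN_HOURS_PER_DAY = 6


def summarize_daily(hourly: pd.Series, min_hours: int = MIN_HOURS_PER_DAY) -> pd.DataFrame:
    """Daily mean, sd, |CV| and coverage for one gas x location hourly series.

    CV = |sd / mean| and is reported missing when |mean| < 1e-12 (sign-flipping
    near-zero series, typical of N2O, have no meaningful relative dispersion).
    Days with fewer than ``min_hours`` surviving hours are missing entirely.
    """
    grouped = hourly.groupby(hourly.index.normalize())
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    n = grouped.count()
    thin = n < min_hours
    mean[thin] = np.nan
    sd[thin] = np.nan
    cv = np.abs(sd / mean.where(np.abs(mean) >= MEAN_EPS))
    out = pd.DataFrame({"daily_mean": mean, "daily_sd": sd, "daily_cv": cv, "n_hours": n})
    out.index = pd.DatetimeIndex(out.index)
    out.index.name = "date"
    return out


def period_mean_ci(daily_means: pd.Series) -> dict:
    """Period mean and 95% CI half-width (1.96 sd / sqrt(n)) over daily means."""
    vals = np.asarray(daily_means.dropna(), dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 daily values for a period CI")
    mean = float(vals.mean())
    half = 1.96 * float(vals.std(ddof=1)) / np.sqrt(vals.size)
    return {"mean": mean, "ci95_half_width": half, "n_obs": int(vals.size)}


def _fill_gaps(hourly: pd.Series, max_gap_hours: int) -> pd.Series:
    """Short gaps by linear interpolation, long gaps by the mean diel cycle.

    A gap is one maximal run of consecutive missing hours; only runs of
    ``max_gap_hours`` or fewer are interpolated, longer runs are filled
    entirely from the mean diel cycle (no partial interpolation).
    """
    isna = hourly.isna().to_numpy()
    if not isna.any():
        return hourly
    run_id = np.cumsum(np.diff(np.concatenate([[False], isna]).astype(int)) == 1)
    run_len = pd.Series(np.ones(len(hourly)), index=hourly.index).groupby(
        np.where(isna, run_id, -1)).transform("sum")
    short = isna & (run_len.to_numpy() <= max_gap_hours)

    interped = hourly.interpolate(method="linear", limit_area="inside",
                                  limit_direction="both")
    filled = hourly.copy()
    filled[short] = interped[short]
    if filled.isna().any():
        diel = hourly.groupby(hourly.index.hour).mean()
        climatology = pd.Series(diel.reindex(filled.index.hour).to_numpy(),
                                index=filled.index)
        filled = filled.fillna(climatology)
    # hours never observed at that clock time fall back to the period mean
    return filled.fillna(hourly.mean())


def cumulative_flux(hourly: pd.Series, gas: str, max_gap_hours: int = 72) -> float:
    """Gap-filled time integral of an hourly flux series as mass per area.

    Gaps up to ``max_gap_hours`` are linearly interpolated; longer outages are
    filled with the period-mean diel cycle (mean per hour-of-day), so a
    multi-day power failure contributes a typical day rather than zero. The
    integral sum(flux) * 3600 s is converted via the molar mass to kg m-2
    (CO2) or g m-2 (CH4, N2O).
    """
    if hourly.dropna().empty:
        raise ValueError("cannot integrate an entirely missing series")
    filled = _fill_gaps(hourly, max_gap_hours)
    mol = float(filled.sum()) * 3600.0 * _MOL_PER_UNIT[gas]
    return mol * MOLAR_MASS[gas] * _MASS_SCALE[gas]


def period_summary(hourly_table: pd.DataFrame, min_hours: int = MIN_HOURS_PER_DAY) -> pd.DataFrame:
    """Table-shaped period summary: mean, ci95, cumulative per gas x location.

    ``hourly_table`` is long form with columns timestamp, gas, location, flux
    (timestamp parseable, flux NaN where QC-removed or missing).
    """
    rows = []
    for (gas, loc), grp in hourly_table.groupby(["gas", "location"]):
        series = pd.Series(grp["flux"].to_numpy(),
                           index=pd.DatetimeIndex(grp["timestamp"])).sort_index()
        daily = summarize_daily(series, min_hours=min_hours)
        stats = period_mean_ci(daily["daily_mean"])
        cum = cumulative_flux(series, gas)
        rows.append({"gas": gas, "location": loc, **stats, "cumulative": cum})
    return pd.DataFrame(rows)


def daily_summary_table(hourly_table: pd.DataFrame, min_hours: int = MIN_HOURS_PER_DAY) -> pd.DataFrame:
    """Long-form daily summary across all gas x location series."""
    frames = []
    for (gas, loc), grp in hourly_table.groupby(["gas", "location"]):
        series = pd.Series(grp["flux"].to_numpy(),
                           index=pd.DatetimeIndex(grp["timestamp"])).sort_index()
        daily = summarize_daily(series, min_hours=min_hours).reset_index()
        daily["gas"] = gas
        daily["location"] = loc
        frames.append(daily)
    return pd.concat(frames, ignore_index=True)
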