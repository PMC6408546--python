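"""Sap-flux computation and driver-series assembly.

Sap flux density (SF) comes from Granier constant-heat-dissipation probes: a
heated probe cools as sap moves past it, so the temperature difference dT to
an unheated reference probe shrinks with flow. The original calibration maps
the flow index K = (dT_max - dT) / dT to SF = 119e-6 * K**1.231 (m3 m-2 s-1).
dT_max, the zero-flow baseline, is taken only from nights with low
evaporative demand (VPD) and stable readings, when transpiration is truly
zero, and carried between such nights as a step function.

The module also aggregates 15-min logger series (temperature, SWC, probe
signals) onto the shared hourly grid every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRANIER_COEF = 119e-6  # m3 m-2 s-1
GRANIER_EXP = 1.231

NIGHT_WINDOW = (0, 5)  # local hours [start, end) used for zero-flow search
VPD_THRESHOLD_KPA = 0.1
STABILITY_THRESHOLD_K = 0.05


@dataclass
class ProbeSeries:
    """Thermal-dissipation probe record on its native 15-min grid."""

    timestamps: pd.DatetimeIndex
    delta_T: np.ndarray  # K
    delta_T_max: np.ndarray | None = None  # K, filled by zero_flow_baseline

    def __post_init__(self) -> None:
        self.delta_T = np.asarray(self.delta_T, dtype=float)
        if len(self.timestamps) != self.delta_T.size:
            raise ValueError("timestamps and delta_T lengths differ")


@dataclass
class DriverSeries:
    """Aligned hourly drivers on one shared, strictly increasing time axis."""

    timestamps: pd.DatetimeIndex
    soil_temp: np.ndarray
    stem_temp_upper: np.ndarray
    stem_temp_lower: np.ndarray
    swc: np.ndarray
    sap_flux: np.ndarray  # mm s-1
    gap_mask: np.ndarray = field(default=None)  # True where missing

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        for name in ("soil_temp", "stem_temp_upper", "stem_temp_lower", "swc", "sap_flux"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"{name} length {arr.size} != time axis length {n}")
            setattr(self, name, arr)
        if np.any(np.diff(self.timestamps.view("int64")) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.gap_mask is None:
            self.gap_mask = np.isnan(self.soil_temp) | np.isnan(self.swc) | np.isnan(self.sap_flux)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "soil_temp_C": self.soil_temp,
                "stem_temp_upper_C": self.stem_temp_upper,
                "stem_temp_lower_C": self.stem_temp_lower,
                "swc_m3m3": self.swc,
                "sap_flux_mm_s": self.sap_flux,
                "gap": self.gap_mask.astype(int),
            },
            index=self.timestamps,
        )


def zero_flow_baseline(
    probe: ProbeSeries,
    vpd_kpa: np.ndarray,
    night_window: tuple[int, int] = NIGHT_WINDOW,
    vpd_threshold: float = VPD_THRESHOLD_KPA,
    stability_threshold: float = STABILITY_THRESHOLD_K,
) -> np.ndarray:
    """Night-anchored dT_max baseline, step-interpolated across the record.

    A night qualifies when every in-window VPD value is below ``vpd_threshold``
    and the in-window dT range is below ``stability_threshold`` — the classic
    low-evaporative-demand / stable-readings criterion for genuine zero flow.
    """
    vpd = np.asarray(vpd_kpa, dtype=float)
    if vpd.size != probe.delta_T.size:
        raise ValueError("vpd series must match probe series length")
    ts = probe.timestamps
    hours = ts.hour
    in_window = (hours >= night_window[0]) & (hours < night_window[1])
    dates = pd.Series(ts.normalize())

    anchors: list[tuple[pd.Timestamp, float]] = []
    for day, idx in dates[in_window].groupby(dates[in_window]).groups.items():
        pos = np.asarray(idx)
        dt_win = probe.delta_T[pos]
        vpd_win = vpd[pos]
        if np.any(np.isnan(dt_win)) or np.any(np.isnan(vpd_win)):
            continue
        if np.nanmax(vpd_win) < vpd_threshold and (dt_win.max() - dt_win.min()) < stability_threshold:
            anchors.append((day, float(dt_win.max())))
    if not anchors:
        raise ValueError(
            "no night qualified for zero-flow baselining; relax the VPD or "
            "stability thresholds"
        )
    anchors.sort()
    anchor_times = pd.DatetimeIndex([a[0] for a in anchors])
    anchor_vals = np.array([a[1] for a in anchors])
    # step interpolation: carry the latest qualifying night forward, backfill
    # before the first anchor
    pos = np.searchsorted(anchor_times, ts, side="right") - 1
    pos = np.clip(pos, 0, len(anchor_vals) - 1)
    baseline = anchor_vals[pos]
    probe.delta_T_max = baseline
    return baseline


def granier_sap_flux(probe: ProbeSeries) -> np.ndarray:
    """Granier calibration SF = 119e-6 K**1.231, returned in mm s-1.

    K < 0 (sensor drift pushing dT above the baseline) is clipped to zero.
    NaN inputs propagate.
    """
    if probe.delta_T_max is None:
        raise ValueError("baseline missing: run zero_flow_baseline first")
    dt = probe.delta_T
    valid = ~np.isnan(dt)
    if np.any(dt[valid] <= 0):
        raise ValueError("delta_T must be > 0 wherever defined")
    k = (probe.delta_T_max - dt) / dt
    k = np.where(np.isnan(k), np.nan, np.clip(k, 0.0, None))
    sf_m3 = GRANIER_COEF * np.power(k, GRANIER_EXP)  # m3 m-2 s-1 == m s-1
    return sf_m3 * 1000.0  # mm s-1


def invert_granier(sf_mm_s: np.ndarray, dT_max: float) -> np.ndarray:
    """dT that reproduces a given SF under the Granier calibration.

    Exact inverse of :func:`granier_sap_flux` at constant baseline:
    K = (SF / 0.119 mm s-1)**(1/1.231); dT = dT_max / (1 + K). SF = 0 maps to
    dT = dT_max (the zero-flow identity).
    """
    sf = np.asarray(sf_mm_s, dtype=float)
    if np.any(sf[~np.isnan(sf)] < 0):
        raise ValueError("sap flux must be >= 0")
    k = np.power(sf / (GRANIER_COEF * 1000.0), 1.0 / GRANIER_EXP)
    return dT_max / (1.0 + k)


def midday_sap_flux(sf_hourly: pd.Series) -> pd.Series:
    """Daily midday SF: mean over local hours 11-13 inclusive.

    The midday value indexes the daily maximum of stem water transport; a day
    with no surviving window value is missing, never zero.
    """
    window = sf_hourly[sf_hourly.index.hour.isin([11, 12, 13])]
    out = window.groupby(window.index.normalize()).mean()
    out.index = pd.DatetimeIndex(out.index)
    return out


def hourly_mean(series_15min: pd.Series, min_count: int = 2) -> pd.Series:
    """Average a 15-min series into hourly bins labelled by bin start.

    Bins with fewer than ``min_count`` of the 4 possible subsamples are
    missing, so short logger dropouts do not manufacture biased hours.
    """
    if series_15min.index.has_duplicates:
        raise ValueError("duplicate timestamps in 15-min input")
    grouped = series_15min.groupby(series_15min.index.floor("h"))
    mean = grouped.mean()
    count = grouped.count()
    mean[count < min_count] = np.nan
    return mean


def align_drivers(
    soil_temp_15: pd.Series,
    stem_temp_upper_15: pd.Series,
    stem_temp_lower_15: pd.Series,
    swc_15: pd.Series,
    sap_flux_15: pd.Series,
    min_count: int = 2,
) -> DriverSeries:
    """Aggregate raw 15-min series to one hourly DriverSeries on a shared axis."""
    hourly = {
        "soil_temp": hourly_mean(soil_temp_15, min_count),
        "stem_temp_upper": hourly_mean(stem_temp_upper_15, min_count),
        "stem_temp_lower": hourly_mean(stem_temp_lower_15, min_count),
        "swc": hourly_mean(swc_15, min_count),
        "sap_flux": hourly_mean(sap_flux_15, min_count),
    }
    start = min(s.index.min() for s in hourly.values())
    end = max(s.index.max() for s in hourly.values())
    axis = pd.date_range(start, end, freq="h")
    cols = {k: s.reindex(axis).to_numpy() for k, s in hourly.items()}
    return DriverSeries(timestamps=axis, **cols)
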