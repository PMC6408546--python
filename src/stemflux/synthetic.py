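"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates a 100-day (April-July) automated-chamber campaign at
three locations (UpperStem, LowerStem, Soil): 15-min logger drivers
(temperature with seasonal + diurnal structure, event-driven soil water,
daylight-gated sap flux), hourly true fluxes responding to those drivers with
AR(1) residuals, 1-Hz chamber concentration traces whose initial slope
encodes the true flux, and thermal-dissipation probe signals that invert the
Granier calibration. Default coefficient signs reproduce the qualitative
source/sink configuration of an upland temperate forest: stems emit CO2 and
CH4, the soil emits CO2 but takes up CH4 and N2O, and stem N2O is a small,
noisy sink.

Everything is driven by one integer seed; identical (config, seed) pairs
produce bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chamber import ChamberSpec, ConcentrationTrace, flux_to_slope
from .drivers import DriverSeries, ProbeSeries, align_drivers, invert_granier

AMBIENT = {"CO2": 410.0, "CH4": 1900.0, "N2O": 332.0}  # ppm, ppb, ppb

#: Per-(gas, location) responses on z-scored drivers. CO2 rows act on the log
#: scale (the flux is exp of the linear predictor), CH4/N2O rows are linear in
#: the flux unit. Signs encode the stem-source / soil-sink configuration.
DEFAULT_FLUX_COEFS: dict[tuple[str, str], dict[str, float]] = {
    ("CO2", "UpperStem"): {"intercept": math.log(2.8), "Temperature": 0.45, "SF": 0.12, "Temp*SF": -0.05},
    ("CO2", "LowerStem"): {"intercept": math.log(4.7), "Temperature": 0.45, "SWC": 0.10, "SF": 0.12},
    ("CO2", "Soil"): {"intercept": math.log(8.2), "Temperature": 0.60, "SWC": 0.15, "Temp*SWC": -0.05},
    ("CH4", "UpperStem"): {"intercept": 0.28, "Temperature": 0.10, "SF": 0.06},
    ("CH4", "LowerStem"): {"intercept": 0.46, "Temperature": 0.12, "SWC": 0.07},
    ("CH4", "Soil"): {"intercept": -0.66, "Temperature": -0.15, "SWC": 0.20, "Temp*SWC": 0.10},
    ("N2O", "UpperStem"): {"intercept": -0.014, "Temperature": 0.006, "SWC": 0.007, "SF": -0.010},
    ("N2O", "LowerStem"): {"intercept": -0.017},
    ("N2O", "Soil"): {"intercept": -0.046, "Temperature": -0.012},
}

#: Residual noise sd per gas, in the flux unit (log units for CO2).
DEFAULT_NOISE_SD = {"CO2": 0.10, "CH4": 0.15, "N2O": 0.05}

_INTERACTIONS = {"Temp*SWC": ("Temperature", "SWC"), "Temp*SF": ("Temperature", "SF"),
                 "SWC*SF": ("SWC", "SF")}


@dataclass
class SynthConfig:
    """Knobs of the synthetic campaign; defaults are the study conditions."""

    start_date: str = "2017-04-01"
    n_days: int = 100
    temp_base: float = 8.0  # early-season mean, degC
    temp_seasonal_amplitude: float = 16.0  # spring-to-summer rise, degC
    temp_diurnal_amplitude: float = 4.0  # half peak-to-trough, degC
    temp_noise_sd: float = 0.5  # AR(1) innovation sd, degC
    swc_initial: float = 0.30  # m3 m-3
    swc_min: float = 0.08
    swc_porosity: float = 0.45
    swc_event_rate: float = 0.15  # wetting events per day
    swc_event_scale: float = 0.04  # mean jump, m3 m-3
    swc_decay: float = 0.05  # recession rate, day-1
    sf_max: float = 0.05  # peak sap flux density, mm s-1
    flux_response_coefs: dict = field(default_factory=lambda: dict(DEFAULT_FLUX_COEFS))
    ar1_phi: float = 0.5
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    # power failures: GHG outage mid-April, sap-flux outage overlapping it
    ghg_gap_windows: list = field(default_factory=lambda: [("2017-04-16", "2017-04-20")])
    sf_gap_windows: list = field(default_factory=lambda: [("2017-04-19", "2017-04-27")])
    ambient: dict = field(default_factory=lambda: dict(AMBIENT))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        for name in ("temp_base", "temp_seasonal_amplitude", "temp_diurnal_amplitude",
                     "temp_noise_sd", "swc_initial", "swc_event_rate", "swc_decay", "sf_max"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"SynthConfig.{name} is not finite: {v!r}")
        for gas, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{gas}] must be >= 0")
        span_start = pd.Timestamp(self.start_date)
        span_end = span_start + pd.Timedelta(days=self.n_days)
        for win in list(self.ghg_gap_windows) + list(self.sf_gap_windows):
            a, b = pd.Timestamp(win[0]), pd.Timestamp(win[1])
            if a < span_start or b > span_end or a > b:
                raise ValueError(f"gap window {win} outside simulated span")


@dataclass
class TruthBundle:
    """Drivers plus the true fluxes (and coefficients) that generated them."""

    drivers: DriverSeries
    true_fluxes: pd.DataFrame  # columns (gas, location), hourly
    true_model_terms: dict


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    )


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, n)
    out = np.empty(n)
    out[0] = eps[0] / math.sqrt(max(1.0 - phi**2, 1e-12))
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i]
    return out


def _window_mask(index: pd.DatetimeIndex, windows) -> np.ndarray:
    mask = np.zeros(len(index), dtype=bool)
    for a, b in windows:
        mask |= (index >= pd.Timestamp(a)) & (index < pd.Timestamp(b) + pd.Timedelta(days=1))
    return mask


def generate_drivers_15min(config: SynthConfig) -> dict[str, pd.Series]:
    """Raw 15-min driver series (logger cadence), before hourly aggregation.

    Returns soil/stem temperatures, SWC, sap flux and VPD on one 15-min axis,
    with the configured sap-flux outage already blanked.
    """
    idx = pd.date_range(config.start_date, periods=config.n_days * 96, freq="15min")
    day_frac = (idx - idx[0]) / pd.Timedelta(days=1)
    d = np.asarray(day_frac, dtype=float)
    hour = np.asarray(idx.hour, dtype=float) + np.asarray(idx.minute, dtype=float) / 60.0

    seasonal = config.temp_base + config.temp_seasonal_amplitude * np.sin(
        0.5 * math.pi * d / config.n_days
    )
    diurnal = config.temp_diurnal_amplitude * np.cos(2 * math.pi * (hour - 14.0) / 24.0)
    rng = _rng(config, "temperature")
    noise = _ar1(len(idx), config.ar1_phi, config.temp_noise_sd, rng)
    # synoptic (multi-day) anomalies decouple temperature from the seasonal
    # ramp that sap flux also follows, keeping daily driver collinearity
    # realistic (VIF < 2 territory rather than near-deterministic coupling)
    synoptic_daily = _ar1(config.n_days, 0.7, 1.2, _rng(config, "synoptic"))
    synoptic = np.repeat(synoptic_daily, 96)
    if config.temp_noise_sd == 0:
        synoptic = np.zeros_like(synoptic)
    soil_temp = seasonal + 0.3 * diurnal + 0.5 * noise + synoptic  # soil damps the diel wave
    stem_lower = seasonal + diurnal + noise + synoptic
    stem_upper = seasonal + 1.1 * diurnal + noise + synoptic

    # SWC: Poisson wetting events with exponential recession toward swc_min
    rng_w = _rng(config, "swc")
    dt_day = 1.0 / 96.0
    events = rng_w.poisson(config.swc_event_rate * dt_day, len(idx)).astype(float)
    jumps = events * rng_w.exponential(config.swc_event_scale, len(idx))
    swc = np.empty(len(idx))
    w = config.swc_initial
    for i in range(len(idx)):
        w = config.swc_min + (w - config.swc_min) * math.exp(-config.swc_decay * dt_day)
        w = min(w + jumps[i], config.swc_porosity)
        swc[i] = w

    # SF: daylight-gated diurnal hump * seasonal ramp * day-to-day cloudiness
    # * soil-moisture limitation; cloudiness keeps midday SF from tracking
    # temperature deterministically
    daylight = np.clip(np.sin(math.pi * (hour - 6.0) / 12.0), 0.0, None) ** 1.5
    ramp = 0.55 + 0.45 * d / config.n_days
    moisture = swc / (swc + 0.05)
    cloud = np.repeat(_rng(config, "weather").uniform(0.45, 1.0, config.n_days), 96)
    sf = config.sf_max * daylight * ramp * cloud * moisture

    # VPD: daytime demand co-varying with cloudiness, exactly zero at night
    # (nightly zero flow anchors the probe baseline)
    vpd = 1.2 * daylight * cloud * (0.5 + 0.5 * d / config.n_days)

    sf = sf.copy()
    sf[_window_mask(idx, config.sf_gap_windows)] = np.nan

    return {
        "soil_temp": pd.Series(soil_temp, index=idx),
        "stem_temp_upper": pd.Series(stem_upper, index=idx),
        "stem_temp_lower": pd.Series(stem_lower, index=idx),
        "swc": pd.Series(swc, index=idx),
        "sap_flux": pd.Series(sf, index=idx),
        "vpd": pd.Series(vpd, index=idx),
    }


def generate_drivers(config: SynthConfig) -> DriverSeries:
    """Hourly DriverSeries: 15-min generation then the standard aggregation path."""
    raw = generate_drivers_15min(config)
    return align_drivers(
        raw["soil_temp"], raw["stem_temp_upper"], raw["stem_temp_lower"],
        raw["swc"], raw["sap_flux"],
    )


def _zscore_nan(x: np.ndarray) -> np.ndarray:
    mu = np.nanmean(x)
    sd = np.nanstd(x, ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - mu) / sd


def generate_flux_truth(drivers: DriverSeries, config: SynthConfig) -> TruthBundle:
    """Hourly true fluxes per gas x location as responses to the scaled drivers.

    CO2 is log-linear (exp backtransform gives temperature-exponential
    behaviour); CH4 and N2O are linear with first-order interactions. AR(1)
    noise is added on the model scale. The configured GHG outage windows are
    blanked, as is any hour whose required driver is missing.
    """
    idx = drivers.timestamps
    z = {
        "SWC": _zscore_nan(drivers.swc),
        "SF": _zscore_nan(drivers.sap_flux),
    }
    temp_for = {
        "UpperStem": _zscore_nan(drivers.stem_temp_upper),
        "LowerStem": _zscore_nan(drivers.stem_temp_lower),
        "Soil": _zscore_nan(drivers.soil_temp),
    }
    ghg_gap = _window_mask(idx, config.ghg_gap_windows)

    cols = {}
    for (gas, loc), coefs in config.flux_response_coefs.items():
        terms = {"Temperature": temp_for[loc], **z}
        lin = np.full(len(idx), float(coefs.get("intercept", 0.0)))
        for name, beta in coefs.items():
            if name == "intercept":
                continue
            if name in terms:
                lin = lin + beta * terms[name]
            elif name in _INTERACTIONS:
                a, b = _INTERACTIONS[name]
                lin = lin + beta * terms[a] * terms[b]
            else:
                raise ValueError(f"coefficient references unknown driver term {name!r}")
        rng = _rng(config, f"flux:{gas}:{loc}")
        lin = lin + _ar1(len(idx), config.ar1_phi, config.noise_sd.get(gas, 0.0), rng)
        flux = np.exp(lin) if gas == "CO2" else lin
        missing = ghg_gap | np.isnan(lin)
        flux = np.where(missing, np.nan, flux)
        cols[(gas, loc)] = flux

    frame = pd.DataFrame(cols, index=idx)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["gas", "location"])
    return TruthBundle(drivers=drivers, true_fluxes=frame,
                       true_model_terms=dict(config.flux_response_coefs))


def generate_chamber_trace(
    true_flux: float,
    chamber: ChamberSpec,
    gas: str,
    model: str = "linear",
    noise_sd: float = 0.0,
    duration_s: int = 150,
    curvature: float = 0.01,
    ambient: float | None = None,
    seed: int = 0,
) -> ConcentrationTrace:
    """1-Hz concentration trace whose initial slope encodes ``true_flux``.

    ``model='linear'`` emits chi(t) = ambient + slope0 t; ``'saturating'``
    emits the exponential relaxation toward equilibrium chi_s = ambient +
    slope0/curvature, so the slope at t=0 still equals slope0 (chamber
    feedback bends the trace but the initial slope is the flux).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if ambient is None:
        ambient = AMBIENT[gas]
    slope0 = flux_to_slope(true_flux, chamber)
    t = np.arange(duration_s, dtype=float)
    if model == "linear":
        conc = ambient + slope0 * t
    elif model == "saturating":
        chi_s = ambient + slope0 / curvature
        conc = chi_s + (ambient - chi_s) * np.exp(-curvature * t)
    else:
        raise ValueError(f"unknown trace model {model!r}")
    if noise_sd > 0:
        conc = conc + np.random.default_rng(seed).normal(0.0, noise_sd, duration_s)
    return ConcentrationTrace(time_s=t, conc=conc, gas=gas, chamber=chamber)


def generate_probe_dT(sf_truth: pd.Series, dT_max: float = 10.0) -> ProbeSeries:
    """Probe dT series that inverts the Granier calibration exactly.

    SF = 0 maps to dT = dT_max; round-tripping through granier_sap_flux
    recovers ``sf_truth`` to numerical precision.
    """
    vals = np.asarray(sf_truth, dtype=float)
    if np.any(vals[~np.isnan(vals)] < 0):
        raise ValueError("sap-flux truth must be >= 0")
    dT = invert_granier(vals, dT_max)
    return ProbeSeries(timestamps=sf_truth.index, delta_T=dT)


# ---------------------------------------------------------------------------
# run-directory output

def write_trace(trace, path: str | Path) -> Path:
    """Write one closure trace as CSV with chamber/environment header rows."""
    path = Path(path)
    ch = trace.chamber
    header = (
        f"# gas,{trace.gas}\n"
        f"# collar_area_m2,{ch.collar_area}\n"
        f"# system_volume_m3,{ch.system_volume}\n"
        f"# pressure_Pa,{ch.pressure}\n"
        f"# air_temperature_K,{ch.air_temperature}\n"
    )
    body = pd.DataFrame({"time_s": trace.time_s, "conc": trace.conc}).to_csv(index=False)
    path.write_text(header + body)
    return path


def write_run(outdir: str | Path, bundle: TruthBundle, config: SynthConfig) -> Path:
    """Write driver and true-flux CSVs plus a YAML manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drivers = bundle.drivers.to_frame()
    drivers.index.name = "timestamp"
    drivers.to_csv(outdir / "drivers_hourly.csv", date_format="%Y-%m-%dT%H:%M:%S")

    long = bundle.true_fluxes.stack(["gas", "location"], future_stack=True).rename("flux").reset_index()
    long.columns = ["timestamp", "gas", "location", "flux"]
    long.to_csv(outdir / "fluxes_true.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")

    manifest = {
        "generator": "stemflux.synthetic",
        "seed": int(config.seed),
        "n_days": int(config.n_days),
        "start_date": str(config.start_date),
        "ar1_phi": float(config.ar1_phi),
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return outdir
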