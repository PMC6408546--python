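"""End-to-end orchestration: synthetic campaign -> flux tables -> analyses.

Stages run in the order the data flows in the field system: trace-level flux
estimation, driver assembly, aggregation, diel coherence, seasonal models,
and sampling sufficiency. Every stage reads and writes only declared CSV/PNG
files inside one run directory, so any stage can be re-run alone by a fresh
process; a YAML manifest records the configuration and the per-stage child
seeds fanned out (by stable hashing of stage names) from the single global
seed.
"""

from __future__ import annotations

import hashlib
import logging
import shutil
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation, coherence, plots, season_models, sufficiency, synthetic
from .chamber import ChamberSpec, estimate_closure, qaqc_filter
from .drivers import ProbeSeries, align_drivers, granier_sap_flux, midday_sap_flux, zero_flow_baseline
from .synthetic import SynthConfig

logger = logging.getLogger("stemflux")

STAGES = ("simulate", "fluxes", "drivers", "aggregate", "coherence", "models", "sufficiency")

DEFAULT_CONFIG: dict = {
    "mode": "synthetic",
    "synthetic": {},  # SynthConfig overrides
    "chamber": {
        "system_volume": 0.004,
        "curvature_co2": 0.004,
        "trace_noise": {"CO2": 0.15, "CH4": 1.0, "N2O": 1.0},
        "bad_closure_rate": 0.04,
        "durations": {"UpperStem": 350, "LowerStem": 350, "Soil": 150},
    },
    "coherence": {
        # surrogate count for the pipeline run; the significance routine's own
        # default is 10,000 (see coherence.mc_significance)
        "n_surrogates": 300,
        "alpha": 0.05,
        "day_rule": 0.5,
        "max_interp_frac": 0.25,
        "write_matrices": False,
    },
    "models": {"correlation": "AR1"},
    "sufficiency": {"n_min": 3, "n_max": 250, "reps": 40},
    "paths": {},  # data mode: flux_table, drivers_15min
}


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) if path else {}
    merged = _deep_merge(DEFAULT_CONFIG, cfg or {})
    if overrides:
        merged = _deep_merge(merged, overrides)
    return merged


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# input validation (data mode and synthetic outputs alike)

def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Schema and sanity report for input CSVs; returns a violation list."""
    report: list[dict] = []
    required_cols = {
        "flux_table": ["timestamp", "location", "gas", "flux"],
        "drivers_15min": ["timestamp", "soil_temp_C", "swc_m3m3"],
    }
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            report.append({"file": str(path), "row": None, "column": None,
                           "problem": "missing file"})
            continue
        df = pd.read_csv(path)
        for col in required_cols.get(name, []):
            if col not in df.columns:
                report.append({"file": str(path), "row": None, "column": col,
                               "problem": "missing column"})
        if "timestamp" in df.columns:
            ts = pd.to_datetime(df["timestamp"])
            if name != "flux_table" and not ts.is_monotonic_increasing:
                bad = int(np.argmin(np.diff(ts.astype("int64")) > 0))
                report.append({"file": str(path), "row": bad + 1, "column": "timestamp",
                               "problem": "timestamps not monotone increasing"})
            if name != "flux_table" and ts.duplicated().any():
                report.append({"file": str(path), "row": int(ts.duplicated().idxmax()),
                               "column": "timestamp", "problem": "duplicate timestamp"})
        for col, lo, hi in (("swc_m3m3", 0.0, 1.0), ("soil_temp_C", -40.0, 60.0)):
            if col in df.columns:
                bad = df.index[(df[col] < lo) | (df[col] > hi)]
                for row in bad[:20]:
                    report.append({"file": str(path), "row": int(row), "column": col,
                                   "problem": f"value {df.loc[row, col]} outside [{lo}, {hi}]"})
    return report


# ---------------------------------------------------------------------------
# stages

def stage_simulate(outdir: Path, cfg: dict, seed: int) -> None:
    synth_cfg = SynthConfig(**cfg["synthetic"], seed=child_seed(seed, "simulate"))
    raw = synthetic.generate_drivers_15min(synth_cfg)
    drv = align_drivers(raw["soil_temp"], raw["stem_temp_upper"],
                        raw["stem_temp_lower"], raw["swc"], raw["sap_flux"])
    truth = synthetic.generate_flux_truth(drv, synth_cfg)
    probe = synthetic.generate_probe_dT(raw["sap_flux"], dT_max=10.0)

    table = pd.DataFrame({
        "timestamp": raw["soil_temp"].index,
        "soil_temp_C": raw["soil_temp"].to_numpy(),
        "stem_temp_upper_C": raw["stem_temp_upper"].to_numpy(),
        "stem_temp_lower_C": raw["stem_temp_lower"].to_numpy(),
        "swc_m3m3": raw["swc"].to_numpy(),
        "vpd_kpa": raw["vpd"].to_numpy(),
        "probe_dT_K": probe.delta_T,
    })
    table.to_csv(outdir / "drivers_15min.csv", index=False,
                 date_format="%Y-%m-%dT%H:%M:%S")
    synthetic.write_run(outdir, truth, synth_cfg)


def stage_fluxes(outdir: Path, cfg: dict, seed: int) -> None:
    """Trace-level flux estimation: generate 1-Hz closures from the true
    fluxes, run the fit competition, and apply the CO2-anchored QA/QC."""
    ccfg = cfg["chamber"]
    truth = pd.read_csv(outdir / "fluxes_true.csv", parse_dates=["timestamp"])
    wide = truth.pivot_table(index="timestamp", columns=["gas", "location"],
                             values="flux")
    rng = np.random.default_rng(child_seed(seed, "fluxes"))
    rows = []
    for loc in ("UpperStem", "LowerStem", "Soil"):
        chamber = ChamberSpec(system_volume=ccfg["system_volume"])
        duration = int(ccfg["durations"][loc])
        sub = {gas: wide[(gas, loc)] for gas in ("CO2", "CH4", "N2O")}
        for ts in wide.index:
            fluxes = {gas: sub[gas].loc[ts] for gas in sub}
            if np.isnan(fluxes["CO2"]):
                continue
            bad = rng.random() < ccfg["bad_closure_rate"]
            traces = {}
            for gas, f in fluxes.items():
                if np.isnan(f):
                    continue
                model = "saturating" if gas == "CO2" else "linear"
                tr = synthetic.generate_chamber_trace(
                    f, chamber, gas, model=model,
                    noise_sd=ccfg["trace_noise"][gas], duration_s=duration,
                    curvature=ccfg["curvature_co2"],
                    seed=int(rng.integers(2**31)),
                )
                if bad and gas == "CO2":
                    # improper closure: pressure bounce swamps the signal
                    amp = max(abs(tr.conc[-1] - tr.conc[0]), 1.0)
                    tr.conc[:] += amp * np.sin(2 * np.pi * tr.time_s / 30.0)
                traces[gas] = tr
            obs = estimate_closure(traces, chamber, timestamp=ts, location=loc)
            obs = qaqc_filter(obs)
            rows.extend(
                {"timestamp": ts, "location": o.location, "gas": o.gas,
                 "flux": o.flux, "fit_model": o.fit_model, "r2": o.r_squared,
                 "qc_pass": o.qc_pass, "qc_reason": o.qc_reason}
                for o in obs
            )
    pd.DataFrame(rows).to_csv(outdir / "flux_table.csv", index=False,
                              date_format="%Y-%m-%dT%H:%M:%S")


def stage_drivers(outdir: Path, cfg: dict, seed: int) -> None:
    """Probe baselining, Granier sap flux and hourly driver alignment."""
    raw = pd.read_csv(outdir / "drivers_15min.csv", parse_dates=["timestamp"])
    idx = pd.DatetimeIndex(raw["timestamp"])
    probe = ProbeSeries(timestamps=idx, delta_T=raw["probe_dT_K"].to_numpy())
    zero_flow_baseline(probe, raw["vpd_kpa"].to_numpy())
    sf = pd.Series(granier_sap_flux(probe), index=idx)
    drv = align_drivers(
        pd.Series(raw["soil_temp_C"].to_numpy(), index=idx),
        pd.Series(raw["stem_temp_upper_C"].to_numpy(), index=idx),
        pd.Series(raw["stem_temp_lower_C"].to_numpy(), index=idx),
        pd.Series(raw["swc_m3m3"].to_numpy(), index=idx),
        sf,
    )
    frame = drv.to_frame()
    frame.index.name = "timestamp"
    frame.to_csv(outdir / "drivers_hourly.csv", date_format="%Y-%m-%dT%H:%M:%S")


def _load_flux_table(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "flux_table.csv", parse_dates=["timestamp"])


def stage_aggregate(outdir: Path, cfg: dict, seed: int) -> None:
    flux = _load_flux_table(outdir)
    daily = aggregation.daily_summary_table(flux)
    daily.to_csv(outdir / "daily_summary.csv", index=False)
    period = aggregation.period_summary(flux)
    period.to_csv(outdir / "period_summary.csv", index=False)
    drivers = pd.read_csv(outdir / "drivers_hourly.csv", parse_dates=["timestamp"],
                          index_col="timestamp")
    plots.plot_seasonal_course(drivers, daily, outdir / "fig_seasonal_course.png")
    plots.plot_daily_cv(daily, outdir / "fig_daily_cv.png")


def stage_coherence(outdir: Path, cfg: dict, seed: int) -> None:
    """Diel wavelet coherence of LowerStem fluxes with temperature and SF."""
    ccfg = cfg["coherence"]
    flux = _load_flux_table(outdir)
    drivers = pd.read_csv(outdir / "drivers_hourly.csv", parse_dates=["timestamp"],
                          index_col="timestamp")
    axis = drivers.index
    plan = coherence.CoherencePlan(len(axis))
    rng = np.random.default_rng(child_seed(seed, "coherence"))
    thresholds = coherence.coherence_thresholds(
        len(axis), n_surrogates=int(ccfg["n_surrogates"]), alpha=ccfg["alpha"],
        rng=rng, plan=plan,
    )
    results, rows = {}, []
    driver_series = {
        "Temperature": drivers["stem_temp_lower_C"],
        "SF": drivers["sap_flux_mm_s"],
    }
    for gas in ("CO2", "CH4", "N2O"):
        sub = flux[(flux.gas == gas) & (flux.location == "LowerStem")]
        series = pd.Series(sub["flux"].to_numpy(),
                           index=pd.DatetimeIndex(sub["timestamp"])).reindex(axis)
        x, x_interp = coherence.interpolate_gaps(series)
        for drv_name, drv in driver_series.items():
            y, y_interp = coherence.interpolate_gaps(drv)
            res = coherence.wavelet_coherence(x, y, times=axis, plan=plan)
            coherence.mc_significance(res, thresholds=thresholds, alpha=ccfg["alpha"])
            interp = pd.Series(x_interp | y_interp, index=axis)
            frac = interp.groupby(axis.normalize()).mean()
            excluded = frac.index[frac > ccfg["max_interp_frac"]]
            pct, flags = coherence.percent_days_significant(
                res, day_rule=ccfg["day_rule"], exclude_days=excluded)
            name = f"{gas}~{drv_name}"
            results[name] = res
            rows.append({"pair": name, "percent_days_significant": pct,
                         "n_days": int(len(flags)), "n_flagged": int(flags.sum())})
            if ccfg.get("write_matrices"):
                _write_coherence_matrix(outdir / f"coherence_{gas}_{drv_name}.csv", res)
    pd.DataFrame(rows).to_csv(outdir / "coherence_summary.csv", index=False)
    flags_frame = pd.DataFrame(
        {name: res.day_flags for name, res in results.items()}
    )
    flags_frame.index.name = "date"
    flags_frame.to_csv(outdir / "coherence_day_flags.csv")
    plots.plot_coherence(results, outdir / "fig_coherence.png")


def _write_coherence_matrix(path: Path, res) -> None:
    nper, nt = res.coherence.shape
    frame = pd.DataFrame({
        "time": np.repeat(np.asarray(res.times), nper),
        "period_h": np.tile(res.periods, nt),
        "coherence": res.coherence.T.ravel().round(4),
        "significant": res.significance_mask.T.ravel().astype(int),
    })
    frame.to_csv(path, index=False)


def _daily_model_table(outdir: Path, gas: str, loc: str) -> pd.DataFrame:
    flux = _load_flux_table(outdir)
    drivers = pd.read_csv(outdir / "drivers_hourly.csv", parse_dates=["timestamp"],
                          index_col="timestamp")
    sub = flux[(flux.gas == gas) & (flux.location == loc)]
    series = pd.Series(sub["flux"].to_numpy(), index=pd.DatetimeIndex(sub["timestamp"]))
    daily_flux = aggregation.summarize_daily(series)["daily_mean"]
    temp_col = {"UpperStem": "stem_temp_upper_C", "LowerStem": "stem_temp_lower_C",
                "Soil": "soil_temp_C"}[loc]
    temp = drivers[temp_col].groupby(drivers.index.normalize()).mean()
    swc = drivers["swc_m3m3"].groupby(drivers.index.normalize()).mean()
    sf = midday_sap_flux(drivers["sap_flux_mm_s"])
    table = pd.DataFrame({"flux": daily_flux, "Temperature": temp, "SWC": swc, "SF": sf})
    return table.dropna()


def stage_models(outdir: Path, cfg: dict, seed: int) -> None:
    """Seasonal GLS selection (Table-2-shaped), simple regressions, and
    cross-location correlations."""
    summary_rows, coef_frames, cand_frames = [], [], []
    points, fit_rows = [], []
    daily_wide_per_gas: dict[str, dict[str, pd.Series]] = {g: {} for g in ("CO2", "CH4", "N2O")}
    for gas in ("CO2", "CH4", "N2O"):
        for loc in ("UpperStem", "LowerStem", "Soil"):
            table = _daily_model_table(outdir, gas, loc)
            daily_wide_per_gas[gas][loc] = table["flux"]
            log_flag = gas == "CO2"
            response = np.log(table["flux"]) if log_flag else table["flux"]
            data = table[["Temperature", "SWC", "SF"]].copy()
            data["response"] = response
            scaled, _ = season_models.scale_predictors(data)
            vif_table = season_models.vif(scaled[["Temperature", "SWC", "SF"]])
            sel = season_models.enumerate_and_select(
                "response", scaled, log_transform=log_flag,
                correlation=cfg["models"]["correlation"])
            label = f"{loc} {'log' if log_flag else ''}{gas}"
            summary_rows.append({
                "gas": gas, "location": loc, "model": label,
                "terms": "+".join(sel.selected.spec.terms) or "(Intercept)",
                "adj_r2": sel.selected.adj_r2, "p_value": sel.overall_p,
                "significant": sel.significant, "phi": sel.selected.phi,
                "n": sel.selected.n, "max_vif": float(vif_table["vif"].max()),
            })
            coefs = sel.selected.coefficients.reset_index(names="term")
            coefs.insert(0, "model", label)
            coef_frames.append(coefs)
            cand = sel.candidates
            cand.insert(0, "model", label)
            cand_frames.append(cand)

            # per-driver simple regressions (seasonal scatter fits)
            for drv in ("Temperature", "SWC", "SF"):
                form = "linear"
                if gas == "CO2" and drv == "Temperature":
                    form = "exponential"
                elif gas == "CH4" and loc == "Soil" and drv == "Temperature":
                    form = "sigmoidal"
                fit = season_models.fit_simple_regression(table[drv], table["flux"], form)
                fit_rows.append({"gas": gas, "location": loc, "driver": drv,
                                 "form": form, "r2": fit.r_squared, "p": fit.p_value,
                                 "n": fit.n, "converged": fit.converged})
            pts = table.copy()
            pts["gas"] = gas
            pts["location"] = loc
            points.append(pts.reset_index(names="date"))

    pd.DataFrame(summary_rows).to_csv(outdir / "table_models_summary.csv", index=False)
    pd.concat(coef_frames).to_csv(outdir / "table_models_coefficients.csv", index=False)
    pd.concat(cand_frames).to_csv(outdir / "model_candidates.csv", index=False)
    fits = pd.DataFrame(fit_rows)
    fits.to_csv(outdir / "simple_regressions.csv", index=False)

    corr_frames = []
    for gas, cols in daily_wide_per_gas.items():
        corr = season_models.cross_location_correlation(pd.DataFrame(cols))
        corr.insert(0, "gas", gas)
        corr_frames.append(corr)
    corr = pd.concat(corr_frames, ignore_index=True)
    corr.to_csv(outdir / "cross_location_correlations.csv", index=False)

    all_points = pd.concat(points, ignore_index=True)
    plots.plot_simple_regressions(all_points, fits, outdir / "fig_regressions.png")
    plots.plot_cross_location(corr, outdir / "fig_cross_location.png")


def stage_sufficiency(outdir: Path, cfg: dict, seed: int) -> None:
    """Minimum-measurement analysis on the pooled stem fluxes per gas."""
    scfg = cfg["sufficiency"]
    flux = _load_flux_table(outdir)
    stem = flux[flux.location.isin(["UpperStem", "LowerStem"])]
    curves, rows, frames = {}, [], []
    for gas in ("CO2", "CH4", "N2O"):
        pool = stem[stem.gas == gas]["flux"].dropna().to_numpy()
        curve = sufficiency.minimum_sampling_effort(
            pool, n_grid=range(int(scfg["n_min"]), int(scfg["n_max"]) + 1),
            reps=int(scfg["reps"]), seed=child_seed(seed, f"sufficiency:{gas}"))
        curves[gas] = curve
        rows.append({"gas": gas, "pool_size": pool.size,
                     "breakpoint_n": curve.breakpoint_n,
                     "flagged": curve.breakpoint_flagged,
                     "slope_left": curve.trend_left[0] if curve.trend_left else np.nan,
                     "slope_right": curve.trend_right[0] if curve.trend_right else np.nan})
        q = np.quantile(curve.replicate_variances, [0.25, 0.5, 0.75], axis=1)
        frames.append(pd.DataFrame({
            "gas": gas, "n": curve.n_grid, "var_q25": q[0], "var_median": q[1],
            "var_q75": q[2], "mk_progressive": curve.mk_progressive,
            "mk_retrograde": curve.mk_retrograde,
        }))
    pd.DataFrame(rows).to_csv(outdir / "sufficiency_breakpoints.csv", index=False)
    pd.concat(frames, ignore_index=True).to_csv(outdir / "sufficiency_curves.csv", index=False)
    plots.plot_sufficiency(curves, outdir / "fig_sufficiency.png")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fluxes": stage_fluxes,
    "drivers": stage_drivers,
    "aggregate": stage_aggregate,
    "coherence": stage_coherence,
    "models": stage_models,
    "sufficiency": stage_sufficiency,
}


def run_pipeline(config: dict, outdir: str | Path, seed: int = 0,
                 force: bool = False, stages=None) -> Path:
    """Run the configured stages into ``outdir``; returns the run directory.

    Refuses to overwrite an existing non-empty run directory unless
    ``force``. In data mode the declared input paths are validated (and the
    flux table copied in) before any stage runs.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not force:
            raise FileExistsError(f"run directory {outdir} exists; use force=True")
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stages = list(stages or STAGES)
    if config["mode"] == "data":
        paths = config.get("paths", {})
        for key in ("flux_table", "drivers_15min"):
            if key not in paths:
                raise ValueError(f"data mode requires paths.{key}")
        report = validate_inputs(paths)
        fatal = [v for v in report if v["problem"] in ("missing file", "missing column")]
        if fatal:
            raise ValueError(f"input validation failed: {fatal}")
        shutil.copy(paths["flux_table"], outdir / "flux_table.csv")
        shutil.copy(paths["drivers_15min"], outdir / "drivers_15min.csv")
        stages = [s for s in stages if s not in ("simulate", "fluxes")]

    cfg_text = yaml.safe_dump(config, sort_keys=True)
    manifest = {
        "seed": int(seed),
        "config": config,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "stage_seeds": {s: child_seed(seed, s) for s in stages},
    }
    (outdir / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    for stage in stages:
        logger.info("[%s] running", stage)
        try:
            _STAGE_FUNCS[stage](outdir, config, seed)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("[%s] done", stage)
    return outdir
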