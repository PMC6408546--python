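"""Per-closure trace-gas flux estimation from closed-chamber concentration traces.

A closed chamber sealed over a soil collar or stem mount accumulates (or
depletes) gas; the flux is inferred from the rate of change of the mole
fraction inside. Two models compete per trace: a straight line and a
saturating exponential that accounts for chamber feedback (the build-up
reduces the diffusion gradient, curving the trace). For CO2 and CH4 the fit
with the higher R-squared wins; N2O, whose fluxes hover near zero, is always
fit linearly to avoid the bias an exponential fit introduces at near-zero
slopes. Quality control is anchored on the CO2 fit: a poor CO2 R-squared
signals an improper chamber closure, which invalidates all three gases for
that timestamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

R_GAS = 8.314  # J mol-1 K-1

#: Gases handled per closure and their areal flux units.
GASES = ("CO2", "CH4", "N2O")
FLUX_UNITS = {"CO2": "umol m-2 s-1", "CH4": "nmol m-2 s-1", "N2O": "nmol m-2 s-1"}
LOCATIONS = ("UpperStem", "LowerStem", "Soil")

#: CO2 fit-quality threshold below which a closure is discarded for all gases.
CO2_R2_THRESHOLD = 0.9


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and environment of one chamber system.

    collar_area is the sealed surface in m2 (default 317.8 cm2, the PVC
    collar of the LI-COR 8100-104 survey chamber); system_volume includes
    chamber, tubing and analyzer cell.
    """

    collar_area: float = 0.03178  # m2
    system_volume: float = 0.004  # m3
    pressure: float = 101325.0  # Pa
    air_temperature: float = 298.15  # K
    deadband_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("collar_area", "system_volume", "pressure", "air_temperature"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"ChamberSpec.{name} must be finite and > 0, got {v!r}")
        if self.deadband_s < 0:
            raise ValueError("ChamberSpec.deadband_s must be >= 0")


@dataclass(frozen=True)
class ConcentrationTrace:
    """One chamber closure: 1-Hz mole fractions for a single gas.

    ``conc`` is in ppm for CO2 and ppb for CH4/N2O; the slope unit then
    propagates to umol / nmol areal fluxes without extra factors.
    """

    time_s: np.ndarray
    conc: np.ndarray
    gas: str
    chamber: ChamberSpec = field(default_factory=ChamberSpec)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("time_s and conc must be 1-D arrays of equal length")
        if self.gas not in GASES:
            raise ValueError(f"unknown gas {self.gas!r}; expected one of {GASES}")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "conc", c)

    def after_deadband(self, deadband_s: Optional[float] = None):
        db = self.chamber.deadband_s if deadband_s is None else deadband_s
        keep = self.time_s >= self.time_s[0] + db
        return self.time_s[keep], self.conc[keep]


@dataclass(frozen=True)
class FitResult:
    model: str  # "linear" | "exponential"
    slope0: float  # mole-fraction s-1 at closure start
    params: tuple
    r_squared: float
    n_points: int
    converged: bool


@dataclass
class FluxObservation:
    """One gas x location x timestamp flux with its fit provenance."""

    timestamp: object
    location: str
    gas: str
    flux: float  # umol m-2 s-1 (CO2) or nmol m-2 s-1 (CH4, N2O)
    fit_model: str
    r_squared: float
    qc_pass: bool = True
    qc_reason: str = ""


def _r_squared(obs: np.ndarray, fitted: np.ndarray) -> float:
    ssr = float(np.sum((obs - fitted) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        # constant trace: no variance to explain
        return 0.0
    return 1.0 - ssr / sst


def fit_linear(trace: ConcentrationTrace, deadband_s: Optional[float] = None) -> FitResult:
    """Ordinary least-squares line chi(t) = b0 + b1*t on the post-deadband trace."""
    t, c = trace.after_deadband(deadband_s)
    if t.size < 3:
        raise ValueError(f"need >= 3 points after deadband, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    slope, intercept = np.polyfit(t, c, 1)
    fitted = intercept + slope * t
    return FitResult(
        model="linear",
        slope0=float(slope),
        params=(float(intercept), float(slope)),
        r_squared=_r_squared(c, fitted),
        n_points=int(t.size),
        converged=True,
    )


def _exp_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    # chi(t) = chi0 + (s/a)(1 - exp(-a t)): s is the initial slope and the
    # parameterization degenerates smoothly into the straight line as a -> 0
    chi_0, s, a = params
    g = -np.expm1(-a * t) / a  # (1 - exp(-a t)) / a, stable for small a
    return chi_0 + s * g


def _exp_jac(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    chi_0, s, a = params
    e = np.exp(-a * t)
    g = -np.expm1(-a * t) / a
    return np.column_stack([np.ones_like(t), g, s * (t * e - g) / a])


def fit_exponential(
    trace: ConcentrationTrace, deadband_s: Optional[float] = None
) -> FitResult:
    """Saturating-exponential fit chi(t) = chi_s + (chi_0 - chi_s) exp(-a (t - t0)).

    chi_s is the equilibrium mole fraction the chamber relaxes toward, chi_0
    the value at the (post-deadband) closure start, and ``a`` the relaxation
    rate. The flux-defining quantity is the initial slope
    slope0 = a (chi_s - chi_0), the unbiased rate before feedback sets in.
    Non-convergence is reported via ``converged=False`` (caller falls back to
    the linear fit), never raised.
    """
    t, c = trace.after_deadband(deadband_s)
    if t.size < 5:
        raise ValueError(f"need >= 5 points after deadband, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    tt = t - t[0]
    span = float(tt[-1])

    lin = np.polyfit(tt, c, 1)
    slope_l, chi0_init = float(lin[0]), float(lin[1])
    scale = max(np.std(c), 1e-9)

    def residuals(p: np.ndarray) -> np.ndarray:
        return _exp_model(p, tt) - c

    # curvature start from a quadratic prefit: chi ~ chi0 + s t - (a s / 2) t^2
    quad = np.polyfit(tt, c, 2)
    a_quad = -2.0 * quad[0] / quad[1] if quad[1] != 0 else 0.0
    starts = [a_quad] if 1e-6 / span < a_quad < 100.0 / span else []
    starts += [1.0 / span]

    def solve(a0: float):
        p0 = np.array([chi0_init, slope_l, a0])
        try:
            return least_squares(
                residuals,
                p0,
                jac=lambda p: _exp_jac(p, tt),
                bounds=([-np.inf, -np.inf, 1e-10], [np.inf, np.inf, np.inf]),
                xtol=1e-10,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=200,
            )
        except Exception:
            return None

    rss_lin = float(np.sum((np.polyval(lin, tt) - c) ** 2))
    best = solve(starts[0])
    if best is None or 2.0 * best.cost > rss_lin * (1.0 + 1e-9):
        # informed start failed to reach even the linear limit: try default
        for a0 in starts[1:]:
            sol = solve(a0)
            if sol is not None and (best is None or sol.cost < best.cost):
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return FitResult("exponential", float("nan"), (), float("-inf"), int(t.size), False)

    chi_0, slope0, a = (float(v) for v in best.x)
    fitted = _exp_model(best.x, tt)
    r2 = _r_squared(c, fitted)
    chi_s = chi_0 + slope0 / a if a > 0 else float("inf")
    if not math.isfinite(slope0):
        return FitResult("exponential", float("nan"), (chi_s, chi_0, a), r2, int(t.size), False)
    return FitResult("exponential", slope0, (chi_s, chi_0, a), r2, int(t.size), bool(best.success))


def slope_to_flux(slope0: float, chamber: ChamberSpec) -> float:
    """Ideal-gas conversion of a mole-fraction rate to an areal molar flux.

    flux = slope0 * P V / (R T A). A slope in ppm s-1 yields umol m-2 s-1 and
    a slope in ppb s-1 yields nmol m-2 s-1 (the 1e-6 / 1e-9 of the mixing
    ratio cancels against the micro/nano prefix of the flux unit).
    """
    if chamber.collar_area <= 0:
        raise ValueError("collar_area must be > 0")
    return (
        slope0
        * chamber.pressure
        * chamber.system_volume
        / (R_GAS * chamber.air_temperature * chamber.collar_area)
    )


def flux_to_slope(flux: float, chamber: ChamberSpec) -> float:
    """Inverse of :func:`slope_to_flux` (used by the trace generator)."""
    return (
        flux
        * R_GAS
        * chamber.air_temperature
        * chamber.collar_area
        / (chamber.pressure * chamber.system_volume)
    )


def estimate_closure(
    traces: dict[str, ConcentrationTrace],
    chamber: ChamberSpec,
    timestamp=None,
    location: str = "Soil",
) -> list[FluxObservation]:
    """Estimate the three gas fluxes of one closure.

    CO2 and CH4 take the better of {linear, exponential} by R-squared, the
    exponential entering the competition only when it converged; N2O is
    always linear. The CO2 trace must be present because QC is CO2-anchored.
    """
    if "CO2" not in traces:
        raise ValueError("closure is missing the CO2 trace (QC is CO2-anchored)")
    out: list[FluxObservation] = []
    for gas in GASES:
        trace = traces.get(gas)
        if trace is None:
            out.append(
                FluxObservation(timestamp, location, gas, float("nan"), "none",
                                float("nan"), qc_pass=False, qc_reason="missing_trace")
            )
            continue
        lin = fit_linear(trace)
        if gas == "N2O":
            chosen = lin
        else:
            exp = fit_exponential(trace)
            chosen = exp if (exp.converged and exp.r_squared > lin.r_squared) else lin
        flux = slope_to_flux(chosen.slope0, chamber)
        out.append(
            FluxObservation(timestamp, location, gas, flux, chosen.model,
                            chosen.r_squared)
        )
    return out


def qaqc_filter(observations: list[FluxObservation]) -> list[FluxObservation]:
    """CO2-anchored QA/QC for one closure triple, in place and returned.

    A CO2 R-squared below 0.9 indicates the chamber did not seal properly,
    so the physical record of that timestamp is untrustworthy: all three
    fluxes become NaN. Otherwise all three pass regardless of the CH4 and
    N2O fit quality.
    """
    co2 = [o for o in observations if o.gas == "CO2"]
    if not co2:
        raise ValueError("closure triple has no CO2 observation")
    bad = not (co2[0].r_squared >= CO2_R2_THRESHOLD)
    if bad:
        for o in observations:
            o.flux = float("nan")
            o.qc_pass = False
            o.qc_reason = "co2_r2"
    return observations
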