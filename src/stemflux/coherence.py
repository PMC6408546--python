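"""Wavelet coherence between hourly flux and driver series.

Wavelet coherence is a time-localized, scale-resolved squared correlation:
the cross-wavelet spectrum of two series, smoothed in time and scale, and
normalized by the smoothed individual power spectra. It exposes transient
couplings — e.g. a diel (1-day period) correlation between stem CH4 flux and
sap flux that holds only on some days — that a global correlation washes
out.

The transform is the Morlet continuous wavelet (omega0 = 6) computed in the
frequency domain on dyadic scales; smoothing follows the standard coherence
formulation (Gaussian in time with width equal to the scale, boxcar over 0.6
octaves in scale). Significance is assessed per scale against Monte-Carlo
surrogate coherence from independent Gaussian white-noise pairs, and a
per-day flag at the 1-day band summarizes how often the coupling is
significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import logging

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

OMEGA0 = 6.0
#: Fourier factor: period = FOURIER_FACTOR * scale for the Morlet(6) wavelet.
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))
DJ = 1.0 / 12.0  # 12 sub-octaves per octave
SCALE_SMOOTH_OCTAVES = 0.6


@dataclass
class CoherenceResult:
    """Time x period coherence with significance bookkeeping."""

    times: np.ndarray  # hourly axis (DatetimeIndex or integer hours)
    periods: np.ndarray  # hours, dyadic
    coherence: np.ndarray  # (n_periods, n_times) in [0, 1]
    phase: np.ndarray  # radians
    coi: np.ndarray  # per-time maximum trustworthy period, hours
    significance_mask: Optional[np.ndarray] = None
    day_flags: Optional[pd.Series] = None
    percent_days_significant: Optional[float] = None

    @property
    def coi_mask(self) -> np.ndarray:
        """True where the pixel's period is inside the cone of influence."""
        return self.periods[:, None] <= self.coi[None, :]


class CoherencePlan:
    """Precomputed wavelet daughters and smoothing kernels for one series length.

    Building the plan once and reusing it across many equal-length pairs (the
    Monte-Carlo surrogates in particular) dominates the cost of repeated
    coherence computation.
    """

    def __init__(self, n: int, dt: float = 1.0, dj: float = DJ):
        if n < 48:
            raise ValueError("series must span at least 2 days of hourly data")
        self.n = n
        self.dt = dt
        self.dj = dj
        # dyadic periods from 2*dt to n*dt/4
        s0 = 2.0 * dt / FOURIER_FACTOR
        j_max = int(np.floor(np.log2(n * dt / 4.0 / (s0 * FOURIER_FACTOR)) / dj))
        self.scales = s0 * 2.0 ** (dj * np.arange(j_max + 1))
        self.periods = self.scales * FOURIER_FACTOR

        self.nfft = next_fast_len(2 * n)
        omega = 2.0 * np.pi * np.fft.fftfreq(self.nfft, d=dt)
        # Morlet daughters in the frequency domain (analytic: positive freqs)
        heaviside = (omega > 0).astype(float)
        arg = self.scales[:, None] * omega[None, :]
        self.daughters = (
            np.pi**-0.25
            * np.sqrt(2.0 * np.pi * self.scales[:, None] / dt)
            * heaviside[None, :]
            * np.exp(-0.5 * (arg - OMEGA0) ** 2 * heaviside[None, :])
        )
        # Gaussian time-smoothing kernels, unit-gain in the frequency domain
        self.smooth_kernels = np.exp(-0.5 * (self.scales[:, None] * omega[None, :]) ** 2)
        self.scale_window = max(1, int(round(SCALE_SMOOTH_OCTAVES / dj)))
        # e-folding cone of influence (period units)
        dist = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
        self.coi = FOURIER_FACTOR / np.sqrt(2.0) * dt * np.maximum(dist, 1e-9)

    def cwt(self, x: np.ndarray) -> np.ndarray:
        """Morlet CWT, shape (n_scales, n)."""
        xhat = fft(x, n=self.nfft)
        return ifft(xhat[None, :] * self.daughters, axis=1)[:, : self.n]

    def smooth(self, field: np.ndarray) -> np.ndarray:
        """Coherence smoothing: scale-wide Gaussian in time, boxcar over scales."""
        fhat = fft(field, n=self.nfft, axis=1)
        out = ifft(fhat * self.smooth_kernels, axis=1)[:, : self.n]
        if not np.iscomplexobj(field):
            out = out.real
        return uniform_filter1d(out, self.scale_window, axis=0, mode="nearest")


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("series contains missing values; gap-fill before the CWT")
    sd = x.std()
    if sd == 0:
        raise ValueError("constant input series (zero variance)")
    return (x - x.mean()) / sd


def interpolate_gaps(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Linear gap interpolation; returns values and the was-interpolated mask."""
    mask = series.isna().to_numpy()
    filled = series.interpolate(method="linear", limit_direction="both")
    return filled.to_numpy(), mask


def cwt_morlet(x: np.ndarray, dt: float = 1.0, plan: Optional[CoherencePlan] = None):
    """Morlet(6) continuous wavelet transform of a standardized series.

    Returns (transform, periods, coi); the transform has one row per dyadic
    scale from 2*dt up to a quarter of the record length.
    """
    x = _standardize(x)
    if plan is None or plan.n != x.size:
        plan = CoherencePlan(x.size, dt)
    return plan.cwt(x), plan.periods, plan.coi


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    dt: float = 1.0,
    times=None,
    plan: Optional[CoherencePlan] = None,
) -> CoherenceResult:
    """Squared wavelet coherence R2(scale, t) of two equal-length series."""
    x = _standardize(x)
    y = _standardize(y)
    if x.size != y.size:
        raise ValueError("series lengths differ")
    if plan is None or plan.n != x.size:
        plan = CoherencePlan(x.size, dt)
    wx = plan.cwt(x)
    wy = plan.cwt(y)
    inv_s = 1.0 / plan.scales[:, None]
    sxx = plan.smooth(np.abs(wx) ** 2 * inv_s)
    syy = plan.smooth(np.abs(wy) ** 2 * inv_s)
    sxy = plan.smooth(wx * np.conj(wy) * inv_s)
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / np.where(denom > 0, denom, np.nan)
    coh = np.clip(np.nan_to_num(coh, nan=0.0), 0.0, 1.0)
    phase = np.angle(sxy)
    if times is None:
        times = np.arange(x.size)
    return CoherenceResult(
        times=times, periods=plan.periods, coherence=coh, phase=phase, coi=plan.coi
    )


def coherence_thresholds(
    n: int,
    n_surrogates: int = 10_000,
    alpha: float = 0.05,
    dt: float = 1.0,
    rng: np.random.Generator | int | None = None,
    plan: Optional[CoherencePlan] = None,
    ar1_phi: float = 0.0,
) -> np.ndarray:
    """Per-scale (1 - alpha) coherence quantiles under the surrogate null.

    For each dyadic scale the in-COI coherence values of ``n_surrogates``
    independent surrogate pairs are pooled (via a fine histogram) and the
    (1 - alpha) quantile is returned; exceeding it is the pixel-level
    significance criterion. The default null is Gaussian white noise;
    ``ar1_phi`` != 0 switches to AR(1) (red-noise) surrogates, a stricter
    null for autocorrelated series, off by default.
    """
    if n_surrogates < 100:
        logger.warning("n_surrogates=%d is low; thresholds will be noisy", n_surrogates)
    rng = np.random.default_rng(rng)

    if ar1_phi:
        scale = 1.0 / np.sqrt(1.0 - ar1_phi**2)

        def draw() -> np.ndarray:
            eps = rng.standard_normal(n)
            out = np.empty(n)
            out[0] = eps[0] * scale
            for i in range(1, n):
                out[i] = ar1_phi * out[i - 1] + eps[i]
            return out
    else:
        def draw() -> np.ndarray:
            return rng.standard_normal(n)
    if plan is None:
        plan = CoherencePlan(n, dt)
    n_scales = plan.periods.size
    if alpha >= 1.0:  # degenerate level: everything in the COI is significant
        return np.full(n_scales, -np.inf)
    in_coi = plan.periods[:, None] <= plan.coi[None, :]
    scale_idx = np.broadcast_to(np.arange(n_scales)[:, None], in_coi.shape)[in_coi]

    nbins = 1000
    hist = np.zeros(n_scales * nbins, dtype=np.int64)
    for _ in range(n_surrogates):
        res = wavelet_coherence(draw(), draw(), dt=dt, plan=plan)
        vals = res.coherence[in_coi]
        bins = np.minimum((vals * nbins).astype(np.int64), nbins - 1)
        hist += np.bincount(scale_idx * nbins + bins, minlength=n_scales * nbins)

    hist = hist.reshape(n_scales, nbins)
    thresholds = np.empty(n_scales)
    for j in range(n_scales):
        c = np.cumsum(hist[j])
        if c[-1] == 0:
            thresholds[j] = 1.0
            continue
        k = int(np.searchsorted(c, (1.0 - alpha) * c[-1]))
        thresholds[j] = (k + 1) / nbins  # conservative: upper bin edge
    return thresholds


def mc_significance(
    result: CoherenceResult,
    n_surrogates: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    thresholds: Optional[np.ndarray] = None,
    dt: float = 1.0,
) -> np.ndarray:
    """Monte-Carlo significance mask for a coherence result.

    A pixel is significant when its coherence exceeds the per-scale
    white-noise threshold and it lies inside the cone of influence.
    Precomputed ``thresholds`` (from :func:`coherence_thresholds`) may be
    passed to amortize the surrogate cost over many pairs.
    """
    if thresholds is None:
        thresholds = coherence_thresholds(
            result.coherence.shape[1], n_surrogates, alpha, dt=dt, rng=rng
        )
    mask = (result.coherence > thresholds[:, None]) & result.coi_mask
    result.significance_mask = mask
    return mask


def percent_days_significant(
    result: CoherenceResult,
    band_days: tuple[float, float] = (0.75, 1.25),
    day_rule: float = 0.5,
    min_pixels: int = 12,
    exclude_days: Optional[np.ndarray] = None,
) -> tuple[float, pd.Series]:
    """Fraction of days with significant 1-day-band coherence.

    A day is flagged when at least ``day_rule`` of its in-band, in-COI pixels
    are significant; the denominator counts days with at least ``min_pixels``
    usable in-band pixels (days swallowed by the cone at the record edges, or
    listed in ``exclude_days``, drop out).
    """
    if result.significance_mask is None:
        raise ValueError("run mc_significance first")
    band = (result.periods >= band_days[0] * 24.0) & (result.periods <= band_days[1] * 24.0)
    if not band.any():
        raise ValueError("no scales inside the requested period band")
    eligible = result.coi_mask[band]
    sig = result.significance_mask[band]

    times = result.times
    if isinstance(times, (pd.DatetimeIndex, pd.Series)):
        day_key = pd.DatetimeIndex(times).normalize()
    else:
        day_key = pd.Index(np.asarray(times) // 24)

    flags = {}
    for day in day_key.unique():
        cols = day_key == day
        n_elig = int(eligible[:, cols].sum())
        if n_elig < min_pixels:
            continue
        if exclude_days is not None and day in exclude_days:
            continue
        flags[day] = (sig[:, cols].sum() / n_elig) >= day_rule
    day_flags = pd.Series(flags, dtype=bool)
    frac = float(day_flags.mean()) if len(day_flags) else float("nan")
    result.day_flags = day_flags
    result.percent_days_significant = frac
    return frac, day_flags
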