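# Methods

`stemflux` implements the complete computational chain behind an automated
greenhouse-gas chamber campaign on a tree stem and its adjacent soil: flux
estimation from raw concentration traces, driver preprocessing, and three
time-series analyses (diel wavelet coherence, seasonal GLS driver models,
and a resampling-based minimum-sampling-effort analysis). This note records
the models, the defaults and why they were chosen, and what the bundled
synthetic campaign does and does not establish.

## Chamber flux estimation

A closure seals a chamber of volume *V* over a collar of area *A*; the gas
mole fraction χ(t) is logged at 1 Hz for 150 s (soil) or 350 s (stem). Two
models compete per trace:

- linear: χ(t) = χ₀ + s·t (OLS);
- saturating exponential: χ(t) = χ_s + (χ₀ − χ_s)·e^(−a·t), which captures
  chamber feedback (the concentration build-up reduces the diffusion
  gradient). Internally it is parameterized as χ(t) = χ₀ + (s/a)(1 − e^(−a·t))
  with *s* the initial slope, so the model degenerates smoothly into the
  straight line as a → 0 and the optimizer (bounded trust-region least
  squares with analytic Jacobian, ftol 1e-12, curvature start from a
  quadratic prefit) never chases a divergent equilibrium parameter.

The flux-defining quantity is always the initial slope s — for the
exponential model that is the tangent at closure start, the standard
unbiased choice under feedback. Conversion to an areal flux uses the ideal
gas law, F = s·PV/(RTA); a ppm·s⁻¹ slope yields µmol m⁻² s⁻¹ and a ppb·s⁻¹
slope yields nmol m⁻² s⁻¹.

R² for both models is 1 − SSR/SST about the trace mean, putting the linear
and nonlinear fits on one comparison scale; a constant trace reports R² = 0
by convention. CO₂ and CH₄ keep the better fit by R² (the exponential only
if it converged; otherwise the linear fit is used and the failure is
recorded). N₂O is always fit linearly: its fluxes sit near zero, where an
exponential fit is biased.

QA/QC is anchored on CO₂: if the CO₂ R² of a closure is below 0.9 the
chamber is assumed not to have sealed properly and **all three** gas fluxes
of that timestamp become NaN; otherwise all three are kept regardless of the
CH₄/N₂O fit quality (near-zero trace-gas slopes legitimately produce low R²).
Missing values propagate as explicit NaN, never dropped rows. The deadband
default is 0 s but configurable.

## Drivers

Sap flux density comes from Granier constant-heat-dissipation probes via the
original calibration SF = 119×10⁻⁶·K^1.231 (m³ m⁻² s⁻¹, reported as mm s⁻¹)
with K = (ΔT_max − ΔT)/ΔT. The zero-flow baseline ΔT_max is anchored only on
nights (00:00–05:00 local, configurable) with low evaporative demand (all
in-window VPD < 0.1 kPa) and stable readings (ΔT range < 0.05 K), and is
carried between qualifying nights as a step function. Negative K from
sensor drift is clipped to zero. Midday sap flux — the daily indicator of
maximum stem water transport — is the mean over local hours 11–13.

Logger series arrive at 15-min cadence and are averaged into hourly bins
labelled by bin start (local standard time, no DST); a bin needs at least 2
of its 4 subsamples, otherwise it is missing. All drivers share one strictly
increasing hourly axis with an explicit gap mask.

## Aggregation

Daily statistics per gas × location: mean, sd, and |CV| = |sd/mean|
(reported missing when |mean| < 10⁻¹², since a sign-flipping near-zero
series has no meaningful relative dispersion); days with fewer than 6
surviving hours are missing. The period mean uses daily means with a
normal-theory 95 % CI (1.96·sd/√n). Daily averaging reduces but does not
remove autocorrelation, so the CI is mildly optimistic — a documented
limitation. Cumulative fluxes integrate the hourly series (Σ flux·3600 s)
after gap filling: runs of ≤ 72 missing hours are linearly interpolated,
longer outages are filled with the period-mean diel cycle so a multi-day
power failure contributes typical days rather than zeros. Conversion to
mass uses molar masses 44.01 (CO₂), 16.04 (CH₄), 44.01 (N₂O) g mol⁻¹,
reported as kg m⁻² for CO₂ and g m⁻² for the trace gases. The gap policy is
an explicit package choice (field-processing conventions vary) and is
configurable.

## Wavelet coherence

The diel question — on which days does a flux co-oscillate with temperature
or sap flux at the 1-day period? — is answered with wavelet coherence:
R²(s,t) = |S(W_xy/s)|² / (S(|W_x|²/s)·S(|W_y|²/s)), where W is the Morlet
(ω₀ = 6) continuous wavelet transform of the standardized, gap-interpolated
hourly series, and S smooths with a Gaussian of width equal to the scale in
time and a boxcar over 0.6 octaves in scale. Scales are dyadic from 2·dt to
a quarter of the record, 12 sub-octaves per octave; the e-folding cone of
influence (COI) marks where record edges corrupt the estimate. The CWT and
smoothing are computed by FFT with precomputed per-length kernels, making
the Monte-Carlo loop cheap.

Significance is Monte-Carlo: per scale, the (1 − α) quantile of in-COI
coherence pooled over surrogate pairs of independent Gaussian white noise
(default 10,000 surrogates at α = 0.05; the pipeline stage uses 300 by
default — the thresholds are smooth in scale and stable well below 10⁴).
A pixel is significant when its coherence exceeds the scale threshold inside
the COI. White-noise surrogates follow the stated methodology of the
original analysis; an AR(1) surrogate option would be stricter but is out of
scope.

The per-day statistic: a day is flagged when ≥ 50 % (configurable,
`day_rule`) of its in-band (0.75–1.25 day periods), in-COI pixels are
significant; the denominator counts days with ≥ 12 usable in-band pixels,
excluding days where more than 25 % of the hours were gap-interpolated.
"Percent of days significant" is the flagged fraction. The day rule is one
of several defensible operationalizations (an "any pixel" rule is
selectable); results are reported for the default only.

Calibration: with independent white-noise inputs the flagged in-band
fraction is 0.051 at α = 0.05 (200 pairs × 1,000 surrogates; the acceptance
script recomputes this).

## Seasonal GLS models

Daily responses (log-transformed for CO₂ to linearize the temperature
relation) are regressed on z-scored daily temperature (location-matched
sensor), SWC, and midday SF, with all first-order interactions available.
Residuals are AR(1): the fit is exact maximum likelihood via the
Prais–Winsten transform with the AR parameter profiled numerically. ML (not
REML) keeps log-likelihoods comparable across fixed-effect sets, which AICc
ranking requires. k counts mean parameters + residual variance + φ;
AICc = AIC + 2k(k+1)/(n−k−1). Gapped days are treated as consecutive AR
steps (a calendar-aware alternative is a config away). Standard errors are
conditional on φ̂ with t-tests on n − p degrees of freedom; adjusted R² uses
the squared correlation of fitted vs observed — the only form that stays
well defined under a non-spherical error covariance.

Model selection enumerates all 18 hierarchy-respecting subsets of the 3 main
effects and 3 interactions (every interaction requires both mains),
including the intercept-only model. Candidates are ranked by AICc; among
models within 2 units of the minimum — statistically indistinguishable at
that spacing — the **most complex** one is kept (most terms, then most
interactions, then lower AICc), because the goal is understanding driver
relations rather than parsimonious prediction. The overall model p-value is
a likelihood-ratio test of the selected model against intercept-only;
p > 0.05 is reported "n.s.". Collinearity is screened with VIF = 1/(1−R²ⱼ)
(threshold 2).

Simple per-pair regressions (daily flux vs one driver) first drop points
with Cook's distance > 4/n from the linear fit, then fit linear (slope
t-test), exponential y = a·e^{bx}, or 4-parameter logistic
y = d + (a−d)/(1+e^{−b(x−c)}) forms (the latter two tested against the
constant model by F-test). The 4PL is our reading of "sigmoidal";
alternatives can be swapped in. Cross-location correlations are
pairwise-complete Pearson r with two-sided t-test p and the conventional
star codes (** p < 0.001, * p < 0.05).

## Sampling sufficiency

For each sample size n in 3…250, 40 replicates of n values are drawn with
replacement from the pooled stem measurements (UpperStem ∪ LowerStem per
gas); the replicate statistic is the (n−1)-denominator sample variance and
the median over replicates is tracked against n. Sampling with replacement
makes each replicate variance unbiased for the pool variance at every n, so
the median curve stabilizes once n is informative.

The breakpoint — the minimum number of measurements — is the split point of
the best two-segment least-squares fit of log σ against log n (sampling
variability decays as a power of n, so the declining limb is linear on that
axis); the two fitted lines are the reported "variance regression trends".
Sequential Mann–Kendall statistics (progressive u and retrograde u′,
standardized cumulative exceedance counts with half credit for ties so an
all-tied series gives u ≡ 0) quantify trend on the curve; the detection is
flagged unreliable when the right-hand limb still carries a significant MK
trend of non-negligible slope (> 10 % of the left limb's), e.g. for a
strictly monotone curve with no regime change, or when the curve is
constant. We evaluated the classic progressive/retrograde crossing as the
breakpoint estimator and found it locates trend *onset*, not the offset this
analysis needs, and is unstable on realistic median curves; the two-segment
fit recovers a constructed change point exactly and matches the two-trend
summary the method reports. On a homogeneous (e.g. Gaussian) pool the curve
has no sharp break and the detected point sits in the small-n curvature
region with substantial seed-to-seed spread — an intrinsic property of the
question, not the detector.

## Synthetic campaign

The generator emulates the study conditions end to end: 100 days (April–
July) of 15-min drivers aggregated to hourly, hourly true fluxes at three
locations, 1-Hz chamber traces, and probe ΔT signals, all from one seed.

- **Temperature**: seasonal rise (8 → 24 °C half-sine ramp) + diurnal
  sinusoid (±4 °C, peak 14:00; soil damped to 30 %) + AR(1) noise +
  synoptic multi-day anomalies (daily AR(1), sd 1.2 °C, φ 0.7).
- **SWC**: Poisson wetting events (0.15 day⁻¹, mean jump 0.04 m³ m⁻³) with
  exponential recession (0.05 day⁻¹) toward a dry floor, bounded by
  porosity. The event/recession form is the simplest model producing
  realistic traces; no soil-water physics is implied.
- **Sap flux**: daylight-gated diurnal hump × seasonal ramp × daily
  cloudiness factor (uniform 0.45–1) × soil-moisture limitation, exactly
  zero at night; VPD co-varies with cloudiness and is exactly zero at night
  so the zero-flow baseline is exercised. The synoptic and cloudiness terms
  keep the daily Temperature/SWC/SF collinearity realistic (VIF < 2, as
  observed in the field) instead of near-deterministic.
- **Fluxes**: per gas × location responses on z-scored drivers — log-linear
  for CO₂ (so the back-transformed flux is temperature-exponential), linear
  with interactions for CH₄ and N₂O — plus AR(1) residuals (φ = 0.5) so the
  GLS correlation structure is exercised non-trivially. Default coefficient
  signs encode the qualitative source/sink configuration: stems emit CO₂
  and CH₄, the soil emits CO₂ but takes up CH₄ and N₂O, and stem N₂O is a
  small noise-dominated sink with frequent sign flips (hence large daily
  CVs). Magnitudes are order-of-magnitude realistic only; matching any
  particular field campaign's numbers is a non-goal.
- **Traces**: ambient 410 ppm CO₂ / 1900 ppb CH₄ / 332 ppb N₂O
  (configurable; instrument ambients are site-specific), Gaussian noise
  (0.15 ppm, 1 ppb, 1 ppb), saturating CO₂ traces (curvature 0.004 s⁻¹) and
  linear trace-gas traces so the fit competition exercises both branches.
  4 % of closures are corrupted with a pressure-bounce artifact that drives
  the CO₂ R² below 0.9, exercising the QA/QC cascade at the field-observed
  failure rate.
- **Gaps**: a mid-April GHG outage and an overlapping, longer sap-flux
  outage mimic the power-failure pattern of such campaigns and are honored
  as NaN by every downstream stage.

What passing on synthetic data does **not** show: the generator's response
surfaces are drawn from the same family the GLS stage fits, so model
selection on synthetic data is easier than on real fluxes with unmodelled
drivers (phenology, stem water status); trace noise is i.i.d. Gaussian,
ignoring analyzer drift; and the AR(1) residual is a crude stand-in for real
flux autocorrelation.

## Reproducibility and problem sizes

One global seed fans out to per-stage child seeds by stable hashing of
stage names, so a stage re-run alone reproduces its output. Identical
(config, seed) pairs give byte-identical CSVs.

Default analysis sizes: the full 100-day campaign everywhere; 300 surrogates
in the pipeline coherence stage (10,000 in the function default); the GLS
acceptance simulations use 100 replicates of 100 daily observations; the
sufficiency analysis uses the full n = 3…250 × 40 replicate grid. The
acceptance script uses 200 white-noise pairs against 1,000-surrogate
thresholds.
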