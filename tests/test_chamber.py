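"""Trace fitting, flux conversion and the CO2-anchored QA/QC cascade."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stemflux.chamber import (
    ChamberSpec,
    ConcentrationTrace,
    R_GAS,
    estimate_closure,
    fit_exponential,
    fit_linear,
    flux_to_slope,
    qaqc_filter,
    slope_to_flux,
)
from stemflux.synthetic import generate_chamber_trace


def _trace(conc, gas="CO2", chamber=None):
    chamber = chamber or ChamberSpec()
    return ConcentrationTrace(np.arange(len(conc), dtype=float), np.asarray(conc, float),
                              gas, chamber)


class TestLinearFit:
    def test_exact_line_recovered(self):
        t = np.arange(150.0)
        fit = fit_linear(_trace(400.0 + 0.1 * t))
        assert fit.slope0 == pytest.approx(0.1, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_trace_zero_slope_zero_r2(self):
        fit = fit_linear(_trace(np.full(50, 410.0)))
        assert fit.slope0 == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0
        assert fit.converged

    def test_matches_normal_equations_oracle(self, rng):
        t = np.arange(150.0)
        c = 400.0 + 0.07 * t + rng.normal(0, 0.5, 150)
        fit = fit_linear(_trace(c))
        # independent closed-form OLS slope
        slope_oracle = np.sum((t - t.mean()) * (c - c.mean())) / np.sum((t - t.mean()) ** 2)
        assert fit.slope0 == pytest.approx(slope_oracle, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(_trace([1.0, 2.0]))

    def test_deadband_removes_early_seconds(self):
        t = np.arange(150.0)
        c = 400.0 + 0.1 * t
        c[:10] = 500.0  # junk before the deadband
        fit = fit_linear(_trace(c), deadband_s=10)
        assert fit.slope0 == pytest.approx(0.1, abs=1e-12)


class TestExponentialFit:
    def test_recovers_generating_parameters(self):
        t = np.arange(150.0)
        conc = 500.0 + (400.0 - 500.0) * np.exp(-0.01 * t)
        fit = fit_exponential(_trace(conc))
        chi_s, chi_0, a = fit.params
        assert chi_s == pytest.approx(500.0, rel=1e-4)
        assert chi_0 == pytest.approx(400.0, rel=1e-4)
        assert a == pytest.approx(0.01, rel=1e-4)
        assert fit.slope0 == pytest.approx(1.0, rel=1e-4)  # a * (chi_s - chi_0)

    def test_linear_limit_agrees_with_ols(self):
        t = np.arange(150.0)
        fit_exp = fit_exponential(_trace(400.0 + 0.1 * t))
        fit_lin = fit_linear(_trace(400.0 + 0.1 * t))
        assert fit_exp.slope0 == pytest.approx(fit_lin.slope0, rel=0.01)

    def test_curved_trace_beats_linear_r2(self, chamber):
        tr = generate_chamber_trace(4.0, chamber, "CO2", model="saturating",
                                    noise_sd=0.1, duration_s=150, curvature=0.01, seed=3)
        assert fit_exponential(tr).r_squared >= fit_linear(tr).r_squared

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_r_squared_never_exceeds_one(self, seed):
        r = np.random.default_rng(seed)
        conc = 400.0 + r.normal(0, 2.0, 60).cumsum() * 0.05 + r.normal(0, 0.5, 60)
        fit = fit_exponential(_trace(conc))
        assert fit.r_squared <= 1.0


class TestSlopeToFlux:
    def test_hand_evaluated_ideal_gas_conversion(self, chamber):
        # slope 0.1 ppm/s, V=0.004 m3, A=0.03178 m2, P=101325 Pa, T=298.15 K
        expected = 0.1 * 101325.0 * 0.004 / (R_GAS * 298.15 * 0.03178)
        assert expected == pytest.approx(0.514, abs=5e-4)  # sanity on the oracle
        assert slope_to_flux(0.1, chamber) == pytest.approx(expected, rel=1e-12)

    def test_zero_slope_zero_flux(self, chamber):
        assert slope_to_flux(0.0, chamber) == 0.0

    def test_volume_proportionality(self, chamber):
        doubled = ChamberSpec(collar_area=chamber.collar_area,
                              system_volume=2 * chamber.system_volume,
                              pressure=chamber.pressure,
                              air_temperature=chamber.air_temperature)
        assert slope_to_flux(0.1, doubled) == pytest.approx(2 * slope_to_flux(0.1, chamber))

    def test_flux_to_slope_inverts(self, chamber):
        assert flux_to_slope(slope_to_flux(0.37, chamber), chamber) == pytest.approx(0.37)


class TestRoundTrip:
    @pytest.mark.parametrize("model,flux", [("linear", 3.0), ("linear", -0.6),
                                            ("saturating", 3.0), ("saturating", -0.6)])
    def test_noise_free_trace_refits_to_true_flux(self, chamber, model, flux):
        tr = generate_chamber_trace(flux, chamber, "CO2", model=model, noise_sd=0.0,
                                    duration_s=150, curvature=0.004)
        fit = fit_exponential(tr) if model == "saturating" else fit_linear(tr)
        assert slope_to_flux(fit.slope0, chamber) == pytest.approx(flux, rel=1e-4)

    def test_flux_invariant_to_constant_offset(self, chamber):
        tr = generate_chamber_trace(2.0, chamber, "CO2", model="saturating",
                                    noise_sd=0.05, duration_s=150, curvature=0.004, seed=5)
        shifted = ConcentrationTrace(tr.time_s, tr.conc + 50.0, tr.gas, chamber)
        for fitter in (fit_linear, fit_exponential):
            assert fitter(shifted).slope0 == pytest.approx(fitter(tr).slope0, rel=1e-6)


class TestClosureEstimation:
    def test_fit_competition_per_gas(self, chamber):
        traces = {
            "CO2": generate_chamber_trace(4.0, chamber, "CO2", model="saturating",
                                          noise_sd=0.1, duration_s=150,
                                          curvature=0.01, seed=1),
            "CH4": generate_chamber_trace(0.4, chamber, "CH4", model="linear",
                                          noise_sd=0.5, duration_s=150, seed=2),
            "N2O": generate_chamber_trace(-0.5, chamber, "N2O", model="saturating",
                                          noise_sd=0.0, duration_s=150, curvature=0.01),
        }
        obs = {o.gas: o for o in estimate_closure(traces, chamber)}
        assert obs["CO2"].fit_model == "exponential"
        assert obs["CH4"].fit_model == "linear"
        # N2O stays linear even on a strongly curved trace
        assert obs["N2O"].fit_model == "linear"

    def test_missing_co2_trace_is_an_error(self, chamber):
        tr = generate_chamber_trace(0.4, chamber, "CH4", duration_s=150)
        with pytest.raises(ValueError, match="CO2"):
            estimate_closure({"CH4": tr}, chamber)

    def test_exponential_failure_falls_back_to_linear(self, chamber, monkeypatch):
        from stemflux import chamber as chamber_mod
        from stemflux.chamber import FitResult

        def broken(trace, deadband_s=None):
            return FitResult("exponential", float("nan"), (), float("-inf"), 150, False)

        monkeypatch.setattr(chamber_mod, "fit_exponential", broken)
        traces = {"CO2": generate_chamber_trace(4.0, chamber, "CO2", model="saturating",
                                                noise_sd=0.0, duration_s=150,
                                                curvature=0.01)}
        obs = {o.gas: o for o in chamber_mod.estimate_closure(traces, chamber)}
        assert obs["CO2"].fit_model == "linear"


class TestQAQC:
    def _closure(self, chamber, co2_r2):
        from stemflux.chamber import FluxObservation
        return [
            FluxObservation(0, "Soil", "CO2", 5.0, "linear", co2_r2),
            FluxObservation(0, "Soil", "CH4", -0.5, "linear", 0.01),
            FluxObservation(0, "Soil", "N2O", -0.02, "linear", 0.2),
        ]

    def test_good_co2_keeps_all_regardless_of_trace_gas_r2(self, chamber):
        obs = qaqc_filter(self._closure(chamber, 0.95))
        assert all(o.qc_pass for o in obs)
        assert not any(np.isnan(o.flux) for o in obs)

    def test_bad_co2_removes_all_three(self, chamber):
        obs = qaqc_filter(self._closure(chamber, 0.89))
        assert all(not o.qc_pass for o in obs)
        assert all(np.isnan(o.flux) for o in obs)
        assert all(o.qc_reason == "co2_r2" for o in obs)

    def test_counting_on_100_closure_fixture(self, chamber):
        """7 constructed sub-0.9 CO2 fits remove exactly 21 flux values."""
        removed = 0
        kept = 0
        for i in range(100):
            co2_r2 = 0.85 if i % 14 == 0 and i < 98 else 0.97  # exactly 7 bad
            obs = qaqc_filter(self._closure(chamber, co2_r2))
            removed += sum(np.isnan(o.flux) for o in obs)
            kept += sum(not np.isnan(o.flux) for o in obs)
        assert removed == 21
        assert kept == 279
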