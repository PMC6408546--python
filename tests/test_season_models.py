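"""Scaling, VIF, AR(1)-GLS, AICc selection and the simple seasonal fits."""

import numpy as np
import pandas as pd
import pytest

from stemflux.season_models import (
    INTERACTIONS,
    ModelSpec,
    aicc,
    cross_location_correlation,
    enumerate_and_select,
    enumerate_model_terms,
    fit_gls,
    fit_simple_regression,
    scale_predictors,
    unscale,
    vif,
)


def _ar1(n, phi, sd, rng):
    e = rng.normal(0, sd, n)
    out = np.empty(n)
    out[0] = e[0] / np.sqrt(1 - phi**2) if sd else 0.0
    for i in range(1, n):
        out[i] = phi * out[i - 1] + e[i]
    return out


def _data(n=100, seed=0, phi=0.0, sd=0.0, coefs=None):
    rng = np.random.default_rng(seed)
    d = pd.DataFrame({
        "Temperature": rng.normal(0, 1, n),
        "SWC": rng.normal(0, 1, n),
        "SF": rng.normal(0, 1, n),
    })
    coefs = coefs or {}
    y = np.full(n, coefs.get("intercept", 0.0))
    for term, b in coefs.items():
        if term == "intercept":
            continue
        if term in INTERACTIONS:
            a, c = INTERACTIONS[term]
            y = y + b * d[a] * d[c]
        else:
            y = y + b * d[term]
    d["response"] = y + _ar1(n, phi, sd, rng)
    return d


class TestScaling:
    def test_zscore_identity(self):
        table = pd.DataFrame({"a": [1.0, 5.0, 2.0, 9.0], "b": [0.1, 0.2, 0.4, 0.3]})
        scaled, consts = scale_predictors(table)
        assert scaled.mean().abs().max() < 1e-12
        assert (scaled.std(ddof=1) - 1).abs().max() < 1e-12

    def test_hand_case(self):
        scaled, _ = scale_predictors(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(scaled["x"], [-1.0, 0.0, 1.0])

    def test_back_transform_round_trip(self):
        table = pd.DataFrame({"x": [3.0, 7.0, 11.0, 2.0]})
        scaled, consts = scale_predictors(table)
        np.testing.assert_allclose(unscale(scaled["x"], consts, "x"), table["x"],
                                   atol=1e-12)

    def test_zero_variance_column_named(self):
        with pytest.raises(ValueError, match="flat"):
            scale_predictors(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self, rng):
        z = rng.normal(size=(100, 3))
        q, _ = np.linalg.qr(z - z.mean(axis=0))  # centered orthogonal columns
        X = pd.DataFrame(q, columns=list("abc"))
        assert (vif(X)["vif"] - 1.0).abs().max() < 1e-9

    def test_duplicated_predictor_infinite(self):
        x = np.arange(10.0)
        out = vif(pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(0).normal(size=10)}))
        assert np.isinf(out.loc["a", "vif"])
        assert not out.loc["a", "below_threshold"]

    def test_closed_form_from_pairwise_correlation(self, rng):
        # construct a pair with empirical r exactly 0.8 via orthonormal basis
        z = rng.normal(size=(200, 2))
        q, _ = np.linalg.qr(z - z.mean(axis=0))
        x1 = q[:, 0]
        x2 = 0.8 * q[:, 0] + np.sqrt(1 - 0.64) * q[:, 1]
        out = vif(pd.DataFrame({"x1": x1, "x2": x2}))
        np.testing.assert_allclose(out["vif"], 1.0 / (1.0 - 0.64), rtol=1e-9)


class TestGLS:
    def test_phi_zero_matches_ols(self):
        d = _data(n=80, seed=1, coefs={"intercept": 1.0, "Temperature": 0.5}, sd=0.3)
        gls = fit_gls(ModelSpec("response", ("Temperature", "SWC"), correlation="none"), d)
        X = np.column_stack([np.ones(80), d["Temperature"], d["SWC"]])
        beta_ols, *_ = np.linalg.lstsq(X, d["response"].to_numpy(), rcond=None)
        np.testing.assert_allclose(gls.coefficients["estimate"], beta_ols, atol=1e-6)
        assert gls.phi == 0.0

    def test_recovers_coefficients_and_phi_near_zero_noise(self):
        d = _data(n=150, seed=2, coefs={"intercept": 0.3, "Temperature": 0.6,
                                        "Temp*SWC": 0.2, "SWC": 0.1},
                  phi=0.0, sd=1e-6)
        res = fit_gls(ModelSpec("response", ("Temperature", "SWC", "Temp*SWC")), d)
        est = res.coefficients["estimate"]
        assert est["(Intercept)"] == pytest.approx(0.3, abs=1e-3)
        assert est["Temperature"] == pytest.approx(0.6, abs=1e-3)
        assert est["Temp*SWC"] == pytest.approx(0.2, abs=1e-3)
        assert abs(res.phi) < 0.3  # phi is weakly identified at sd -> 0

    def test_recovers_ar1_parameter(self):
        d = _data(n=400, seed=3, coefs={"Temperature": 0.5}, phi=0.6, sd=0.5)
        res = fit_gls(ModelSpec("response", ("Temperature",)), d)
        assert res.phi == pytest.approx(0.6, abs=0.12)

    def test_aicc_formula(self):
        # logLik = -10, k = 3, n = 20 -> AIC 26, AICc 26 + 24/16 = 27.5
        assert aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_aicc_approaches_aic_for_large_n(self):
        assert aicc(-10.0, 3, 10_000) == pytest.approx(26.0, abs=0.01)

    def test_adj_r2_at_most_one(self):
        d = _data(n=60, seed=4, coefs={"Temperature": 1.0}, sd=0.01)
        res = fit_gls(ModelSpec("response", ("Temperature",)), d)
        assert res.adj_r2 <= 1.0
        assert res.adj_r2 > 0.99

    def test_hierarchy_enforced_in_spec(self):
        with pytest.raises(ValueError, match="hierarchy"):
            ModelSpec("response", ("Temperature", "Temp*SWC"))


class TestSelection:
    def test_enumeration_is_hierarchy_complete(self):
        models = enumerate_model_terms()
        # brute-force oracle: all subsets of the 6 terms that respect hierarchy
        import itertools
        all_terms = ["Temperature", "SWC", "SF"] + list(INTERACTIONS)
        valid = 0
        for r in range(7):
            for sub in itertools.combinations(all_terms, r):
                ok = all(
                    INTERACTIONS[t][0] in sub and INTERACTIONS[t][1] in sub
                    for t in sub if t in INTERACTIONS
                )
                valid += ok
        assert len(models) == valid == 18
        assert () in models  # intercept-only included

    def test_strong_single_driver_selected(self):
        d = _data(n=100, seed=5, coefs={"Temperature": 1.0}, phi=0.4, sd=0.3)
        sel = enumerate_and_select("response", d)
        assert "Temperature" in sel.selected.spec.terms
        assert sel.significant

    def test_interaction_truth_keeps_both_mains(self):
        d = _data(n=120, seed=6, coefs={"Temperature": 0.5, "SWC": 0.4,
                                        "Temp*SWC": 0.5}, sd=0.3)
        sel = enumerate_and_select("response", d)
        if "Temp*SWC" in sel.selected.spec.terms:
            assert {"Temperature", "SWC"} <= set(sel.selected.spec.terms)

    def test_window_prefers_more_complex_model(self):
        d = _data(n=100, seed=7, coefs={"Temperature": 1.0}, sd=0.3)
        sel = enumerate_and_select("response", d)
        window = sel.candidates[sel.candidates.in_window]
        assert sel.selected.spec.terms and len(sel.selected.spec.terms) == window.n_terms.max()

    def test_candidate_table_has_all_models(self):
        d = _data(n=100, seed=8, coefs={"Temperature": 0.8}, sd=0.4)
        sel = enumerate_and_select("response", d)
        assert len(sel.candidates) == 18
        assert sel.candidates.selected.sum() == 1


class TestSimpleRegressions:
    def test_exact_line(self):
        x = np.linspace(0, 10, 30)
        fit = fit_simple_regression(x, 2 * x + 1, "linear")
        assert fit.params[1] == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-10

    def test_exponential_recovery(self):
        x = np.linspace(5, 25, 40)
        fit = fit_simple_regression(x, 0.7 * np.exp(0.1 * x), "exponential")
        assert fit.params[1] == pytest.approx(0.1, abs=1e-4)
        assert fit.converged

    def test_sigmoidal_recovery(self):
        x = np.linspace(0, 30, 60)
        a, b, c, d = 2.0, 0.5, 15.0, -1.0
        y = d + (a - d) / (1 + np.exp(-b * (x - c)))
        fit = fit_simple_regression(x, y, "sigmoidal")
        np.testing.assert_allclose(fit.params, (a, b, c, d), atol=1e-3)

    def test_influential_point_screened(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 10, 40)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.1, 40)
        y[-1] += 30.0  # gross outlier at high leverage
        fit = fit_simple_regression(x, y, "linear")
        assert fit.n == 39
        assert fit.params[1] == pytest.approx(0.5, abs=0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_simple_regression([1, 2, 3], [1, 2, 3], "linear")


class TestCrossLocation:
    def test_identity_and_anti_identity(self):
        x = pd.Series(np.arange(30.0))
        out = cross_location_correlation(pd.DataFrame({"A": x, "B": x, "C": -x}))
        r = {(row.a, row.b): row.r for row in out.itertuples()}
        assert r[("A", "B")] == pytest.approx(1.0)
        assert r[("A", "C")] == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self, rng):
        a = pd.Series(rng.normal(size=30))
        b = pd.Series(rng.normal(size=30))
        out = cross_location_correlation(pd.DataFrame({"A": a, "B": b}))
        r_oracle = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        t_stat = r_oracle * np.sqrt(28 / (1 - r_oracle**2))
        from scipy import stats
        p_oracle = 2 * stats.t.sf(abs(t_stat), 28)
        row = out.iloc[0]
        assert row["r"] == pytest.approx(r_oracle, abs=1e-12)
        assert row["p"] == pytest.approx(p_oracle, rel=1e-9)

    def test_insufficient_overlap_gives_missing_cell(self):
        a = pd.Series([1.0, 2.0, np.nan, np.nan])
        b = pd.Series([np.nan, np.nan, 1.0, 2.0])
        out = cross_location_correlation(pd.DataFrame({"A": a, "B": b}))
        assert np.isnan(out.iloc[0]["r"])

    def test_star_codes(self):
        n = 200
        rng = np.random.default_rng(1)
        x = pd.Series(rng.normal(size=n))
        strong = x + 0.1 * pd.Series(rng.normal(size=n))
        out = cross_location_correlation(pd.DataFrame({"A": x, "B": strong}))
        assert out.iloc[0]["stars"] == "**"
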