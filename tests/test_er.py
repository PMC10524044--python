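"""Exposure-response models: logistic/ordinal fits, selection, elimination."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from bosutinib_pkpd import er


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(20230808)


def simulate_binary(rng, n, icpt, slope, mu=4.4, sd=0.5, metric="Ctrough"):
    x = rng.lognormal(mu, sd, n)
    y = (rng.random(n) < expit(icpt + slope * np.log(x))).astype(float)
    return y, pd.DataFrame({metric: x})


class TestComputeTTE:
    @pytest.mark.parametrize(
        "grade, day, expected",
        [(0, 366, 1.0), (3, 366, 365 / 366), (2, 1, 0.0), (1, 184, 0.5)],
    )
    def test_values(self, grade, day, expected):
        assert er.compute_tte(grade, day) == pytest.approx(expected, rel=1e-12)

    def test_grade0_is_exactly_one(self):
        assert er.compute_tte(0, 200) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            er.compute_tte(1, 0)
        with pytest.raises(ValueError):
            er.compute_tte(5, 10)


class TestAnchorCalibration:
    def test_curve_passes_through_anchors(self):
        icpt, slope = er.calibrate_logistic_from_anchors((90.7, 0.83), (67.9, 0.76))
        assert expit(icpt + slope * math.log(90.7)) == pytest.approx(0.83, abs=1e-12)
        assert expit(icpt + slope * math.log(67.9)) == pytest.approx(0.76, abs=1e-12)

    def test_known_solution(self):
        icpt, slope = er.calibrate_logistic_from_anchors((120.8, 0.94), (91.2, 0.87))
        assert slope == pytest.approx(3.026, abs=2e-3)
        assert icpt == pytest.approx(-11.756, abs=5e-3)


class TestBinaryFit:
    def test_recovers_known_coefficients(self, rng):
        y, m = simulate_binary(rng, 5000, -5.0, 1.5)
        fit = er.fit_binary_er(y, m, "Ctrough", "log")
        b1 = fit.coef("log(Ctrough)")
        se = fit.se("log(Ctrough)")
        assert abs(b1 - 1.5) < 1.96 * se

    def test_permuted_exposure_ci_covers_zero(self, rng):
        y, m = simulate_binary(rng, 3000, -5.0, 1.5)
        m_perm = m.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit = er.fit_binary_er(y, m_perm, "Ctrough", "log")
        b1, se = fit.coef("log(Ctrough)"), fit.se("log(Ctrough)")
        assert abs(b1) < 1.96 * se

    def test_deviance_matches_direct_optimizer(self, rng):
        y, m = simulate_binary(rng, 50, -4.0, 1.2)
        fit = er.fit_binary_er(y, m, "Ctrough", "log")
        X = np.column_stack([np.ones(50), np.log(m["Ctrough"])])

        def nll(b):
            eta = X @ b
            return -np.sum(y * eta - np.logaddexp(0.0, eta))

        direct = minimize(nll, np.zeros(2), method="BFGS").fun
        assert fit.deviance == pytest.approx(2 * direct, abs=1e-6)

    def test_single_class_rejected(self, rng):
        m = pd.DataFrame({"Cavg": rng.lognormal(4.6, 0.4, 100)})
        with pytest.raises(ValueError):
            er.fit_binary_er(np.ones(100), m, "Cavg")

    def test_odds_ratio_scale(self, rng):
        # data generated at OR 1.3 per ln-unit: exp(b1) recovered in [1.2, 1.4]
        y, m = simulate_binary(rng, 10_000, 0.0, math.log(1.3), mu=4.5, sd=1.0)
        fit = er.fit_binary_er(y, m, "Ctrough", "log")
        assert 1.2 < math.exp(fit.coef("log(Ctrough)")) < 1.4


class TestOrdinalFit:
    @staticmethod
    def simulate_ordinal(rng, n, slope, taus=(-1.0, 0.5, 1.5, 2.5)):
        x = rng.lognormal(4.6, 0.5, n)
        eta = slope * (np.log(x) - 4.6)
        z = eta + rng.logistic(size=n)
        g = (z[:, None] > np.asarray(taus)[None, :]).sum(axis=1)
        return g, pd.DataFrame({"Cavg": x, "tte": rng.random(n)})

    def test_slope_recovery(self, rng):
        g, m = self.simulate_ordinal(rng, 5000, 0.9)
        fit = er.fit_ordinal_er(g, m, "Cavg", "log", include_tte=False)
        b, se = fit.coef("log(Cavg)"), fit.se("log(Cavg)")
        assert abs(b - 0.9) < 1.96 * se

    def test_probabilities_sum_to_one_and_thresholds_increase(self, rng):
        g, m = self.simulate_ordinal(rng, 2000, 0.8)
        fit = er.fit_ordinal_er(g, m, "Cavg", "log")
        assert np.all(np.diff(fit.thresholds) > 0)
        probs = er.predict_probability(fit, {"Cavg": np.array([50.0, 100.0, 200.0]), "tte": 0.5})
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-12)

    def test_tte_sign_property(self, rng):
        # later events (larger tte) push mass toward grade 0 when its slope < 0
        g, m = self.simulate_ordinal(rng, 3000, 0.8)
        z = 0.8 * (np.log(m["Cavg"]) - 4.6) - 2.0 * (m["tte"] - 0.5) + rng.logistic(size=3000)
        g2 = (np.asarray(z)[:, None] > np.array([-1.0, 0.5, 1.5, 2.5])[None, :]).sum(axis=1)
        fit = er.fit_ordinal_er(g2, m, "Cavg", "log", include_tte=True)
        tts = np.linspace(0.05, 0.95, 8)
        p0 = [er.predict_probability(fit, {"Cavg": 100.0, "tte": t})[0] for t in tts]
        assert np.all(np.diff(p0) > 0)

    def test_single_category_rejected(self):
        m = pd.DataFrame({"Cavg": np.ones(50) * 100.0, "tte": np.ones(50)})
        with pytest.raises(ValueError):
            er.fit_ordinal_er(np.zeros(50, dtype=int), m, "Cavg")


class TestBinaryFallback:
    def test_all_below_threshold_rejected(self, rng):
        m = pd.DataFrame({"Cavg": rng.lognormal(4.6, 0.4, 200)})
        grades = rng.integers(0, 3, 200)  # nothing above grade 2
        with pytest.raises(ValueError):
            er.binary_fallback(grades, m, 2, "Cavg")

    def test_printed_equation_evaluation(self):
        # logit(p) = -1.5 - 0.06 ln(BPLTS) - 0.03 age + 0.008 Cavg28
        eta = -1.5 - 0.06 * math.log(386.0) - 0.03 * 48.0 + 0.008 * 100.9
        assert expit(eta) == pytest.approx(0.076, abs=0.001)

    def test_thrombocytopenia_coefficient_recovery(self, rng):
        n = 5000  # large n for a tight unit-level check
        bplts = rng.lognormal(math.log(390.0), 0.45, n)
        age = np.clip(rng.normal(51, 14, n), 18, 91)
        cavg = rng.lognormal(math.log(100.0), 0.4, n)
        p = expit(-1.5 - 0.06 * np.log(bplts) - 0.03 * age + 0.008 * cavg)
        grades = np.where(rng.random(n) < p, 3, 0)
        m = pd.DataFrame({"Cavg28": cavg, "bplts": bplts, "age": age})
        fit = er.fit_thrombocytopenia(grades, m)
        b, se = fit.coef("Cavg28"), fit.se("Cavg28")
        assert abs(b - 0.008) < 1.96 * se


class TestSelectMetric:
    def test_generating_metric_selected(self, rng):
        n = 1500
        hits = 0
        reps = 50
        for _ in range(reps):
            base = rng.lognormal(4.4, 0.8, n)
            m = pd.DataFrame({
                "Ctrough": base,
                "Cavg": base * rng.lognormal(0.2, 0.6, n),
                "cAUC": rng.lognormal(6.0, 0.6, n),
            })
            y = (rng.random(n) < expit(-6.0 + 1.4 * np.log(m["Ctrough"]))).astype(float)
            best = er.select_metric(y, m, candidates=("cAUC", "Cavg", "Ctrough"))
            hits += best.metric == "Ctrough" and best.transform == "log"
        assert hits / reps >= 0.9

    def test_tie_break_prefers_documented_order(self, rng):
        x = rng.lognormal(4.4, 0.5, 300)
        m = pd.DataFrame({"Cavg": x, "Ctrough": x})  # identical columns
        y = (rng.random(300) < expit(-5.0 + 1.2 * np.log(x))).astype(float)
        best = er.select_metric(y, m, candidates=("Cavg", "Ctrough"))
        assert best.metric == "Cavg"

    def test_log_beats_linear_on_log_truth(self, rng):
        y, m = simulate_binary(rng, 4000, -5.15, 1.5, sd=0.7)
        flog = er.fit_binary_er(y, m, "Ctrough", "log")
        flin = er.fit_binary_er(y, m, "Ctrough", "linear")
        assert flog.deviance < flin.deviance

    def test_requires_two_candidates(self, rng):
        y, m = simulate_binary(rng, 100, -5.0, 1.5)
        with pytest.raises(ValueError):
            er.select_metric(y, m, candidates=("Ctrough",))


class TestBackwardElimination:
    def test_noise_covariates_removed(self, rng):
        n = 1000
        removed_all = 0
        reps = 100
        for _ in range(reps):
            x = rng.lognormal(4.4, 0.5, n)
            m = pd.DataFrame({
                "Ctrough": x,
                "noise1": rng.standard_normal(n),
                "noise2": rng.standard_normal(n),
            })
            y = (rng.random(n) < expit(-5.0 + 1.2 * np.log(x))).astype(float)
            fit = er.backward_eliminate(y, m, "Ctrough", "log", ("noise1", "noise2"), alpha=0.01)
            removed_all += not ({"noise1", "noise2"} & set(fit.exog_names))
        assert removed_all / reps >= 0.95

    def test_strong_covariate_retained(self, rng):
        n = 2000
        x = rng.lognormal(4.4, 0.5, n)
        c = rng.standard_normal(n)
        y = (rng.random(n) < expit(-5.0 + 1.2 * np.log(x) + 1.0 * c)).astype(float)
        m = pd.DataFrame({"Ctrough": x, "strong": c, "noise": rng.standard_normal(n)})
        fit = er.backward_eliminate(y, m, "Ctrough", "log", ("strong", "noise"), alpha=0.01)
        assert "strong" in fit.exog_names
        assert "noise" not in fit.exog_names

    def test_empty_candidates_returns_base(self, rng):
        y, m = simulate_binary(rng, 500, -5.0, 1.5)
        fit = er.backward_eliminate(y, m, "Ctrough", "log", ())
        assert fit.exog_names == ["const", "log(Ctrough)"]

    def test_exposure_term_never_removed(self, rng):
        # null exposure: still present in the final model
        x = rng.lognormal(4.4, 0.5, 800)
        y = (rng.random(800) < 0.5).astype(float)
        m = pd.DataFrame({"Ctrough": x, "noise": rng.standard_normal(800)})
        fit = er.backward_eliminate(y, m, "Ctrough", "log", ("noise",), alpha=0.01)
        assert "log(Ctrough)" in fit.exog_names


class TestPredictProbability:
    def test_null_model_is_half(self):
        fit = er.ERModelFit(
            family="binary", exog_names=["const", "log(Ctrough)"],
            params=np.array([0.0, 0.0]), deviance=0.0,
            cov_params=np.eye(2), metric="Ctrough", transform="log",
        )
        assert er.predict_probability(fit, {"Ctrough": 123.0}) == 0.5

    def test_round_trip_prediction_matches_truth(self, rng):
        icpt, slope = er.calibrate_logistic_from_anchors((120.8, 0.94), (91.2, 0.87))
        y, m = simulate_binary(rng, 10_000, icpt, slope, mu=4.65, sd=0.45, metric="Cavg")
        fit = er.fit_binary_er(y, m, "Cavg", "log")
        assert er.predict_probability(fit, {"Cavg": 120.8}) == pytest.approx(0.94, abs=0.02)
        assert er.predict_probability(fit, {"Cavg": 91.2}) == pytest.approx(0.87, abs=0.02)
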