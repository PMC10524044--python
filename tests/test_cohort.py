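"""Virtual-cohort generator: marginals, determinism, outcome calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import chi2_contingency

from bosutinib_pkpd import cohort as ch
from bosutinib_pkpd import er


@pytest.fixture(scope="module")
def bela(pop):
    return ch.generate_cohort("BELA", seed=7, pop=pop)


@pytest.fixture(scope="module")
def bela_exposures(bela, pop):
    return ch.steady_state_exposures(bela, pop)


class TestCovariates:
    @pytest.mark.parametrize("name", ["BELA", "BFORE", "B1871048"])
    def test_medians_and_ranges(self, pop, name):
        tmpl = ch.TEMPLATES[name]
        subs = ch.generate_cohort(tmpl, seed=31, pop=pop)
        assert len(subs) == tmpl.n
        for attr, marg in (("age", tmpl.age), ("weight", tmpl.weight),
                           ("bccl", tmpl.bccl), ("platelets", tmpl.platelets)):
            v = np.array([getattr(s.covariates, attr) for s in subs])
            assert marg.lo <= v.min() and v.max() <= marg.hi
            assert abs(np.median(v) / marg.median - 1.0) < 0.10

    def test_bela_median_weight_bracket(self, bela):
        wts = [s.covariates.weight for s in bela]
        assert 62.0 <= np.median(wts) <= 76.0

    def test_asian_fractions(self, pop):
        jp = ch.generate_cohort("B1871048", seed=1, pop=pop)
        assert all(s.covariates.asian == 1 for s in jp)

    def test_determinism(self, pop):
        a = ch.generate_cohort("BELA", seed=42, pop=pop, n=1)
        b = ch.generate_cohort("BELA", seed=42, pop=pop, n=1)
        assert a[0].covariates == b[0].covariates
        assert a[0].eta == b[0].eta
        assert np.array_equal(a[0].dose_by_day, b[0].dose_by_day)


class TestDosingAndSampling:
    def test_dose_levels_confined(self, pop):
        for name in ("BELA", "BFORE", "B1871048"):
            subs = ch.generate_cohort(name, seed=3, pop=pop)
            doses = np.unique(np.concatenate([s.dose_by_day for s in subs]))
            assert set(doses).issubset({200.0, 300.0, 400.0, 500.0, 600.0})

    def test_sampling_schedules(self, pop):
        assert all(len(s.obs_times) == 8 for s in ch.generate_cohort("BELA", seed=2, pop=pop, n=20))
        for name in ("BFORE", "B1871048"):
            subs = ch.generate_cohort(name, seed=2, pop=pop, n=20)
            assert all(len(s.obs_times) == 4 for s in subs)
            # all samples are pre-dose draws (taken just before a scheduled dose)
            for s in subs:
                assert all(t == 0.0 or (t % 24.0) > 23.9 for t in s.obs_times)

    def test_event_records_shape(self, pop):
        subs = ch.generate_cohort("BELA", seed=2, pop=pop, n=5)
        df = ch.simulate_observations(subs, pop, seed=9)
        assert set(df["EVID"]) == {0, 1}
        assert (df[df["EVID"] == 0].groupby("ID").size() == 8).all()
        assert (df[df["EVID"] == 1].groupby("ID").size() == 366).all()


class TestExposureCalibration:
    def test_500mg_stratum_geometric_means(self, bela, bela_exposures):
        doses = np.array([s.dose_by_day[-1] for s in bela])
        at500 = bela_exposures[doses == 500.0]
        gm_tr = float(np.exp(np.mean(np.log(at500["ss_trough"]))))
        gm_ca = float(np.exp(np.mean(np.log(at500["ss_cavg"]))))
        assert gm_tr == pytest.approx(90.7, rel=0.05)
        assert gm_ca == pytest.approx(120.8, rel=0.05)


class TestEfficacyAssignment:
    def test_zero_slope_rate(self, pop, bela, bela_exposures, monkeypatch):
        monkeypatch.setattr(ch, "MMR_ANCHORS", ((100.0, 0.7), (100.0 * np.e, 0.7)))
        occ = ch.assign_efficacy(bela, bela_exposures, seed=5, endpoint="MMR")
        rate = np.mean([o.response for o in occ])
        assert rate == pytest.approx(0.7, abs=0.06)

    def test_bela_mmr_rate_matches_curve_average(self, bela, bela_exposures):
        occ = ch.assign_efficacy(bela, bela_exposures, seed=11, endpoint="MMR")
        rate = np.mean([o.response for o in occ])
        icpt, slope = er.calibrate_logistic_from_anchors(*ch.MMR_ANCHORS)
        expected = float(np.mean(expit(icpt + slope * np.log(bela_exposures["ss_trough"]))))
        sd = np.sqrt(expected * (1 - expected) / len(bela))
        assert abs(rate - expected) < 3.5 * sd
        assert 0.64 <= rate <= 0.80  # brackets the observed BELA MMR rate

    def test_responder_times_in_window(self, bela, bela_exposures):
        occ = ch.assign_efficacy(bela, bela_exposures, seed=11, endpoint="MMR")
        for o in occ:
            if o.response:
                assert 90 * 24.0 <= o.response_time <= ch.YEAR_H
            else:
                assert o.response_time == ch.YEAR_H

    def test_ph_positive_flag_for_ccyr(self, pop):
        subs = []
        for i, seed in enumerate((1, 2, 3)):
            subs += ch.generate_cohort(["BELA", "BFORE", "B1871048"][i], seed=seed,
                                       pop=pop, id_offset=1000 * i)
        exp = ch.steady_state_exposures(subs, pop)
        occ = ch.assign_efficacy(subs, exp, seed=4, endpoint="CCyR")
        frac = np.mean([o.ph_positive for o in occ])
        assert frac == pytest.approx(ch.PH_POS_FRACTION, abs=0.03)


class TestAEAssignment:
    def test_diarrhea_marginals(self, bela, bela_exposures):
        aes = ch.assign_ae_grades(bela, bela_exposures, seed=13)
        g = np.array([a.grade for a in aes if a.ae == "diarrhea"])
        frac1 = np.mean(g == 1)
        frac0 = np.mean(g == 0)
        assert frac1 == pytest.approx(0.413, abs=0.02)
        assert frac0 == pytest.approx(0.293, abs=0.02)

    def test_grade0_lands_on_landmark_day(self, bela, bela_exposures):
        aes = ch.assign_ae_grades(bela, bela_exposures, seed=13)
        for a in aes:
            assert (a.event_day == 366) if a.grade == 0 else (1 <= a.event_day <= 366)

    def test_exposure_dependence_null_when_slope_zero(self, pop, bela, bela_exposures, monkeypatch):
        gens = dict(ch.AE_GENERATORS)
        gens["diarrhea"] = ("ss_cavg", "log", 0.0, 0.0)
        monkeypatch.setattr(ch, "AE_GENERATORS", gens)
        # a large cohort so the test is about independence, not power
        subs = ch.generate_cohort("BFORE", seed=23, pop=pop, n=5000)
        exp = ch.steady_state_exposures(subs, pop)
        aes = [a for a in ch.assign_ae_grades(subs, exp, seed=29, ae_names=("diarrhea",))]
        g = np.array([a.grade for a in aes])
        x = exp["ss_cavg"].to_numpy()
        tert = np.digitize(x, np.quantile(x, [1 / 3, 2 / 3]))
        table = pd.crosstab(tert, np.minimum(g, 3))
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_thrombocytopenia_prevalence_matches_equation(self, pop):
        subs = ch.generate_cohort("BFORE", seed=17, pop=pop, n=5000)
        exp = ch.steady_state_exposures(subs, pop)
        aes = ch.assign_ae_grades(subs, exp, seed=19, ae_names=("thrombocytopenia",))
        g = np.array([a.grade for a in aes])
        c = ch.THROMBO_COEFS
        bplts = np.array([s.covariates.platelets for s in subs])
        age = np.array([s.covariates.age for s in subs])
        cavg = exp["ss_cavg"].to_numpy()
        expected = float(np.mean(expit(
            c["const"] + c["log_bplts"] * np.log(bplts) + c["age"] * age + c["cavg28"] * cavg)))
        observed = float(np.mean(g > 2))
        assert observed == pytest.approx(expected, abs=3.5 * np.sqrt(expected * (1 - expected) / 5000))

    def test_threshold_calibration_is_exact_in_expectation(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(0, 1.2, 20_000)
        taus = ch.calibrate_ordinal_thresholds(eta, ch.DIARRHEA_MARGINALS)
        assert np.all(np.diff(taus) > 0)
        cum = [float(np.mean(expit(t - eta))) for t in taus]
        np.testing.assert_allclose(cum, np.cumsum(ch.DIARRHEA_MARGINALS)[:-1], atol=1e-9)
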