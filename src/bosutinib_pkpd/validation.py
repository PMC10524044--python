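"""Calibration round-trips and parameter-recovery studies.

These routines define the package's validation study conditions:

* exposure-response round trips: simulate a large cohort from the
  anchor-calibrated efficacy curves, refit by maximum likelihood and predict
  back at the anchor exposures;
* thrombocytopenia recovery: simulate Grade>2 events from the published
  logistic equation over generator covariates and recover its exposure
  coefficient;
* mixed-effects recovery: simulate rich-sampled concentration data at the
  reported population parameters and recover the typical clearance;
* adverse-event marginals: realized worst-grade distribution of the pooled
  safety cohort.

Each function is deterministic given its seed and returns plain dicts, so
the same entry points back both the acceptance checks and user-facing
reproduction runs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import cohort as ch
from . import er
from .exposure import DAY28_H, cavg_from_cauc, cumulative_auc
from .nlme import fit_population
from .params import PopulationPKParameters, REFERENCE_COVARIATES, default_parameters, individualize
from .pk import add_residual_error, concentration_at, qd_doses

__all__ = [
    "er_round_trip",
    "thrombocytopenia_recovery",
    "nlme_cl_recovery",
    "pooled_safety_cohort",
    "diarrhea_grade_marginals",
    "renal_effect_percents",
    "simulate_rich_pk_dataset",
]

# Lognormal spread of simulated exposures in the round trips (approximately
# the ~40% CV of the derived exposure metrics in the analysis population).
ROUND_TRIP_SDLOG = 0.4


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def er_round_trip(endpoint: str = "MMR", n: int = 10_000, seed: int = 0) -> dict:
    """Generator -> refit -> predict round trip for one efficacy endpoint.

    Half the virtual cohort is centred at each printed geometric-mean
    exposure (the 500-mg and 400-mg starting-dose populations); responses are
    Bernoulli draws from the anchor-calibrated curve.  Returns the refit
    predictions at the anchor exposures (as probabilities in [0, 1]).
    """
    anchors = ch.MMR_ANCHORS if endpoint == "MMR" else ch.CCYR_ANCHORS
    metric = "Ctrough" if endpoint == "MMR" else "Cavg"
    icpt, slope = er.calibrate_logistic_from_anchors(*anchors)
    rng = np.random.default_rng(seed)
    (gm1, _), (gm2, _) = anchors
    x = np.concatenate([
        rng.lognormal(np.log(gm1), ROUND_TRIP_SDLOG, n // 2),
        rng.lognormal(np.log(gm2), ROUND_TRIP_SDLOG, n - n // 2),
    ])
    y = (rng.random(n) < expit(icpt + slope * np.log(x))).astype(float)
    fit = er.fit_binary_er(y, pd.DataFrame({metric: x}), metric, "log")
    return {
        "fit": fit,
        "predictions": {gm: float(er.predict_probability(fit, {metric: gm}))
                        for gm, _ in anchors},
    }


def pooled_safety_cohort(seed: int, pop: PopulationPKParameters | None = None):
    """The pooled 574-patient safety population across the three templates."""
    if pop is None:
        pop = default_parameters()
    seeds = _child_seeds(seed, 3)
    subjects = []
    # template n gives 573 evaluable efficacy patients; the safety population
    # is 574, carried by one extra 400-mg starting-dose subject
    for i, (name, n) in enumerate((("BELA", 247), ("BFORE", 267), ("B1871048", 60))):
        subjects += ch.generate_cohort(name, seed=seeds[i], pop=pop, n=n,
                                       id_offset=1000 * (i + 1))
    return subjects


def _day28_cavg(subjects, pop) -> np.ndarray:
    out = np.empty(len(subjects))
    for i, s in enumerate(subjects):
        ind = s.individual(pop)
        out[i] = cavg_from_cauc(cumulative_auc(ind, pop, s.doses(), DAY28_H), DAY28_H)
    return out


def thrombocytopenia_recovery(seed: int = 0, pop: PopulationPKParameters | None = None) -> dict:
    """Simulate Grade>2 events from the published equation; refit the model.

    Covariates (baseline platelets, age) and Day-28 average concentration
    come from the pooled 574-patient generator; the recovered Cavg28
    coefficient and its Wald SE are returned.
    """
    if pop is None:
        pop = default_parameters()
    s_cohort, s_event = _child_seeds(seed, 2)
    subjects = pooled_safety_cohort(s_cohort, pop)
    cavg28 = _day28_cavg(subjects, pop)
    bplts = np.array([s.covariates.platelets for s in subjects])
    age = np.array([s.covariates.age for s in subjects])
    c = ch.THROMBO_COEFS
    p = expit(c["const"] + c["log_bplts"] * np.log(bplts) + c["age"] * age
              + c["cavg28"] * cavg28)
    rng = np.random.default_rng(s_event)
    grades = np.where(rng.random(len(subjects)) < p, 3, 0)
    m = pd.DataFrame({"Cavg28": cavg28, "bplts": bplts, "age": age})
    fit = er.fit_thrombocytopenia(grades, m)
    return {"coef": fit.coef("Cavg28"), "se": fit.se("Cavg28"),
            "n": len(subjects), "events": int((grades > 2).sum())}


RICH_TIMES = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 25.0, 30.0, 48.0)


def simulate_rich_pk_dataset(pop: PopulationPKParameters, n: int, seed: int) -> pd.DataFrame:
    """Event records for n subjects: 400 mg QD x2, 11 samples over 48 h."""
    rng = np.random.default_rng(seed)
    rows = []
    times = np.asarray(RICH_TIMES)
    for i in range(n):
        eta = rng.normal(0.0, [pop.omega_CL, pop.omega_V2, pop.omega_ka])
        ind = individualize(pop, REFERENCE_COVARIATES, eta)
        doses = qd_doses([400.0, 400.0])
        for d in doses:
            rows.append(dict(ID=i + 1, TIME=d.time, AMT=d.amount, DV=np.nan,
                             EVID=1, ROUTE="oral"))
        pred = concentration_at(ind, pop, doses, times)
        obs = add_residual_error(pred, "oral", pop, rng.standard_normal(times.size))
        for t, o in zip(times, obs):
            rows.append(dict(ID=i + 1, TIME=float(t), AMT=0.0, DV=float(o),
                             EVID=0, ROUTE="oral"))
    return pd.DataFrame(rows)


def nlme_cl_recovery(seed: int = 0, n_subjects: int = 100, n_seeds: int = 3,
                     pop: PopulationPKParameters | None = None) -> dict:
    """Median recovered typical clearance over replicate simulated studies."""
    if pop is None:
        pop = default_parameters()
    init = replace(pop, CL_typ=pop.CL_typ * 1.5, V2_typ=pop.V2_typ * 1.5, ka=pop.ka * 1.5)
    cls = []
    for s in _child_seeds(seed, n_seeds):
        df = simulate_rich_pk_dataset(pop, n_subjects, s)
        res = fit_population(df, init)
        cls.append(res.params["CL_typ"])
    return {"cl_estimates": cls, "cl_median": float(np.median(cls)), "n": n_subjects}


def diarrhea_grade_marginals(seed: int = 0, pop: PopulationPKParameters | None = None) -> dict:
    """Worst-grade diarrhea distribution of a pooled 574-patient cohort."""
    if pop is None:
        pop = default_parameters()
    s_cohort, s_ae = _child_seeds(seed, 2)
    subjects = pooled_safety_cohort(s_cohort, pop)
    exposures = ch.steady_state_exposures(subjects, pop)
    aes = ch.assign_ae_grades(subjects, exposures, seed=s_ae, ae_names=("diarrhea",))
    g = np.array([a.grade for a in aes])
    return {"fractions": {k: float(np.mean(g == k)) for k in range(5)}, "n": len(g)}


def renal_effect_percents(pop: PopulationPKParameters | None = None) -> dict:
    """Percent decreases in CL at the renal-impairment landmarks, from the
    power model calibrated to the moderate-impairment anchor."""
    from .params import covariate_effect_percent

    if pop is None:
        pop = default_parameters()
    return {bccl: -covariate_effect_percent(pop, "bccl", bccl) for bccl in (75.0, 45.0, 22.0, 15.0)}
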