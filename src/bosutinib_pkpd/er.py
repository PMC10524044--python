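"""Exposure-response models for efficacy and graded adverse events.

Efficacy (cumulative MMR / CCyR) uses binary logistic regression of response
on a single exposure metric (linear or log scale) plus optional covariates,
with the best metric chosen by lowest deviance and covariates pruned by
backward elimination.  Safety uses proportional-odds ordinal regression of
the worst first-year CTCAE grade (0-4) on exposure plus a time-to-event
covariate, with a binary Grade>threshold fallback when the ordinal exposure
term is not significant.

Model fits are maximum likelihood via statsmodels (Logit / OrderedModel);
this module owns the modelling conventions: natural log by default for
"log"-transformed exposure (a log10 switch is provided), the exposure term
never a candidate for elimination, and the proportional-odds convention
P(grade <= g) = expit(tau_g - x*beta), so positive slopes push probability
mass toward higher grades.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "ERModelFit",
    "compute_tte",
    "calibrate_logistic_from_anchors",
    "fit_binary_er",
    "fit_ordinal_er",
    "binary_fallback",
    "fit_thrombocytopenia",
    "select_metric",
    "backward_eliminate",
    "predict_probability",
    "AE_NAMES",
    "EXPOSURE_METRICS",
]

AE_NAMES = (
    "diarrhea",
    "nausea",
    "vomiting",
    "rash",
    "alt",
    "ast",
    "thrombocytopenia",
    "neutropenia",
)

# Documented fixed order; also the tie-break order in select_metric.
EXPOSURE_METRICS = ("cAUC", "Cavg", "Ctrough", "cAUC28", "Cavg28", "Ctrough28")

YEAR_DAYS = 366


def compute_tte(grade: int, event_day: int) -> float:
    """Time-to-event covariate: (day before the worst-grade AE) / 366.

    Patients with no event (grade 0) are set to the one-year landmark
    366/366 = 1 exactly.
    """
    if not 0 <= grade <= 4:
        raise ValueError("grade must be in 0..4")
    if grade == 0:
        return 1.0
    if not 1 <= event_day <= YEAR_DAYS:
        raise ValueError("event_day must be in 1..366")
    return (event_day - 1) / YEAR_DAYS


def calibrate_logistic_from_anchors(anchor1, anchor2, log_exposure: bool = True):
    """Intercept and slope of a logistic curve through two (exposure, p) pairs.

    With ``log_exposure`` the linear predictor is in ln(exposure).  This is
    the two-point solve used to turn printed (geometric-mean, probability)
    pairs into a generating curve.
    """
    (x1, p1), (x2, p2) = anchor1, anchor2
    g1 = math.log(x1) if log_exposure else x1
    g2 = math.log(x2) if log_exposure else x2
    if g1 == g2:
        raise ValueError("anchor exposures must differ")
    slope = (logit(p1) - logit(p2)) / (g1 - g2)
    intercept = logit(p1) - slope * g1
    return float(intercept), float(slope)


@dataclass
class ERModelFit:
    """A fitted exposure-response model."""

    family: str  # "binary" | "ordinal"
    exog_names: list
    params: np.ndarray
    deviance: float
    cov_params: np.ndarray
    metric: str
    transform: str  # "linear" | "log"
    thresholds: np.ndarray | None = None  # ordinal cut points, strictly increasing
    pvalues: dict = field(default_factory=dict)
    bse: dict = field(default_factory=dict)
    converged: bool = True
    log_base: str = "e"  # "e" | "10"
    notes: list = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.params[self.exog_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[name])


def _transform(x, transform: str, log_base: str = "e"):
    x = np.asarray(x, dtype=float)
    if transform == "linear":
        return x
    if transform == "log":
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive exposure")
        return np.log(x) if log_base == "e" else np.log10(x)
    raise ValueError("transform must be 'linear' or 'log'")


def _exposure_col_name(metric: str, transform: str) -> str:
    return metric if transform == "linear" else f"log({metric})"


def _build_design(metrics: pd.DataFrame, metric: str, transform: str,
                  covariates=(), log_base: str = "e") -> pd.DataFrame:
    X = pd.DataFrame(index=metrics.index)
    X[_exposure_col_name(metric, transform)] = _transform(metrics[metric], transform, log_base)
    for c in covariates:
        X[c] = np.asarray(metrics[c], dtype=float)
    return X


def fit_binary_er(
    outcomes,
    metrics: pd.DataFrame,
    metric: str,
    transform: str = "log",
    covariates=(),
    log_base: str = "e",
) -> ERModelFit:
    """Maximum-likelihood binary logistic fit: logit(p) = b0 + b1*g(metric) + ...

    ``outcomes`` is a 0/1 array aligned with ``metrics``.  Complete
    separation is detected and reported on the fit (``converged=False`` with
    a note) rather than raised.
    """
    y = np.asarray(outcomes, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = _build_design(metrics, metric, transform, covariates, log_base)
    exog = sm.add_constant(X, has_constant="add")
    notes = []
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        except PerfectSeparationWarning:
            notes.append("complete separation detected")
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, exog).fit(disp=0, maxiter=50)
    if not res.mle_retvals.get("converged", True):
        converged = False
        notes.append("optimizer did not converge")
    return ERModelFit(
        family="binary",
        exog_names=list(exog.columns),
        params=np.asarray(res.params, dtype=float),
        deviance=float(-2.0 * res.llf),
        cov_params=np.asarray(res.cov_params(), dtype=float),
        metric=metric,
        transform=transform,
        pvalues=dict(zip(exog.columns, np.asarray(res.pvalues, dtype=float))),
        bse=dict(zip(exog.columns, np.asarray(res.bse, dtype=float))),
        converged=converged,
        log_base=log_base,
        notes=notes,
    )


def fit_ordinal_er(
    grades,
    metrics: pd.DataFrame,
    metric: str,
    transform: str = "linear",
    include_tte: bool = True,
    baseline_lab: str | None = None,
    log_base: str = "e",
) -> ERModelFit:
    """Proportional-odds fit of grades 0-4 on exposure (+ tte, + baseline lab).

    Requires a ``tte`` column in ``metrics`` when ``include_tte``.  Grade
    levels absent from the data are collapsed (with a warning); at least two
    levels must remain.
    """
    g = np.asarray(grades, dtype=int)
    levels = np.unique(g)
    if levels.size < 2:
        raise ValueError("at least two grade levels must be present")
    if levels.size < 5:
        warnings.warn("empty grade categories collapsed", stacklevel=2)
    covs = []
    if include_tte:
        covs.append("tte")
    if baseline_lab is not None:
        covs.append(baseline_lab)
    X = _build_design(metrics, metric, transform, covs, log_base)
    endog = pd.Categorical(g, categories=levels, ordered=True)
    mod = OrderedModel(endog, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mod.fit(method="bfgs", disp=0, maxiter=500)
    k = X.shape[1]
    params = np.asarray(res.params[:k], dtype=float)
    thresholds = np.asarray(mod.transform_threshold_params(res.params)[1:-1], dtype=float)
    return ERModelFit(
        family="ordinal",
        exog_names=list(X.columns),
        params=params,
        deviance=float(-2.0 * res.llf),
        cov_params=np.asarray(res.cov_params(), dtype=float)[:k, :k],
        metric=metric,
        transform=transform,
        thresholds=thresholds,
        pvalues=dict(zip(X.columns, np.asarray(res.pvalues[:k], dtype=float))),
        bse=dict(zip(X.columns, np.asarray(res.bse[:k], dtype=float))),
        converged=bool(res.mle_retvals.get("converged", True)),
        log_base=log_base,
        notes=[f"grade levels present: {levels.tolist()}"],
    )


def binary_fallback(
    grades,
    metrics: pd.DataFrame,
    grade_threshold: int,
    metric: str,
    transform: str = "linear",
    covariates=(),
    log_base: str = "e",
) -> ERModelFit:
    """Dichotomize at Grade > threshold and fit binary logistic.

    Used when the ordinal exposure term is not significant.  Raises if only
    one class remains after dichotomization.
    """
    if grade_threshold not in (0, 1, 2):
        raise ValueError("grade_threshold must be 0, 1 or 2")
    y = (np.asarray(grades, dtype=int) > grade_threshold).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"no events above grade {grade_threshold}; cannot fit")
    fit = fit_binary_er(y, metrics, metric, transform, covariates, log_base)
    fit.notes.append(f"binary fallback at grade > {grade_threshold}")
    return fit


def fit_thrombocytopenia(
    grades,
    metrics: pd.DataFrame,
    log_base: str = "e",
) -> ERModelFit:
    """Grade>2 thrombocytopenia model: logit(p) ~ log(BPLTS) + age + Cavg28.

    ``metrics`` must carry ``bplts`` and ``age`` columns alongside Cavg28.
    The baseline-platelet term uses the natural log by default; ``log_base``
    switches to base 10.
    """
    m = metrics.copy()
    m["log(BPLTS)"] = _transform(m["bplts"], "log", log_base)
    return binary_fallback(
        grades, m, grade_threshold=2, metric="Cavg28", transform="linear",
        covariates=("log(BPLTS)", "age"), log_base=log_base,
    )


def select_metric(
    outcomes,
    metrics: pd.DataFrame,
    family: str = "binary",
    candidates=EXPOSURE_METRICS,
    transforms=("linear", "log"),
    **fit_kwargs,
):
    """Fit every candidate metric x transform and return the lowest-deviance fit.

    Ties (within 1e-9) go to the model appearing first in the documented
    order: metrics in ``EXPOSURE_METRICS`` order, 'linear' before 'log'.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate metrics")
    fitter = fit_binary_er if family == "binary" else fit_ordinal_er
    best = None
    for metric in candidates:
        for transform in transforms:
            try:
                fit = fitter(outcomes, metrics, metric=metric, transform=transform, **fit_kwargs)
            except ValueError:
                continue
            if best is None or fit.deviance < best.deviance - 1e-9:
                best = fit
    if best is None:
        raise ValueError("no candidate model could be fitted")
    return best


def backward_eliminate(
    outcomes,
    metrics: pd.DataFrame,
    metric: str,
    transform: str,
    candidate_covariates,
    alpha: float = 0.01,
    family: str = "binary",
    **fit_kwargs,
) -> ERModelFit:
    """Iteratively drop the least-significant covariate until all p < alpha.

    The exposure term (and the intercept) are never candidates for removal.
    An empty candidate set returns the base fit unchanged.
    """
    fitter = fit_binary_er if family == "binary" else fit_ordinal_er
    covs = list(candidate_covariates)
    while True:
        fit = fitter(outcomes, metrics, metric=metric, transform=transform,
                     covariates=tuple(covs), **fit_kwargs)
        if not covs:
            return fit
        pvals = {c: fit.pvalues[c] for c in covs}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            return fit
        covs.remove(worst)


def predict_probability(fit: ERModelFit, values: dict):
    """Evaluate a fitted model at given predictor values.

    ``values`` maps metric / covariate names (untransformed exposure under
    the fitted metric name) to scalars or arrays.  Binary fits return the
    response probability; ordinal fits return the per-grade probability
    vector (last axis), which sums to 1.
    """
    name = _exposure_col_name(fit.metric, fit.transform)
    x = _transform(values[fit.metric], fit.transform, fit.log_base)
    eta = 0.0
    for pname, coef in zip(fit.exog_names, fit.params):
        if pname == "const":
            eta = eta + coef
        elif pname == name:
            eta = eta + coef * x
        else:
            eta = eta + coef * np.asarray(values[pname], dtype=float)
    if fit.family == "binary":
        p = expit(eta)
        return p if np.shape(p) else float(p)
    cum = expit(fit.thresholds - np.asarray(eta)[..., None])
    cum = np.concatenate([np.zeros_like(cum[..., :1]), cum, np.ones_like(cum[..., :1])], axis=-1)
    return np.diff(cum, axis=-1)
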