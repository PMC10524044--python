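"""Nonlinear mixed-effects recovery of the population PK parameters.

The estimator maximizes a Laplace approximation to the marginal likelihood
of log-concentrations.  With proportional (log-normal) residual error the
subject-level model is

    log y_ij = log f(t_ij; theta, eta_i) + eps_ij,   eps ~ N(0, sigma^2)
    eta_i ~ N(0, diag(omega_CL^2, omega_V2^2, omega_ka^2))

Per outer iteration, each subject's empirical-Bayes mode eta_i is found by
a damped Gauss-Newton step (vectorized across subjects), and the Laplace
objective uses the Gauss-Newton curvature J'J/sigma^2 + Omega^-1.  The
outer search over (log CL, log V2, log ka, log omegas, log sigma) is
Nelder-Mead, preceded by a pooled naive (eta = 0) least-squares stage for
starting values.  The peripheral parameters, lag and bioavailability are
fixed: with oral-only data F is structurally non-identifiable (only CL/F
and V2/F are), which the result flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import PopulationPKParameters, omega_to_cv, cv_to_omega
from .pk import hybrid_rates, _oral_unit_conc

__all__ = ["EstimationResult", "EstimationSettings", "fit_population"]

_ETA_DIM = 3  # CL, V2, ka


@dataclass
class EstimationSettings:
    estimate_ka: bool = True
    max_outer_iter: int = 400
    inner_iter: int = 8
    tol: float = 1e-6
    omega_bounds: tuple = (1e-3, 5.0)
    sigma_bounds: tuple = (1e-3, 2.0)


@dataclass
class EstimationResult:
    """Point estimates, SEs (natural scale, delta method), and diagnostics."""

    params: dict
    se: dict
    objective: float
    converged: bool
    n_iter: int
    history: list = field(default_factory=list)
    notes: list = field(default_factory=list)
    etas: np.ndarray | None = None


def _prepare(data: pd.DataFrame):
    """Split an event-record table into per-subject dose/observation arrays.

    Requires columns ID, TIME, AMT, DV, EVID (ROUTE optional; oral assumed).
    Observation and dose counts may differ across subjects; arrays are
    NaN-padded.  Subjects are keyed by sorted ID so the likelihood is
    invariant to row order.
    """
    df = data.copy()
    if "ROUTE" in df.columns and (df.loc[df["EVID"] == 1, "ROUTE"] == "iv").any():
        raise NotImplementedError("IV records are not supported by this estimator")
    ids = np.sort(df["ID"].unique())
    obs = df[df["EVID"] == 0]
    dose = df[df["EVID"] == 1]
    dv = pd.to_numeric(obs["DV"], errors="coerce")
    if not (dv.dropna() > 0).any():
        raise ValueError("all observations are zero or missing")
    if (dv.dropna() <= 0).any():
        raise ValueError("non-positive concentration observations cannot enter the log-scale fit")
    n = len(ids)
    nobs = obs.groupby("ID").size().reindex(ids).fillna(0).astype(int)
    ndose = dose.groupby("ID").size().reindex(ids).fillna(0).astype(int)
    if (nobs < 2).mean() > 0.5:
        raise ValueError("most subjects need at least two observations")
    t_obs = np.full((n, nobs.max()), np.nan)
    logy = np.full((n, nobs.max()), np.nan)
    t_dose = np.full((n, ndose.max()), np.nan)
    amt = np.zeros((n, ndose.max()))
    for i, sid in enumerate(ids):
        o = obs[obs["ID"] == sid]
        d = dose[dose["ID"] == sid]
        t_obs[i, : len(o)] = o["TIME"].to_numpy(dtype=float)
        logy[i, : len(o)] = np.log(pd.to_numeric(o["DV"]).to_numpy(dtype=float))
        t_dose[i, : len(d)] = d["TIME"].to_numpy(dtype=float)
        amt[i, : len(d)] = d["AMT"].to_numpy(dtype=float)
    return ids, t_obs, logy, t_dose, amt


def _log_pred(eta, logcl, logv2, logka, pop, t_obs, t_dose, amt):
    """Vectorized log model prediction, shape (n_subj, n_obs)."""
    cl = np.exp(logcl + eta[:, 0])[:, None]
    v2 = np.exp(logv2 + eta[:, 1])[:, None]
    ka = np.exp(logka + eta[:, 2])[:, None, None]
    alpha, beta, k21 = hybrid_rates(cl, v2, pop.Q, pop.V3)
    tau = t_obs[:, None, :] - np.nan_to_num(t_dose, nan=np.inf)[:, :, None] - pop.t_lag
    unit = _oral_unit_conc(tau, ka, alpha[:, :, None] * np.ones_like(tau),
                           beta[:, :, None] * np.ones_like(tau), k21)
    conc = (1000.0 * pop.F_oral / v2)[:, :, None] * amt[:, :, None] * unit
    total = conc.sum(axis=1)
    return np.log(np.maximum(total, 1e-12))


def _map_step(eta, sse_fn, oinv, sigma2, n_iter, damp0=1.0):
    """Damped Gauss-Newton MAP update of all subjects' etas at once."""
    def objective(e):
        r = sse_fn(e)
        return np.nansum(r * r, axis=1) / sigma2 + np.einsum("ij,j,ij->i", e, oinv, e)

    obj = objective(eta)
    h = 1e-5
    for _ in range(n_iter):
        r0 = sse_fn(eta)  # residual logy - logf, (n, nobs)
        J = np.empty(eta.shape[:1] + (r0.shape[1], _ETA_DIM))
        for k in range(_ETA_DIM):
            ek = eta.copy()
            ek[:, k] += h
            J[:, :, k] = -(sse_fn(ek) - r0) / h
        Jm = np.nan_to_num(J)
        r0m = np.nan_to_num(r0)
        g = np.einsum("ijk,ij->ik", Jm, r0m) / sigma2 - eta * oinv[None, :]
        H = np.einsum("ijk,ijl->ikl", Jm, Jm) / sigma2 + np.diag(oinv)[None, :, :]
        delta = np.linalg.solve(H + 1e-10 * np.eye(_ETA_DIM)[None], g[:, :, None])[:, :, 0]
        damp = np.full(eta.shape[0], damp0)
        for _ls in range(6):
            cand = eta + damp[:, None] * delta
            new = objective(cand)
            worse = new > obj + 1e-12
            if not np.any(worse):
                break
            damp[worse] *= 0.5
        improved = new <= obj
        eta = np.where(improved[:, None], cand, eta)
        obj = np.where(improved, new, obj)
        if np.max(np.abs(delta)) < 1e-8:
            break
    return eta, obj, H


def fit_population(
    data: pd.DataFrame,
    init: PopulationPKParameters,
    settings: EstimationSettings | dict | None = None,
) -> EstimationResult:
    """Fit typical values, IIV and residual error to an event-record table.

    Deterministic given the data (no stochastic steps).  Returns estimates on
    the natural scale; IIV and residual magnitudes are reported as %CV
    fractions to match :class:`PopulationPKParameters`.
    """
    if settings is None:
        settings = EstimationSettings()
    elif isinstance(settings, dict):
        settings = EstimationSettings(**settings)
    pop = init
    ids, t_obs, logy, t_dose, amt = _prepare(data)
    n = len(ids)
    n_obs_total = int(np.isfinite(logy).sum())
    notes = ["F fixed (oral-only design: F is not identifiable; CL and V2 are apparent CL/F-scaled values times the assumed F)"]

    def resid_fn(logcl, logv2, logka):
        def fn(eta):
            return logy - _log_pred(eta, logcl, logv2, logka, pop, t_obs, t_dose, amt)
        return fn

    # Stage 1: pooled naive fit (eta = 0) for typical-value starting values.
    zero_eta = np.zeros((n, _ETA_DIM))

    def pooled_sse(x):
        r = resid_fn(x[0], x[1], x[2] if settings.estimate_ka else np.log(init.ka))(zero_eta)
        return float(np.nansum(r * r))

    x0 = [np.log(init.CL_typ), np.log(init.V2_typ)]
    if settings.estimate_ka:
        x0.append(np.log(init.ka))
    def pooled_obj(x):
        full = np.array([x[0], x[1], x[2] if settings.estimate_ka else np.log(init.ka)])
        return pooled_sse(full)
    stage1 = minimize(pooled_obj, np.array(x0), method="Nelder-Mead",
                      options={"xatol": 1e-8, "fatol": 1e-10, "maxfev": 2000})
    logcl0, logv20 = stage1.x[0], stage1.x[1]
    logka0 = stage1.x[2] if settings.estimate_ka else np.log(init.ka)

    if stage1.fun / n_obs_total < 1e-10:
        # Degenerate noise-free data: the pooled fit already interpolates the
        # observations, so IIV and residual variances are at their floors and
        # the Laplace stage has nothing to add.
        lb = settings.omega_bounds[0]
        params = {
            "CL_typ": float(np.exp(logcl0)), "V2_typ": float(np.exp(logv20)),
            "ka": float(np.exp(logka0)),
            "omega_CL": lb, "omega_V2": lb, "omega_ka": lb,
            "cv_CL": omega_to_cv(lb), "cv_V2": omega_to_cv(lb), "cv_ka": omega_to_cv(lb),
            "sigma_log": settings.sigma_bounds[0],
            "sigma_prop_oral": omega_to_cv(settings.sigma_bounds[0]),
            "F_oral": pop.F_oral,
        }
        return EstimationResult(
            params=params, se={}, objective=float(stage1.fun), converged=True,
            n_iter=int(stage1.nit), history=[float(stage1.fun)],
            notes=notes + ["noise-free data: pooled least-squares solution; variances at bounds"],
            etas=np.zeros((n, _ETA_DIM)),
        )

    lb_o, ub_o = np.log(settings.omega_bounds[0]), np.log(settings.omega_bounds[1])
    lb_s, ub_s = np.log(settings.sigma_bounds[0]), np.log(settings.sigma_bounds[1])

    state = {"eta": np.zeros((n, _ETA_DIM))}
    history: list[float] = []

    def unpack(x):
        logcl, logv2 = x[0], x[1]
        if settings.estimate_ka:
            logka = x[2]
            rest = x[3:]
        else:
            logka = np.log(init.ka)
            rest = x[2:]
        lomega = np.clip(rest[:3], lb_o, ub_o)
        lsigma = np.clip(rest[3], lb_s, ub_s)
        return logcl, logv2, logka, np.exp(lomega), np.exp(lsigma)

    def neg2ll(x):
        logcl, logv2, logka, omega, sigma = unpack(x)
        sigma2 = sigma * sigma
        oinv = 1.0 / (omega * omega)
        fn = resid_fn(logcl, logv2, logka)
        eta, q, H = _map_step(state["eta"], fn, oinv, sigma2, settings.inner_iter)
        state["eta"] = eta
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return 1e12
        val = (
            n_obs_total * np.log(2.0 * np.pi * sigma2)
            + np.sum(q)
            + n * np.sum(np.log(omega * omega))
            + np.sum(logdet)
        )
        return float(val)

    x0 = [logcl0, logv20]
    if settings.estimate_ka:
        x0.append(logka0)
    x0 += [np.log(max(init.omega_CL, 0.05)), np.log(max(init.omega_V2, 0.05)),
           np.log(max(init.omega_ka, 0.05)), np.log(max(cv_to_omega(init.sigma_prop_oral), 0.05))]
    x0 = np.array(x0, dtype=float)

    best = {"f": np.inf}

    def tracked(xk):
        f = neg2ll(xk)
        if f < best["f"]:
            best["f"] = f
        return f

    res = minimize(
        tracked, x0, method="Nelder-Mead",
        callback=lambda xk: history.append(best["f"]),
        options={"xatol": 1e-3, "fatol": max(settings.tol, 1e-2),
                 "maxiter": settings.max_outer_iter, "adaptive": True},
    )
    logcl, logv2, logka, omega, sigma = unpack(res.x)
    params = {
        "CL_typ": float(np.exp(logcl)),
        "V2_typ": float(np.exp(logv2)),
        "ka": float(np.exp(logka)),
        "omega_CL": float(omega[0]),
        "omega_V2": float(omega[1]),
        "omega_ka": float(omega[2]),
        "cv_CL": omega_to_cv(float(omega[0])),
        "cv_V2": omega_to_cv(float(omega[1])),
        "cv_ka": omega_to_cv(float(omega[2])),
        "sigma_log": float(sigma),
        "sigma_prop_oral": omega_to_cv(float(sigma)),
        "F_oral": pop.F_oral,
    }

    # SEs from a finite-difference Hessian of the objective at the optimum
    # (log scale), delta-method back to the natural scale.
    se: dict = {}
    try:
        k = len(res.x)
        h = 1e-2
        Hm = np.zeros((k, k))
        f0 = neg2ll(res.x)
        for a in range(k):
            for b in range(a, k):
                xa = res.x.copy(); xa[a] += h; xa[b] += h
                xb = res.x.copy(); xb[a] += h
                xc = res.x.copy(); xc[b] += h
                Hm[a, b] = Hm[b, a] = (neg2ll(xa) - neg2ll(xb) - neg2ll(xc) + f0) / (h * h)
        cov = 2.0 * np.linalg.inv(Hm)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
        names = ["CL_typ", "V2_typ"] + (["ka"] if settings.estimate_ka else [])
        for j, nm in enumerate(names):
            se[nm] = float(np.exp(res.x[j]) * sd[j])
    except np.linalg.LinAlgError:
        notes.append("standard errors unavailable (singular Hessian)")

    converged = bool(np.isfinite(res.fun)) and (res.success or res.fun < 1e11)
    if not res.success:
        notes.append(f"outer optimizer status: {res.message}")
    return EstimationResult(
        params=params,
        se=se,
        objective=float(res.fun),
        converged=converged,
        n_iter=int(res.nit),
        history=history,
        notes=notes,
        etas=state["eta"].copy(),
    )
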