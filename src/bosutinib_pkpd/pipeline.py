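"""End-to-end virtual-trial pipeline: generate -> simulate PK -> metrics ->
exposure-response fits -> report.

Stages write their outputs as they complete, so a failure in a later stage
leaves upstream artifacts on disk; the raised :class:`PipelineError` names
the failing stage.  Everything is reproducible from the single master seed
recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from scipy.special import expit

from . import cohort as ch
from . import er
from .exposure import compute_metrics, metrics_frame, cavg_from_cauc, cumulative_auc, trough_before
from .io import write_event_records, write_outcomes
from .params import PopulationPKParameters, default_parameters, load_parameters
from .pipeline_util import fit_to_dict  # noqa: F401  (re-export for callers)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report_quartiles"]

STAGES = ("generate", "simulate-pk", "metrics", "fit-er", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    templates: list = field(default_factory=lambda: ["BELA", "BFORE", "B1871048"])
    seed: int = 0
    params_file: str | None = None
    endpoints: list = field(default_factory=lambda: ["MMR", "CCyR"])
    ae_list: list = field(default_factory=lambda: list(er.AE_NAMES))
    alpha_efficacy: float = 0.01
    alpha_safety: float = 0.05
    log_base: str = "e"
    outdir: str = "run_output"
    n_override: int | None = None  # scale templates down for quick runs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def __post_init__(self):
        for t in self.templates:
            if t not in ch.TEMPLATES:
                raise ValueError(f"unknown template '{t}'")
        if self.log_base not in ("e", "10"):
            raise ValueError("log_base must be 'e' or '10'")


def report_quartiles(metric_values, responses) -> pd.DataFrame:
    """Response rate by exposure quartile with a monotone-trend statistic.

    Quartiles are formed by stable rank order (ties broken by original row
    order), sizes as equal as possible; a Spearman rank correlation between
    quartile index and response is attached as the trend statistic.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(responses, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 patients for quartiles")
    order = np.argsort(x, kind="stable")
    q = np.empty(n, dtype=int)
    bounds = [round(i * n / 4) for i in range(5)]
    for k in range(4):
        q[order[bounds[k]:bounds[k + 1]]] = k + 1
    rho, pval = sps.spearmanr(q, y)
    rows = []
    for k in range(1, 5):
        m = q == k
        rows.append({"quartile": f"Q{k}", "n": int(m.sum()),
                     "response_rate": float(y[m].mean()),
                     "exposure_median": float(np.median(x[m]))})
    out = pd.DataFrame(rows)
    out.attrs["spearman_rho"] = float(rho) if np.isfinite(rho) else 0.0
    out.attrs["spearman_p"] = float(pval) if np.isfinite(pval) else 1.0
    return out


def _prediction_curve(fit: er.ERModelFit, grid: np.ndarray) -> pd.DataFrame:
    """Mean curve with pointwise 95% CI (delta method on the logit scale)."""
    name = fit.exog_names  # const + exposure for the final efficacy models
    g = np.log(grid) if fit.transform == "log" else grid
    X = np.column_stack([np.ones_like(g) if nm == "const" else g for nm in name])
    eta = X @ fit.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_params, X))
    return pd.DataFrame({
        "exposure": grid,
        "probability": expit(eta),
        "lo95": expit(eta - 1.96 * se),
        "hi95": expit(eta + 1.96 * se),
    })


def _ae_exposure_table(subjects, pop, ae_outcomes: pd.DataFrame) -> pd.DataFrame:
    """Cavg/Ctrough up to the (event or landmark) day, plus tte and labs."""
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    for r in ae_outcomes.itertuples():
        s = by_id[r.subject_id]
        ind = s.individual(pop)
        doses = s.doses()
        t_end = max(24.0, r.event_day * 24.0)
        cauc = cumulative_auc(ind, pop, doses, t_end)
        rows.append({
            "subject_id": r.subject_id, "ae": r.ae, "grade": r.grade,
            "Cavg": cavg_from_cauc(cauc, t_end),
            "Ctrough": trough_before(ind, pop, doses, t_end),
            "tte": er.compute_tte(r.grade, r.event_day),
            "age": s.covariates.age, "ast": s.covariates.ast,
            "bplts": s.covariates.platelets,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the pipeline through the requested stages; returns artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    pop = load_parameters(config.params_file) if config.params_file else default_parameters()
    master = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("cohort", "pk", "efficacy", "ae"), master.spawn(4))}
    artifacts: dict = {"pop": pop, "outdir": str(out)}

    stage = "generate"
    try:
        subjects = []
        for i, tname in enumerate(config.templates):
            tmpl = ch.TEMPLATES[tname]
            n = min(config.n_override, tmpl.n) if config.n_override else tmpl.n
            subjects += ch.generate_cohort(
                tmpl, seed=seeds["cohort"].spawn(1)[0].generate_state(1)[0] + i,
                pop=pop, n=n, id_offset=1000 * (i + 1))
        artifacts["subjects"] = subjects

        stage = "simulate-pk"
        if "simulate-pk" in stages:
            events = ch.simulate_observations(
                subjects, pop, seed=seeds["pk"].generate_state(1)[0])
            write_event_records(events, out / "events.csv")
            artifacts["events"] = events

        stage = "metrics"
        exposures = ch.steady_state_exposures(subjects, pop)
        eff_outcomes = {}
        metrics = {}
        for j, ep in enumerate(config.endpoints):
            occ = ch.assign_efficacy(
                subjects, exposures,
                seed=seeds["efficacy"].generate_state(1)[0] + j, endpoint=ep)
            eff_outcomes[ep] = occ
            mm = {}
            for s, o in zip(subjects, occ):
                ind = s.individual(pop)
                mm[s.subject_id] = compute_metrics(ind, pop, s.doses(), o.response_time)
            mf = metrics_frame(mm)
            mf["response"] = [o.response for o in occ]
            mf["ph_positive"] = [o.ph_positive for o in occ]
            mf["age"] = [s.covariates.age for s in subjects]
            mf["weight"] = [s.covariates.weight for s in subjects]
            mf["asian"] = [s.covariates.asian for s in subjects]
            if ep == "CCyR":
                mf = mf[mf["ph_positive"] == 1]
            metrics[ep] = mf
            if "metrics" in stages:
                mf.to_csv(out / f"metrics_{ep}.csv")
                write_outcomes(pd.DataFrame([dataclasses.asdict(o) for o in occ]),
                               out / f"outcomes_{ep}.csv")
        artifacts["metrics"] = metrics

        ae_rows = ch.assign_ae_grades(
            subjects, exposures, seed=seeds["ae"].generate_state(1)[0],
            ae_names=tuple(config.ae_list))
        ae_df = pd.DataFrame([dataclasses.asdict(a) for a in ae_rows])
        if "metrics" in stages:
            write_outcomes(ae_df, out / "outcomes_ae.csv")
        artifacts["ae_outcomes"] = ae_df

        stage = "fit-er"
        fits = {}
        if "fit-er" in stages:
            for ep, mf in metrics.items():
                best = er.select_metric(mf["response"], mf, family="binary",
                                        log_base=config.log_base)
                final = er.backward_eliminate(
                    mf["response"], mf, metric=best.metric, transform=best.transform,
                    candidate_covariates=("age", "weight", "asian"),
                    alpha=config.alpha_efficacy, family="binary",
                    log_base=config.log_base)
                fits[ep] = final
                (out / f"fit_{ep}.json").write_text(json.dumps(fit_to_dict(final), indent=2))
                grid = np.linspace(float(mf[final.metric].quantile(0.02)),
                                   float(mf[final.metric].quantile(0.98)), 50)
                _prediction_curve(final, grid).to_csv(out / f"curve_{ep}.csv", index=False)
            ae_fits = {}
            for ae in config.ae_list:
                sub = _ae_exposure_table(subjects, pop, ae_df[ae_df["ae"] == ae])
                fit = _fit_one_ae(ae, sub, config)
                ae_fits[ae] = fit
                (out / f"fit_ae_{ae}.json").write_text(json.dumps(fit_to_dict(fit), indent=2))
            fits["ae"] = ae_fits
        artifacts["fits"] = fits

        stage = "report"
        if "report" in stages:
            t2 = _exposure_by_response(metrics)
            t2.to_csv(out / "table2_analog.csv", index=False)
            artifacts["table2"] = t2
            qt = {}
            for ep, mf in metrics.items():
                metric = fits.get(ep).metric if ep in fits else "Cavg"
                q = report_quartiles(mf[metric], mf["response"])
                q.to_csv(out / f"quartiles_{ep}.csv", index=False)
                qt[ep] = q
            artifacts["quartiles"] = qt
            manifest = {
                "seed": config.seed,
                "templates": config.templates,
                "n_subjects": len(subjects),
                "calibration": {
                    "mmr_curve": er.calibrate_logistic_from_anchors(*ch.MMR_ANCHORS),
                    "ccyr_curve": er.calibrate_logistic_from_anchors(*ch.CCYR_ANCHORS),
                    "Q": pop.Q, "V3": pop.V3,
                },
                "config": {k: v for k, v in dataclasses.asdict(config).items()},
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            artifacts["manifest"] = manifest
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, e) from e
    return artifacts


def _fit_one_ae(ae: str, sub: pd.DataFrame, config: RunConfig) -> er.ERModelFit:
    """Ordinal fit with tte (baseline lab where applicable); binary fallback
    (Grade>0/1/2) when the ordinal exposure term is not significant."""
    lab = {"ast": "ast", "alt": "ast", "thrombocytopenia": "bplts"}.get(ae)
    grades = sub["grade"].to_numpy()
    if ae == "thrombocytopenia":
        m = sub.rename(columns={"Cavg": "Cavg28"})
        try:
            return er.fit_thrombocytopenia(grades, m, log_base=config.log_base)
        except ValueError as e:
            fit = er.fit_binary_er((grades > 0).astype(float), sub, "Cavg", "linear")
            fit.notes.append(str(e))
            return fit
    best = None
    for metric in ("Cavg", "Ctrough"):
        for transform in ("linear", "log"):
            try:
                with warnings.catch_warnings():
                    # small cohorts routinely miss grade levels; the collapse
                    # is expected during model screening
                    warnings.simplefilter("ignore", UserWarning)
                    f = er.fit_ordinal_er(grades, sub, metric, transform,
                                          include_tte=True, baseline_lab=lab,
                                          log_base=config.log_base)
            except ValueError:
                continue
            if best is None or f.deviance < best.deviance - 1e-9:
                best = f
    if best is None:
        raise ValueError(f"no ordinal model could be fitted for {ae}")
    exp_name = best.exog_names[0]
    if best.pvalues.get(exp_name, 1.0) < config.alpha_safety:
        return best
    for thr in (0, 1, 2):
        try:
            fb = er.binary_fallback(grades, sub, thr, best.metric, best.transform)
        except ValueError:
            continue
        if fb.pvalues.get(fb.exog_names[1], 1.0) < config.alpha_safety:
            return fb
    best.notes.append("no significant exposure term in ordinal or binary fallback")
    return best


def _exposure_by_response(metrics: dict) -> pd.DataFrame:
    rows = []
    for ep, mf in metrics.items():
        for col in ("cAUC", "Cavg", "Ctrough", "cAUC28", "Cavg28", "Ctrough28"):
            for resp in (1, 0):
                v = mf.loc[mf["response"] == resp, col]
                rows.append({
                    "endpoint": ep, "metric": col,
                    "group": "responders" if resp else "non-responders",
                    "n": int(len(v)), "median": float(v.median()),
                    "mean": float(v.mean()), "sd": float(v.std()),
                    "min": float(v.min()), "max": float(v.max()),
                })
    return pd.DataFrame(rows)
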