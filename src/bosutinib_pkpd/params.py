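"""Population PK parameters and the covariate model for bosutinib.

Bosutinib disposition is described by a two-compartment model with
first-order absorption and an absorption lag.  The population model carries

* typical values (clearance CL, central volume V2, absorption rate ka,
  lag time, absolute oral bioavailability F),
* power-law covariate effects of baseline creatinine clearance on CL and of
  age and body weight on V2, plus proportional shifts for Asian race on
  both CL and V2,
* log-normal inter-individual variability (IIV) on CL, V2 and ka, and
* proportional (log-normal) residual error per route.

The peripheral-compartment parameters (Q, V3) are not part of the reported
parameter set; the defaults here come from a steady-state trough calibration
(see :func:`bosutinib_pkpd.pk.calibrate_peripheral`) and are plain
configuration values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = [
    "AGE_REF",
    "WT_REF",
    "CCL_REF",
    "PopulationPKParameters",
    "CovariateVector",
    "IndividualPKParameters",
    "cv_to_omega",
    "omega_to_cv",
    "derive_power_exponent",
    "individualize",
    "covariate_effect_percent",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]

# Reference covariate values (analysis-population medians).
AGE_REF = 51.0  # years
WT_REF = 72.5  # kg
CCL_REF = 98.6  # mL/min


def cv_to_omega(cv: float) -> float:
    """Exact log-normal SD for a given coefficient of variation.

    omega = sqrt(ln(1 + CV^2)); for small CV, omega ~= CV.
    """
    return math.sqrt(math.log1p(cv * cv))


def omega_to_cv(omega: float) -> float:
    """Inverse of :func:`cv_to_omega`: CV = sqrt(exp(omega^2) - 1)."""
    return math.sqrt(math.expm1(omega * omega))


def derive_power_exponent(cov_value: float, ref_value: float, frac_change: float) -> float:
    """Back out a power-model exponent from one printed fractional change.

    Solves ``(cov_value / ref_value) ** theta == 1 + frac_change`` for theta,
    i.e. ``theta = ln(1 + frac_change) / ln(cov_value / ref_value)``.

    Raises ``ValueError`` for non-positive levels, a zero log-ratio
    (cov_value == ref_value) or ``1 + frac_change <= 0``.
    """
    if cov_value <= 0 or ref_value <= 0:
        raise ValueError("covariate and reference values must be positive")
    if 1.0 + frac_change <= 0:
        raise ValueError("1 + frac_change must be positive")
    if cov_value == ref_value:
        raise ValueError("undefined exponent: covariate value equals the reference value")
    return math.log1p(frac_change) / math.log(cov_value / ref_value)


# Exponents calibrated from one printed anchor each; the remaining printed
# percentages then follow as forward predictions (checked in the test suite).
THETA_AGE = derive_power_exponent(29.0, AGE_REF, -0.096)   # V2 vs age
THETA_WT = derive_power_exponent(55.0, WT_REF, -0.129)     # V2 vs body weight
THETA_CCL = derive_power_exponent(45.0, CCL_REF, -0.144)   # CL vs creatinine clearance


@dataclass(frozen=True)
class PopulationPKParameters:
    """Typical values, covariate coefficients, IIV and residual error.

    Volumes in L, clearances in L/h, rates in 1/h, lag in h.  IIV and
    residual magnitudes are stored as %CV fractions (e.g. 0.434 for 43.4%)
    and converted to log-normal SDs on demand.
    """

    CL_typ: float = 56.3
    V2_typ: float = 1325.7
    ka: float = 0.358
    t_lag: float = 0.442
    F_oral: float = 0.331
    # Peripheral compartment: calibrated so the geometric-mean steady-state
    # 500-mg QD trough of a simulated IIV population is 90.7 ng/mL (see
    # pk.calibrate_peripheral); configuration values, not reported estimates.
    Q: float = 150.0
    V3: float = 869.7
    # Inter-individual variability, %CV as fractions.
    cv_CL: float = 0.434
    cv_V2: float = 0.381
    cv_ka: float = 1.121
    # Proportional residual error, %CV as fractions.
    sigma_prop_oral: float = 0.399
    sigma_prop_iv: float = 0.481
    # Covariate model.
    theta_age: float = THETA_AGE
    theta_wt: float = THETA_WT
    theta_ccl: float = THETA_CCL
    frac_asian_CL: float = 0.184
    frac_asian_V2: float = 0.202
    age_ref: float = AGE_REF
    wt_ref: float = WT_REF
    ccl_ref: float = CCL_REF

    def __post_init__(self):
        for name in ("CL_typ", "V2_typ", "ka", "F_oral", "Q", "V3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.t_lag < 0:
            raise ValueError("t_lag must be non-negative")
        if not 0 < self.F_oral <= 1:
            raise ValueError("F_oral must be in (0, 1]")
        for name in ("frac_asian_CL", "frac_asian_V2"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")

    @property
    def omega_CL(self) -> float:
        return cv_to_omega(self.cv_CL)

    @property
    def omega_V2(self) -> float:
        return cv_to_omega(self.cv_V2)

    @property
    def omega_ka(self) -> float:
        return cv_to_omega(self.cv_ka)


# Broad physiologic plausibility bounds spanning the pooled trial ranges.
_COV_BOUNDS = {
    "age": (18.0, 91.0),
    "weight": (33.2, 136.0),
    "bccl": (15.0, 250.5),  # lower bound relaxed to end-stage renal disease
}


@dataclass(frozen=True)
class CovariateVector:
    """Baseline covariates for one patient."""

    age: float
    weight: float
    bccl: float
    asian: int = 0
    ast: float = 24.0        # baseline AST, U/L
    platelets: float = 386.0  # baseline platelets, 1e9 cells/L

    def __post_init__(self):
        for name in ("age", "weight", "bccl", "ast", "platelets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"covariate '{name}' must be positive")
        for name, (lo, hi) in _COV_BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(
                    f"covariate '{name}'={v} outside plausible range [{lo}, {hi}]"
                )
        if self.asian not in (0, 1):
            raise ValueError("covariate 'asian' must be 0 or 1")


REFERENCE_COVARIATES = CovariateVector(age=AGE_REF, weight=WT_REF, bccl=CCL_REF, asian=0)


@dataclass(frozen=True)
class IndividualPKParameters:
    """Individual parameters after covariate adjustment and IIV draw."""

    CL_i: float
    V2_i: float
    ka_i: float
    eta: tuple = (0.0, 0.0, 0.0)


def individualize(
    pop: PopulationPKParameters,
    cov: CovariateVector,
    eta=(0.0, 0.0, 0.0),
) -> IndividualPKParameters:
    """Apply the covariate model and log-normal random effects.

    CL_i = CL_typ * (bccl/ccl_ref)^theta_ccl * (1 - frac_asian_CL*asian) * exp(eta_CL)
    V2_i = V2_typ * (age/age_ref)^theta_age * (wt/wt_ref)^theta_wt
                  * (1 - frac_asian_V2*asian) * exp(eta_V2)
    ka_i = ka * exp(eta_ka)

    With zero etas and reference covariates this is the identity on the
    typical values.
    """
    eta = tuple(float(e) for e in eta)
    if len(eta) != 3:
        raise ValueError("eta must have three components (CL, V2, ka)")
    cl = (
        pop.CL_typ
        * (cov.bccl / pop.ccl_ref) ** pop.theta_ccl
        * (1.0 - pop.frac_asian_CL * cov.asian)
        * math.exp(eta[0])
    )
    v2 = (
        pop.V2_typ
        * (cov.age / pop.age_ref) ** pop.theta_age
        * (cov.weight / pop.wt_ref) ** pop.theta_wt
        * (1.0 - pop.frac_asian_V2 * cov.asian)
        * math.exp(eta[1])
    )
    ka = pop.ka * math.exp(eta[2])
    return IndividualPKParameters(CL_i=cl, V2_i=v2, ka_i=ka, eta=eta)


def covariate_effect_percent(pop: PopulationPKParameters, name: str, value: float) -> float:
    """Percent change of the affected parameter vs the reference subject.

    ``name`` is one of ``bccl`` (on CL), ``age``/``weight`` (on V2) or
    ``asian`` (proportional shift on CL).  Returns the signed percentage,
    un-rounded.
    """
    if name == "bccl":
        ratio = (value / pop.ccl_ref) ** pop.theta_ccl
    elif name == "age":
        ratio = (value / pop.age_ref) ** pop.theta_age
    elif name == "weight":
        ratio = (value / pop.wt_ref) ** pop.theta_wt
    elif name == "asian":
        ratio = 1.0 - pop.frac_asian_CL * value
    else:
        raise KeyError(f"unknown covariate '{name}'")
    return 100.0 * (ratio - 1.0)


def default_parameters() -> PopulationPKParameters:
    """The reported population parameter set with calibrated Q/V3 defaults."""
    return PopulationPKParameters()


def save_parameters(pop: PopulationPKParameters, path) -> None:
    """Write parameters to JSON or YAML depending on the file suffix."""
    path = Path(path)
    data = asdict(pop)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_parameters(path) -> PopulationPKParameters:
    """Read a parameter file written by :func:`save_parameters`."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    known = {f.name for f in PopulationPKParameters.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return PopulationPKParameters(**data)
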