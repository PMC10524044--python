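"""Shared fixtures: population parameters and a stiff-ODE oracle.

The oracle integrates the three-state absorption/disposition system with
LSODA at tight tolerances, dosing the depot by impulses at dose time + lag.
It is deliberately independent of the closed-form implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from bosutinib_pkpd import default_parameters, individualize
from bosutinib_pkpd.params import REFERENCE_COVARIATES


@pytest.fixture(scope="session")
def pop():
    return default_parameters()


@pytest.fixture(scope="session")
def ref_ind(pop):
    return individualize(pop, REFERENCE_COVARIATES)


def ode_concentration(ind, pop, doses, tgrid):
    """Reference concentrations (ng/mL) by numeric integration."""
    tgrid = np.asarray(tgrid, dtype=float)
    k10 = ind.CL_i / ind.V2_i
    k12 = pop.Q / ind.V2_i
    k21 = pop.Q / pop.V3

    def rhs(t, y):
        a1, a2, a3 = y
        return [
            -ind.ka_i * a1,
            ind.ka_i * a1 - (k10 + k12) * a2 + k21 * a3,
            k12 * a2 - k21 * a3,
        ]

    impulses = sorted(
        (d.time + (pop.t_lag if d.route == "oral" else 0.0),
         (pop.F_oral if d.route == "oral" else 1.0) * d.amount,
         0 if d.route == "oral" else 1)  # depot for oral, central for IV bolus
        for d in doses
    )
    y = [0.0, 0.0, 0.0]
    t0 = 0.0
    out = np.zeros_like(tgrid)
    segments = impulses + [(float(tgrid.max()) + 1.0, 0.0, 0)]
    for t_end, amount, comp in segments:
        if t0 < t_end:
            mask = (tgrid >= t0) & (tgrid < t_end)
            t_eval = tgrid[mask]
            if t_eval.size:
                sol = solve_ivp(rhs, (t0, t_end), y, t_eval=t_eval,
                                rtol=1e-11, atol=1e-13, method="LSODA")
                out[mask] = sol.y[1]
            sol = solve_ivp(rhs, (t0, t_end), y, rtol=1e-11, atol=1e-13, method="LSODA")
            y = sol.y[:, -1].tolist()
        y[comp] += amount
        t0 = t_end
    return 1000.0 * out / ind.V2_i


@pytest.fixture(scope="session")
def ode_oracle():
    return ode_concentration
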