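import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tobramipd.pk import ModelSpec, PKParameters, Regimen, load_model


@pytest.fixture(scope="session")
def hennig():
    return load_model("hennig_like")


@pytest.fixture(scope="session")
def alghanem():
    return load_model("alghanem_like")


@pytest.fixture(scope="session")
def ref_covariates():
    """Reference covariates at which all covariate factors are exactly 1."""
    return {"AGE": 32.7, "WT": 70.0, "HT": 165.0, "SEX": 1.0, "SCR": 0.73, "CRCL": 100.0}


@pytest.fixture
def spec_1cmt_cl():
    """Minimal one-compartment model with a single random effect on CL."""
    return ModelSpec(
        n_compartments=1,
        theta={"CL": 5.0, "V1": 30.0},
        omega=np.array([[0.09]]),
        iiv=("CL",),
        sigma_prop=0.10,
        sigma_add=0.1,
        label="test-1cmt",
    )


@pytest.fixture
def spec_1cmt_lownoise():
    """Near-noise-free assay model for round-trip identifiability checks."""
    return ModelSpec(
        n_compartments=1,
        theta={"CL": 5.0, "V1": 30.0},
        omega=np.array([[0.09]]),
        iiv=("CL",),
        sigma_prop=0.01,
        sigma_add=0.01,
        label="test-1cmt-lownoise",
    )


def ode_concentrations_2cmt(params: PKParameters, regimen: Regimen, times):
    """Independent two-compartment oracle by stiff ODE integration."""
    k10 = params.CL / params.V1
    k12 = params.Q / params.V1
    k21 = params.Q / params.V2

    def rate(t):
        return sum(
            d.rate for d in regimen.doses if d.time <= t < d.time + d.tinf
        )

    def rhs(t, y):
        a1, a2 = y
        return [rate(t) - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    # integrate piecewise between infusion switch points to keep accuracy
    switch = sorted({0.0, *[d.time for d in regimen.doses], *[d.end for d in regimen.doses], *times})
    switch = [s for s in switch if s <= max(times)]
    y = np.array([0.0, 0.0])
    out = {}
    for a, b in zip(switch, switch[1:]):
        want = [t for t in times if a < t <= b]
        sol = solve_ivp(
            rhs, (a, b), y, t_eval=sorted(set(want + [b])), rtol=1e-11, atol=1e-12,
            method="LSODA",
        )
        for t, col in zip(sol.t, sol.y.T):
            out[float(t)] = col[0] / params.V1
        y = sol.y[:, -1]
    out[0.0] = 0.0
    return np.array([out[float(t)] for t in times])
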