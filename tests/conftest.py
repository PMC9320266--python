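import numpy as np
import pytest
from scipy.integrate import solve_ivp

from vancomipd.engine import DoseEvent, Regimen
from vancomipd.models import (
    CovariateRecord,
    IndividualParameters,
    PopPKModel,
    load_default_panel,
)


@pytest.fixture(scope="session")
def goti() -> PopPKModel:
    return load_default_panel(include_synthetic=False)[0]


@pytest.fixture(scope="session")
def panel() -> list[PopPKModel]:
    return load_default_panel()


@pytest.fixture
def cov() -> CovariateRecord:
    return CovariateRecord(age=63, sex="male", total_body_weight=76, serum_creatinine=0.83)


def make_1cmt(
    cl=4.0, v1=50.0, eta_names=("CL",), omega=None, additive=1.0, proportional=0.0
) -> PopPKModel:
    """Plain one-compartment model without covariate effects."""
    eta_names = list(eta_names)
    if omega is None:
        omega = 0.09 * np.eye(len(eta_names))
    return PopPKModel(
        model_id="test_1cmt",
        n_compartments=1,
        parameters={"CL": cl, "V1": v1},
        eta_names=eta_names,
        omega=np.asarray(omega),
        residual_additive=additive,
        residual_proportional=proportional,
    )


@pytest.fixture
def simple_1cmt() -> PopPKModel:
    return make_1cmt()


def ode_concentration(params: IndividualParameters, events, times) -> np.ndarray:
    """Independent oracle: numerically integrate the compartment ODEs over
    the same infusion schedule, segment by segment between rate changes."""
    times = np.asarray(times, dtype=float)
    n = params.n_compartments
    cl, v1 = params["CL"], params["V1"]
    if n == 2:
        q, v2 = params["Q"], params["V2"]
        k10, k12, k21 = cl / v1, q / v1, q / v2
    else:
        k10 = cl / v1

    deltas: dict[float, float] = {}
    for e in events:
        deltas[e.start_time] = deltas.get(e.start_time, 0.0) + e.rate
        deltas[e.start_time + e.duration] = deltas.get(e.start_time + e.duration, 0.0) - e.rate
    changes = sorted(deltas.items())
    bps = [0.0] + [t for t, _ in changes if t > 0] + [float(times.max()) + 1.0]
    bps = sorted(set(bps))

    def rhs(t, a, rate):
        if n == 1:
            return [rate - k10 * a[0]]
        return [rate - (k10 + k12) * a[0] + k21 * a[1], k12 * a[0] - k21 * a[1]]

    out = np.empty_like(times)
    state = np.zeros(n)
    rate = 0.0
    for lo, hi in zip(bps[:-1], bps[1:]):
        rate = sum(dr for t, dr in changes if t <= lo + 1e-12)
        inside = times[(times > lo) & (times <= hi)]
        sol = solve_ivp(
            rhs, (lo, hi), state, t_eval=np.unique(np.concatenate([inside, [hi]])),
            args=(rate,), method="LSODA", rtol=1e-11, atol=1e-12,
        )
        for t in inside:
            out[np.isclose(times, t)] = sol.y[0][np.isclose(sol.t, t)][0] / v1
        state = sol.y[:, -1]
    out[times == 0.0] = 0.0
    return out


def random_case(rng: np.random.Generator):
    """Random (params, regimen, times) triple for engine oracle checks."""
    n = int(rng.integers(1, 3))
    values = {"CL": float(rng.uniform(1, 8)), "V1": float(rng.uniform(20, 90))}
    if n == 2:
        values["Q"] = float(rng.uniform(2, 12))
        values["V2"] = float(rng.uniform(20, 90))
    params = IndividualParameters(values=values, n_compartments=n)
    mode = rng.choice(["intermittent", "continuous"])
    events = []
    if mode == "intermittent":
        tau = float(rng.choice([8.0, 12.0, 24.0]))
        dur = float(rng.uniform(0.5, 2.0))
        amount = float(rng.integers(1, 9) * 250)
        for i in range(int(rng.integers(2, 7))):
            events.append(DoseEvent(i * tau, amount, dur))
        regimen = Regimen("intermittent", events, tau, dur)
        horizon = events[-1].start_time + tau
    else:
        t = 0.0
        for _ in range(int(rng.integers(1, 4))):
            seg = float(rng.uniform(6, 48))
            rate = float(rng.uniform(20, 200))
            events.append(DoseEvent(t, rate * seg, seg))
            t += seg
        regimen = Regimen("continuous", events)
        horizon = t
    times = np.sort(rng.uniform(0.0, horizon, size=4))
    return params, regimen, times
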