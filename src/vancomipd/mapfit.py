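"""MAP Bayesian estimation of individual random effects.

Given a population-PK model, a patient's covariates, the dosing history and
one or more informing concentrations, the maximum-a-posteriori estimate of
the log-normal random effects eta minimizes

    OFV(eta) = sum_j [ (y_j - f_j(eta))^2 / g_j^2 + ln g_j^2 ]
               + eta' Omega^{-1} eta,

where ``f_j`` is the model prediction at the observation time and
``g_j^2 = a^2 + (b f_j)^2`` is the residual variance.  The minimized OFV and
the squared prediction error SSE = sum_j (y_j - f_j(eta_hat))^2 are the two
fit criteria used downstream for model selection and model averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .engine import Regimen, predict_profile
from .models import CovariateRecord, IndividualParameters, PopPKModel, individual_parameters

__all__ = ["Observation", "FitResult", "ofv", "map_fit", "posterior_predict"]

ETA_BOUND = 6.0
_OFV_TOL = 1e-8
_N_RESTARTS = 5


@dataclass(frozen=True)
class Observation:
    """One measured concentration (mg/L) at ``time`` h after the first dose."""

    time: float
    concentration: float

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError("observed concentration must be > 0")
        if self.time < 0:
            raise ValueError("observation time must be >= 0")


@dataclass
class FitResult:
    """MAP fit of one model to one patient's informing data."""

    model_id: str
    eta: np.ndarray
    ofv: float
    sse: float
    params: IndividualParameters
    n_obs: int
    converged: bool
    n_iter: int
    message: str = ""
    model: PopPKModel | None = field(default=None, repr=False)


def _omega_inverse(model: PopPKModel) -> np.ndarray:
    if model.n_eta == 0:
        return np.zeros((0, 0))
    try:
        inv = np.linalg.inv(model.omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"{model.model_id}: omega is singular; drop the unidentifiable eta "
            "(reduce eta_names/omega to a full-rank block) instead of inverting"
        ) from exc
    return inv


def _predictions(
    model: PopPKModel,
    eta: np.ndarray,
    observations: list[Observation],
    cov: CovariateRecord,
    regimen: Regimen,
    ref_time: float,
) -> np.ndarray:
    params = individual_parameters(model, cov, eta, at_time=ref_time)
    times = np.array([o.time for o in observations])
    return predict_profile(params, regimen, times)


def ofv(
    model: PopPKModel,
    eta,
    observations: list[Observation],
    cov: CovariateRecord,
    regimen: Regimen,
) -> float:
    """MAP objective for the given eta (see module docstring)."""
    if not observations:
        raise ValueError("at least one observation is required")
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    omega_inv = _omega_inverse(model)
    ref_time = max(o.time for o in observations)
    f = _predictions(model, eta, observations, cov, regimen, ref_time)
    y = np.array([o.concentration for o in observations])
    g2 = model.residual_variance(f)
    if np.any(g2 <= 0):
        raise ValueError(f"{model.model_id}: zero residual variance at a prediction")
    value = float(np.sum((y - f) ** 2 / g2 + np.log(g2)))
    if model.n_eta:
        value += float(eta @ omega_inv @ eta)
    return value


def map_fit(
    model: PopPKModel,
    observations: list[Observation],
    cov: CovariateRecord,
    regimen: Regimen,
) -> FitResult:
    """Minimize the OFV over eta (L-BFGS-B from eta = 0, |eta_k| <= 6;
    five seeded restarts if the first start fails to converge)."""
    if not observations:
        raise ValueError("at least one informing observation is required")
    k = model.n_eta
    omega_inv = _omega_inverse(model)
    ref_time = max(o.time for o in observations)
    y = np.array([o.concentration for o in observations])
    times = np.array([o.time for o in observations])

    def objective(eta: np.ndarray) -> float:
        params = individual_parameters(model, cov, eta, at_time=ref_time)
        f = predict_profile(params, regimen, times)
        g2 = model.residual_variance(f)
        val = float(np.sum((y - f) ** 2 / g2 + np.log(g2)))
        if k:
            val += float(eta @ omega_inv @ eta)
        return val

    if k == 0:
        eta_hat = np.zeros(0)
        res_nit, converged, message = 0, True, "no random effects"
    else:
        bounds = [(-ETA_BOUND, ETA_BOUND)] * k
        starts = [np.zeros(k)]
        rng = np.random.default_rng(20220713)  # fixed multi-start seed
        starts += [rng.uniform(-1.5, 1.5, size=k) for _ in range(_N_RESTARTS)]
        best = None
        for i, x0 in enumerate(starts):
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": _OFV_TOL, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            if res.success and i == 0:
                break  # first start converged; restarts are a fallback only
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(
                f"{model.model_id}: MAP fit failed to converge after "
                f"{_N_RESTARTS} seeded restarts"
            )
        eta_hat = np.asarray(best.x)
        res_nit, converged, message = best.nit, bool(best.success), str(best.message)

    params = individual_parameters(model, cov, eta_hat, at_time=ref_time)
    f_hat = predict_profile(params, regimen, times)
    return FitResult(
        model_id=model.model_id,
        eta=eta_hat,
        ofv=objective(eta_hat) if k else ofv(model, eta_hat, observations, cov, regimen),
        sse=float(np.sum((y - f_hat) ** 2)),
        params=params,
        n_obs=len(observations),
        converged=converged,
        n_iter=int(res_nit),
        message=message,
        model=model,
    )


def posterior_predict(fit: FitResult, regimen: Regimen, t) -> float | np.ndarray:
    """Concentration prediction at time(s) ``t`` using the MAP individual
    parameters and the full dosing history in ``regimen``."""
    scalar = np.isscalar(t)
    out = predict_profile(fit.params, regimen, np.atleast_1d(np.asarray(t, dtype=float)))
    return float(out[0]) if scalar else out
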