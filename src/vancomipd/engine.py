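"""Closed-form concentration-time predictions for linear compartment models.

All dosing is by zero-order infusion.  A course is a list of
:class:`DoseEvent` (start time, amount, infusion duration); a continuous
infusion with rate changes is encoded as back-to-back long infusions and a
loading dose is just a short infusion.  Between rate change-points the
system ``dA/dt = K A + u`` has the exact solution

    A(t0 + dt) = A_ss + exp(K dt) (A(t0) - A_ss),   A_ss = -K^{-1} u,

evaluated here with the analytic 2x2 (or scalar) matrix exponential, so a
profile is computed by marching the state through the change-points.  The
concentration reported is the central-compartment concentration ``A1/V1``;
it is continuous in time (infusions change the rate, not the state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import IndividualParameters

__all__ = [
    "DoseEvent",
    "Regimen",
    "concentration",
    "predict_profile",
    "steady_state_trough",
]


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order infusion: ``amount`` mg over ``duration`` h starting
    at ``start_time`` h (times from first dose)."""

    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if not self.duration > 0:
            raise ValueError(f"infusion duration must be > 0, got {self.duration}")
        if self.start_time < 0:
            raise ValueError("dose start_time must be >= 0")

    @property
    def rate(self) -> float:
        return self.amount / self.duration


@dataclass
class Regimen:
    """Dosing course: the event list plus, for intermittent dosing, the
    maintenance descriptor (dosing interval and infusion duration)."""

    mode: str  # "intermittent" | "continuous"
    events: list[DoseEvent] = field(default_factory=list)
    interval: float | None = None  # h, intermittent maintenance
    duration: float | None = None  # h, intermittent infusion duration

    def __post_init__(self) -> None:
        if self.mode not in ("intermittent", "continuous"):
            raise ValueError(f"mode must be 'intermittent' or 'continuous', got {self.mode!r}")
        self.events = sorted(self.events, key=lambda e: e.start_time)
        if self.mode == "intermittent" and self.interval is not None and self.duration is not None:
            if not self.interval > self.duration:
                raise ValueError("dosing interval must exceed infusion duration")


def _params_tuple(params: IndividualParameters) -> tuple:
    v = params.values
    cl, v1 = v["CL"], v["V1"]
    if params.n_compartments == 1:
        return (1, cl / v1, 0.0, 0.0, v1)
    q, v2 = v["Q"], v["V2"]
    return (2, cl / v1, q / v1, q / v2, v1)


def _step(pt: tuple, a1: float, a2: float, rate: float, dt: float) -> tuple[float, float]:
    """Exact propagation of compartment amounts over dt at constant rate."""
    n, k10, k12, k21, _ = pt
    if n == 1:
        ass = rate / k10
        return ass + (a1 - ass) * math.exp(-k10 * dt), 0.0
    s = k10 + k12 + k21
    d = math.sqrt(s * s - 4.0 * k10 * k21)
    lam1 = 0.5 * (-s + d)
    lam2 = 0.5 * (-s - d)
    c1 = math.exp(lam1 * dt)
    c2 = math.exp(lam2 * dt)
    m = (c1 - c2) / d if d > 1e-14 * s else dt * c2
    e11 = c2 + m * (-(k10 + k12) - lam2)
    e12 = m * k21
    e21 = m * k12
    e22 = c2 + m * (-k21 - lam2)
    ass1 = rate / k10
    ass2 = rate * k12 / (k10 * k21)
    b1 = a1 - ass1
    b2 = a2 - ass2
    return ass1 + e11 * b1 + e12 * b2, ass2 + e21 * b1 + e22 * b2


def _rate_changes(events: Sequence[DoseEvent]) -> list[tuple[float, float]]:
    """Sorted (time, delta_rate) change-points from the event list."""
    deltas: dict[float, float] = {}
    for e in events:
        deltas[e.start_time] = deltas.get(e.start_time, 0.0) + e.rate
        end = e.start_time + e.duration
        deltas[end] = deltas.get(end, 0.0) - e.rate
    return sorted(deltas.items())


def _profile(pt: tuple, events: Sequence[DoseEvent], times: np.ndarray) -> np.ndarray:
    """Concentrations at sorted non-negative times."""
    v1 = pt[4]
    changes = _rate_changes(events)
    out = np.empty(len(times))
    a1 = a2 = 0.0
    cur_t = 0.0
    rate = 0.0
    ci = 0
    for j, t in enumerate(times):
        while ci < len(changes) and changes[ci][0] <= t:
            bt, dr = changes[ci]
            if bt > cur_t:
                a1, a2 = _step(pt, a1, a2, rate, bt - cur_t)
                cur_t = bt
            rate += dr
            ci += 1
        if t > cur_t:
            a1, a2 = _step(pt, a1, a2, rate, t - cur_t)
            cur_t = t
        out[j] = a1 / v1
    return out


def predict_profile(
    params: IndividualParameters,
    regimen: Regimen,
    times: Sequence[float],
) -> np.ndarray:
    """Central-compartment concentrations (mg/L) at the given times (h)."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t.size and t.min() < 0:
        raise ValueError("times must be >= 0")
    order = np.argsort(t, kind="stable")
    sorted_c = _profile(_params_tuple(params), regimen.events, t[order])
    out = np.empty_like(sorted_c)
    out[order] = sorted_c
    return out


def concentration(params: IndividualParameters, regimen: Regimen, t: float) -> float:
    """Concentration (mg/L) at a single time t (h)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return float(_profile(_params_tuple(params), regimen.events, np.array([float(t)]))[0])


def steady_state_trough(
    params: IndividualParameters, dose: float, interval: float, duration: float
) -> float:
    """Trough of the periodic steady state for ``dose`` mg infused over
    ``duration`` h every ``interval`` h: the concentration at the end of a
    dosing interval, immediately before the next infusion.

    Computed in closed form as the fixed point of the one-interval map
    ``A -> M A + b`` (geometric-series accumulation of the single-dose
    response).
    """
    if not interval > duration:
        raise ValueError("interval must exceed infusion duration")
    if not dose > 0:
        raise ValueError("dose must be > 0")
    pt = _params_tuple(params)
    n = 1 if pt[0] == 1 else 2
    rate = dose / duration

    def one_period(a1: float, a2: float) -> tuple[float, float]:
        a1, a2 = _step(pt, a1, a2, rate, duration)
        return _step(pt, a1, a2, 0.0, interval - duration)

    # b = response from rest; M columns = unit responses
    b = np.array(one_period(0.0, 0.0))
    m0 = np.array(one_period(1.0, 0.0)) - b
    m1 = np.array(one_period(0.0, 1.0)) - b
    M = np.column_stack([m0, m1])[:n, :n]
    a_star = np.linalg.solve(np.eye(n) - M, b[:n])
    return float(a_star[0] / pt[4])
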