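"""Target-driven dose optimization and standardized dose comparison.

After an informing concentration, the "first two doses" are optimized:

* intermittent — the first dose is chosen so the predicted trough at the
  end of the next dosing interval hits the target (attainment as soon as
  possible); the second dose is the steady-state dose whose periodic
  steady-state trough equals the target.
* continuous — the first infusion-rate segment corrects the concentration
  toward the target over the next 12 h; the second rate is the
  steady-state rate ``target * CL`` (ensemble: ``target / sum_i w_i/CL_i``,
  the rate whose weighted plateau prediction equals the target).

Linear PK makes every predicted concentration affine in the new dose,
``pred = legacy + dose * unit_response``, so doses are solved in closed
form and clamped at zero (flagged) when the target is unreachable.

Doses are compared on a common scale as mg per 12 h (``q12h``); an absolute
difference of 125 mg or more between the model-predicted and prescribed
q12h dose is flagged clinically relevant (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import DoseEvent, Regimen, concentration, steady_state_trough
from .ensemble import EnsembleFit
from .mapfit import FitResult

__all__ = [
    "DoseRecommendation",
    "optimize_doses",
    "normalize_q12h",
    "dose_difference",
    "clinically_relevant",
    "dose_difference_summary",
    "CLINICALLY_RELEVANT_MG",
]

CLINICALLY_RELEVANT_MG = 125.0


@dataclass
class DoseRecommendation:
    """Model-based first and second (steady-state) dose after an informing
    concentration.  For continuous infusion the 'doses' are rates in mg/h."""

    mode: str
    target: float  # mg/L
    first_dose: float  # mg, or mg/h for continuous
    second_dose: float  # mg, or mg/h for continuous
    first_dose_q12h: float  # mg per 12 h
    second_dose_q12h: float  # mg per 12 h
    predicted_at_eval: float  # mg/L at the first-dose evaluation time
    eval_time: float  # h
    clamped: bool  # first and/or second dose truncated at 0


def _weighted_fits(fit_or_ensemble) -> list[tuple[float, FitResult]]:
    if isinstance(fit_or_ensemble, EnsembleFit):
        ens = fit_or_ensemble
        return [(float(w), f) for w, f in zip(ens.weights, ens.fits)]
    return [(1.0, fit_or_ensemble)]


def _history_until(events: list[DoseEvent], now: float) -> list[DoseEvent]:
    """Administered drug up to ``now``: future doses dropped, the ongoing
    infusion truncated (its future part is what is being re-optimized)."""
    out = []
    for e in events:
        if e.start_time >= now:
            continue
        end = e.start_time + e.duration
        if end <= now:
            out.append(e)
        else:
            frac = (now - e.start_time) / e.duration
            out.append(DoseEvent(e.start_time, e.amount * frac, now - e.start_time))
    return out


def optimize_doses(
    fit_or_ensemble: FitResult | EnsembleFit,
    regimen: Regimen,
    target: float,
    now: float,
    horizon: float = 12.0,
) -> DoseRecommendation:
    """Solve for the first two doses after the informing concentration at
    time ``now`` (h).  ``regimen`` carries the prescribed course; only the
    part administered before ``now`` is kept as legacy drug.

    For intermittent dosing the maintenance descriptor
    (``regimen.interval``/``regimen.duration``) is required; the first new
    dose is given at the next scheduled administration time.  For continuous
    infusion the first rate segment spans ``horizon`` h (default 12 h).
    """
    if not target > 0:
        raise ValueError("target concentration must be > 0")
    wfits = _weighted_fits(fit_or_ensemble)
    history = _history_until(regimen.events, now)
    clamped = False

    if regimen.mode == "intermittent":
        tau, dur = regimen.interval, regimen.duration
        if tau is None or dur is None:
            raise ValueError("intermittent optimization needs interval and duration")
        past_starts = [e.start_time for e in regimen.events if e.start_time <= now]
        t_next = (past_starts[-1] if past_starts else 0.0) + tau
        while t_next <= now:
            t_next += tau
        t_eval = t_next + tau  # trough at the end of the next interval

        legacy = unit = 0.0
        unit_ss = 0.0
        for w, fit in wfits:
            legacy += w * concentration(fit.params, Regimen("intermittent", history, tau, dur), t_eval)
            unit += w * concentration(
                fit.params,
                Regimen("intermittent", [DoseEvent(t_next, 1.0, dur)], tau, dur),
                t_eval,
            )
            unit_ss += w * steady_state_trough(fit.params, 1.0, tau, dur)
        if unit <= 0 or unit_ss <= 0:
            raise RuntimeError("non-positive unit dose response; inconsistent fit state")
        d1 = (target - legacy) / unit
        if d1 < 0:
            d1, clamped = 0.0, True
        d2 = target / unit_ss
        predicted = legacy + d1 * unit
        return DoseRecommendation(
            mode="intermittent",
            target=target,
            first_dose=d1,
            second_dose=d2,
            first_dose_q12h=normalize_q12h(d1, tau),
            second_dose_q12h=normalize_q12h(d2, tau),
            predicted_at_eval=predicted,
            eval_time=t_eval,
            clamped=clamped,
        )

    # continuous infusion
    t_eval = now + horizon
    legacy = unit = 0.0
    inv_cl = 0.0
    for w, fit in wfits:
        legacy += w * concentration(fit.params, Regimen("continuous", history), t_eval)
        unit += w * concentration(
            fit.params,
            Regimen("continuous", [DoseEvent(now, horizon, horizon)]),  # 1 mg/h
            t_eval,
        )
        inv_cl += w / fit.params["CL"]
    if unit <= 0:
        raise RuntimeError("non-positive unit rate response; inconsistent fit state")
    r1 = (target - legacy) / unit
    if r1 < 0:
        r1, clamped = 0.0, True
    r2 = target / inv_cl  # weighted plateau sum_i w_i r2/CL_i == target
    return DoseRecommendation(
        mode="continuous",
        target=target,
        first_dose=r1,
        second_dose=r2,
        first_dose_q12h=r1 * 12.0,
        second_dose_q12h=r2 * 12.0,
        predicted_at_eval=legacy + r1 * unit,
        eval_time=t_eval,
        clamped=clamped,
    )


def normalize_q12h(dose: float, interval: float) -> float:
    """Express ``dose`` mg given every ``interval`` h as mg per 12 h.
    (A continuous rate in mg/h is a dose per 1 h: pass ``interval=1``.)"""
    if not interval > 0:
        raise ValueError("interval must be > 0")
    return dose * 12.0 / interval


def dose_difference(predicted_q12h: float, prescribed_q12h: float) -> float:
    """Model-predicted minus prescribed q12h dose (mg)."""
    return predicted_q12h - prescribed_q12h


def clinically_relevant(difference: float) -> bool:
    """|difference| >= 125 mg q12h (boundary inclusive)."""
    return abs(difference) >= CLINICALLY_RELEVANT_MG


def dose_difference_summary(df: pd.DataFrame, by: str = "category") -> pd.DataFrame:
    """Median [IQR] of the q12h dose difference and the fraction of
    clinically relevant differences, per exposure category.

    ``df`` needs columns ``difference`` and ``by``.
    """
    def _agg(g: pd.Series) -> pd.Series:
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        return pd.Series(
            {
                "n": len(g),
                "median": med,
                "iqr_lo": q1,
                "iqr_hi": q3,
                "pct_clinically_relevant": 100.0 * np.mean(np.abs(g) >= CLINICALLY_RELEVANT_MG),
            }
        )

    return df.groupby(by)["difference"].apply(_agg).unstack()
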