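"""Model selection (MSA) and model averaging (MAA) over a fitted panel.

Each panel model is MAP-fitted to the informing concentration(s); the fit
criterion is either the minimized MAP objective (OFV scheme) or the squared
prediction error (SSE scheme).  Normalized weights are

    OFV:  w_i = exp(-(OFV_i - min_j OFV_j)/2) / sum_k exp(-(OFV_k - min_j OFV_j)/2)
    SSE:  w_i = (1/SSE_i) / sum_k (1/SSE_k)        (SSE floored at 1e-12)

MSA predicts with the single maximal-weight model; MAA predicts with the
weighted sum of all panel predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .engine import Regimen
from .mapfit import FitResult, posterior_predict

__all__ = ["EnsembleFit", "compute_weights", "build_ensemble", "msa_predict", "maa_predict"]

logger = logging.getLogger(__name__)

SSE_FLOOR = 1e-12  # (mg/L)^2
SCHEMES = ("OFV", "SSE")


def compute_weights(fits: list[FitResult], scheme: str) -> np.ndarray:
    """Normalized panel weights under the OFV or SSE scheme."""
    if not fits:
        raise ValueError("empty model panel")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "OFV":
        crit = np.array([f.ofv for f in fits])
        if not np.all(np.isfinite(crit)):
            raise ValueError("non-finite OFV in panel")
        raw = np.exp(-0.5 * (crit - crit.min()))
    else:
        crit = np.maximum(np.array([f.sse for f in fits]), SSE_FLOOR)
        raw = 1.0 / crit
    return raw / raw.sum()


@dataclass
class EnsembleFit:
    """Per-model MAP fits plus normalized weights for one weighting scheme."""

    fits: list[FitResult]
    scheme: str
    weights: np.ndarray
    selected_model_id: str

    @property
    def selected_fit(self) -> FitResult:
        for f in self.fits:
            if f.model_id == self.selected_model_id:
                return f
        raise KeyError(self.selected_model_id)


def build_ensemble(fits: list[FitResult], scheme: str) -> EnsembleFit:
    """Assemble weights and the selected (maximal-weight) model.

    Ties are broken by panel (registry) order and logged.
    """
    weights = compute_weights(fits, scheme)
    best = int(np.argmax(weights))  # argmax takes the first maximum: registry order
    if np.sum(np.isclose(weights, weights[best], rtol=0, atol=1e-12)) > 1:
        logger.info(
            "weight tie under %s scheme; selected %s by registry order",
            scheme,
            fits[best].model_id,
        )
    return EnsembleFit(
        fits=fits, scheme=scheme, weights=weights, selected_model_id=fits[best].model_id
    )


def msa_predict(ensemble: EnsembleFit, regimen: Regimen, t):
    """Prediction of the selected (best-fitting) panel model."""
    return posterior_predict(ensemble.selected_fit, regimen, t)


def maa_predict(ensemble: EnsembleFit, regimen: Regimen, t):
    """Weighted prediction over all panel models."""
    preds = [posterior_predict(f, regimen, t) for f in ensemble.fits]
    return float(np.dot(ensemble.weights, preds)) if np.isscalar(preds[0]) else (
        np.tensordot(ensemble.weights, np.asarray(preds), axes=1)
    )
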