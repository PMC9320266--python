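"""Population-PK model registry and covariate transforms.

A :class:`PopPKModel` is a declarative description of a linear one- or
two-compartment vancomycin model: typical parameter values (theta),
covariate relations, a log-normal between-subject variance-covariance
matrix (omega), and a combined additive + proportional residual-error
model with variance ``g^2 = a^2 + (b*f)^2`` for a model prediction ``f``.

Models are stored as YAML documents (one per model, or a multi-document
file / directory as a registry) so that the forecasting pipeline runs
with any user-supplied panel of one or more models.  The Goti model for
hospitalized adults (two compartments; clearance scaled by
Cockcroft-Gault creatinine clearance and a dialysis factor; central
volume scaled by total body weight) ships as the reference registry
entry.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateRecord",
    "CovariateRelation",
    "PopPKModel",
    "IndividualParameters",
    "MissingCovariateError",
    "ModelValidationError",
    "crcl_cockcroft_gault",
    "egfr_ckd_epi",
    "individual_parameters",
    "load_model_registry",
    "write_registry",
    "default_registry_path",
    "load_default_panel",
]


class MissingCovariateError(ValueError):
    """A covariate required by an equation or model is absent."""


class ModelValidationError(ValueError):
    """A model definition violates the PopPKModel invariants."""


def _locf(series: Sequence[tuple[float, float]] | None, t: float, fallback: float) -> float:
    """Last-observation-carried-forward lookup; before the first entry the
    baseline value is used."""
    if not series:
        return fallback
    value = fallback
    for time, v in series:
        if time <= t:
            value = v
        else:
            break
    return value


@dataclass
class CovariateRecord:
    """Patient covariates for one treatment course.

    Time-varying creatinine/weight are optional ``(time_h, value)`` series
    evaluated as step functions (LOCF); times are hours from the first dose.
    """

    age: float
    sex: str  # "male" | "female"
    total_body_weight: float
    serum_creatinine: float
    dialysis: bool = False
    icu: bool = False
    creatinine_series: list[tuple[float, float]] | None = None
    weight_series: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.age >= 18:
            raise ValueError(f"adult cohort: age must be >= 18, got {self.age}")
        if not self.total_body_weight > 0:
            raise ValueError("total_body_weight must be > 0")
        if not self.serum_creatinine > 0:
            raise ValueError("serum_creatinine must be > 0")
        for name in ("creatinine_series", "weight_series"):
            series = getattr(self, name)
            if series:
                times = [t for t, _ in series]
                if sorted(times) != times or len(set(times)) != len(times):
                    raise ValueError(f"{name} must be sorted by time with no duplicates")

    def creatinine_at(self, t: float) -> float:
        return _locf(self.creatinine_series, t, self.serum_creatinine)

    def weight_at(self, t: float) -> float:
        return _locf(self.weight_series, t, self.total_body_weight)


def crcl_cockcroft_gault(
    cov: CovariateRecord, at_time: float = 0.0, cap: float | None = None
) -> float:
    """Cockcroft-Gault estimated creatinine clearance in mL/min.

    ``((140 - age) * weight) / (72 * Scr)``, times 0.85 for females, using
    total body weight.  ``cap`` optionally truncates high values (logged).
    """
    for name in ("age", "total_body_weight", "serum_creatinine"):
        if getattr(cov, name, None) is None:
            raise MissingCovariateError(f"missing covariate: {name}")
    scr = cov.creatinine_at(at_time)
    wt = cov.weight_at(at_time)
    crcl = ((140.0 - cov.age) * wt) / (72.0 * scr)
    if cov.sex == "female":
        crcl *= 0.85
    if cap is not None and crcl > cap:
        logger.info("CrCl %.1f mL/min capped at %.1f mL/min", crcl, cap)
        crcl = cap
    if not crcl > 0:
        raise ValueError(f"non-positive creatinine clearance ({crcl:.2f}); check age/weight/Scr")
    return crcl


def egfr_ckd_epi(cov: CovariateRecord, at_time: float = 0.0) -> float:
    """CKD-EPI (2009) estimated GFR, mL/min/1.73 m^2, without the ethnicity
    coefficient.  Used for cohort description only."""
    scr = cov.creatinine_at(at_time)
    if cov.sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    ratio = scr / kappa
    egfr = (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993**cov.age
        * sex_factor
    )
    return egfr


@dataclass
class CovariateRelation:
    """One multiplicative covariate effect on a PK parameter.

    forms:
      - ``power``: ``(x / reference) ** value``
      - ``proportional``: ``x / reference``
      - ``linear``: ``1 + value * (x - reference)``
      - ``factor_if_flag``: ``value`` when the boolean covariate is set, else 1
    """

    parameter: str
    covariate: str
    form: str
    value: float
    reference: float = 1.0

    _FORMS = ("power", "proportional", "linear", "factor_if_flag")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ModelValidationError(
                f"unknown covariate-relation form {self.form!r} (expected one of {self._FORMS})"
            )


#: covariate names resolvable from a CovariateRecord (directly or derived)
_DERIVED_COVARIATES = ("crcl_cg", "egfr_ckd_epi")
_FLAG_COVARIATES = ("dialysis", "icu")
_DIRECT_COVARIATES = ("age", "total_body_weight", "serum_creatinine")


def _covariate_value(name: str, cov: CovariateRecord, at_time: float, crcl_cap: float | None):
    if name == "crcl_cg":
        return crcl_cockcroft_gault(cov, at_time=at_time, cap=crcl_cap)
    if name == "egfr_ckd_epi":
        return egfr_ckd_epi(cov, at_time=at_time)
    if name == "serum_creatinine":
        return cov.creatinine_at(at_time)
    if name == "total_body_weight":
        return cov.weight_at(at_time)
    if name in _FLAG_COVARIATES:
        return bool(getattr(cov, name))
    if name == "sex":
        return cov.sex
    if hasattr(cov, name):
        return getattr(cov, name)
    raise MissingCovariateError(f"missing covariate: {name}")


@dataclass
class PopPKModel:
    """Declarative population-PK model definition.

    ``parameters`` maps ``CL``/``V1`` (and ``Q``/``V2`` for two compartments)
    to typical values in L/h and L.  ``eta_names`` lists the parameters that
    carry log-normal random effects, in the order of ``omega`` rows.
    Residual error: additive sd ``residual_additive`` (mg/L) and proportional
    sd ``residual_proportional`` (fraction).
    """

    model_id: str
    n_compartments: int
    parameters: dict[str, float]
    covariate_relations: list[CovariateRelation] = field(default_factory=list)
    eta_names: list[str] = field(default_factory=list)
    omega: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    residual_additive: float = 0.0
    residual_proportional: float = 0.0
    crcl_variant: str = "cockcroft_gault_total_body_weight"
    crcl_cap: float | None = None
    covariate_support: dict[str, tuple[float, float]] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.validate()

    def validate(self) -> None:
        mid = self.model_id
        if self.n_compartments not in (1, 2):
            raise ModelValidationError(f"{mid}: n_compartments must be 1 or 2")
        required = {"CL", "V1"} | ({"Q", "V2"} if self.n_compartments == 2 else set())
        missing = required - set(self.parameters)
        if missing:
            raise ModelValidationError(f"{mid}: missing parameters {sorted(missing)}")
        for name, tv in self.parameters.items():
            if not tv > 0:
                raise ModelValidationError(f"{mid}: typical value {name} must be > 0, got {tv}")
        k = len(self.eta_names)
        if self.omega.shape != (k, k):
            raise ModelValidationError(
                f"{mid}: omega shape {self.omega.shape} does not match eta_names ({k})"
            )
        if k:
            if not np.allclose(self.omega, self.omega.T):
                raise ModelValidationError(f"{mid}: omega must be symmetric")
            eigv = np.linalg.eigvalsh(self.omega)
            if eigv.min() < -1e-10:
                raise ModelValidationError(f"{mid}: omega is not positive semi-definite")
        for name in self.eta_names:
            if name not in self.parameters:
                raise ModelValidationError(f"{mid}: eta on unknown parameter {name!r}")
        if not (self.residual_additive > 0 or self.residual_proportional > 0):
            raise ModelValidationError(
                f"{mid}: at least one residual-error component must be > 0"
            )
        if self.residual_additive < 0 or self.residual_proportional < 0:
            raise ModelValidationError(f"{mid}: residual sds must be non-negative")
        known = set(_DIRECT_COVARIATES) | set(_FLAG_COVARIATES) | set(_DERIVED_COVARIATES)
        for rel in self.covariate_relations:
            if rel.parameter not in self.parameters:
                raise ModelValidationError(
                    f"{mid}: covariate relation on unknown parameter {rel.parameter!r}"
                )
            if rel.covariate not in known:
                raise ModelValidationError(
                    f"{mid}: unknown covariate {rel.covariate!r} in relation"
                )

    @property
    def n_eta(self) -> int:
        return len(self.eta_names)

    def residual_variance(self, f):
        """g^2 = a^2 + (b*f)^2 for model prediction(s) f."""
        return self.residual_additive**2 + (self.residual_proportional * np.asarray(f)) ** 2


@dataclass
class IndividualParameters:
    """Covariate-adjusted, eta-perturbed parameter values for one patient:
    ``theta_k,i = TV_k * prod(covariate factors) * exp(eta_k)``."""

    values: dict[str, float]
    n_compartments: int
    model_id: str = ""

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def individual_parameters(
    model: PopPKModel,
    cov: CovariateRecord,
    eta: Sequence[float] | None = None,
    at_time: float = 0.0,
) -> IndividualParameters:
    """Compose typical values, covariate factors and exp(eta).

    ``eta`` is ordered as ``model.eta_names``; ``None`` means all zero.
    Covariates outside the model's declared support trigger a warning (the
    value is still computed: extrapolation is logged, not fatal).
    """
    if eta is None:
        eta = np.zeros(model.n_eta)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (model.n_eta,):
        raise ValueError(f"eta has shape {eta.shape}, expected ({model.n_eta},)")

    values = dict(model.parameters)
    for rel in model.covariate_relations:
        x = _covariate_value(rel.covariate, cov, at_time, model.crcl_cap)
        if rel.form == "factor_if_flag":
            factor = rel.value if x else 1.0
        else:
            lo_hi = model.covariate_support.get(rel.covariate)
            if lo_hi is not None and not (lo_hi[0] <= x <= lo_hi[1]):
                warnings.warn(
                    f"{model.model_id}: covariate {rel.covariate}={x:.3g} outside "
                    f"declared support {lo_hi}; extrapolating",
                    stacklevel=2,
                )
            if rel.form == "power":
                factor = (x / rel.reference) ** rel.value
            elif rel.form == "proportional":
                factor = x / rel.reference
            else:  # linear
                factor = 1.0 + rel.value * (x - rel.reference)
        values[rel.parameter] = values[rel.parameter] * factor

    for name, e in zip(model.eta_names, eta):
        values[name] = values[name] * math.exp(e)

    for name, v in values.items():
        if not v > 0:
            raise ValueError(
                f"{model.model_id}: non-positive individual parameter {name}={v:.3g}"
            )
    return IndividualParameters(values=values, n_compartments=model.n_compartments,
                                model_id=model.model_id)


# ---------------------------------------------------------------------------
# registry I/O

def _model_to_dict(model: PopPKModel) -> dict:
    d: dict = {
        "model_id": model.model_id,
        "compartments": model.n_compartments,
        "parameters": {k: float(v) for k, v in model.parameters.items()},
        "covariate_relations": [
            {
                "parameter": r.parameter,
                "covariate": r.covariate,
                "form": r.form,
                "value": float(r.value),
                "reference": float(r.reference),
            }
            for r in model.covariate_relations
        ],
        "omega": {
            "names": list(model.eta_names),
            "matrix": [[float(x) for x in row] for row in model.omega],
        },
        "residual_error": {
            "additive": float(model.residual_additive),
            "proportional": float(model.residual_proportional),
        },
        "crcl_variant": model.crcl_variant,
    }
    if model.crcl_cap is not None:
        d["crcl_cap"] = float(model.crcl_cap)
    if model.covariate_support:
        d["covariate_support"] = {
            k: [float(v[0]), float(v[1])] for k, v in model.covariate_support.items()
        }
    if model.notes:
        d["notes"] = model.notes
    return d


def _model_from_dict(d: dict, source: str = "<registry>") -> PopPKModel:
    try:
        mid = d["model_id"]
        relations = [
            CovariateRelation(
                parameter=r["parameter"],
                covariate=r["covariate"],
                form=r["form"],
                value=float(r["value"]),
                reference=float(r.get("reference", 1.0)),
            )
            for r in d.get("covariate_relations", [])
        ]
        omega_block = d.get("omega", {"names": [], "matrix": []})
        resid = d.get("residual_error", {})
        support = {
            k: (float(v[0]), float(v[1]))
            for k, v in d.get("covariate_support", {}).items()
        }
        return PopPKModel(
            model_id=mid,
            n_compartments=int(d["compartments"]),
            parameters={k: float(v) for k, v in d["parameters"].items()},
            covariate_relations=relations,
            eta_names=list(omega_block.get("names", [])),
            omega=np.asarray(omega_block.get("matrix", []), dtype=float).reshape(
                len(omega_block.get("names", [])), -1
            )
            if omega_block.get("names")
            else np.zeros((0, 0)),
            residual_additive=float(resid.get("additive", 0.0)),
            residual_proportional=float(resid.get("proportional", 0.0)),
            crcl_variant=d.get("crcl_variant", "cockcroft_gault_total_body_weight"),
            crcl_cap=float(d["crcl_cap"]) if "crcl_cap" in d else None,
            covariate_support=support,
            notes=d.get("notes", ""),
        )
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(
            f"invalid model definition in {source} "
            f"(model_id={d.get('model_id', '?')!r}): {exc}"
        ) from exc


def load_model_registry(path: str | Path) -> list[PopPKModel]:
    """Load a panel of models from a YAML file (single- or multi-document)
    or a directory of ``*.yaml`` files, sorted by filename."""
    path = Path(path)
    models: list[PopPKModel] = []
    if path.is_dir():
        files = sorted(path.glob("*.yaml")) + sorted(path.glob("*.yml"))
        if not files:
            raise FileNotFoundError(f"no model files in registry directory {path}")
        for f in files:
            models.extend(load_model_registry(f))
    else:
        with open(path) as fh:
            for doc in yaml.safe_load_all(fh):
                if doc is None:
                    continue
                models.append(_model_from_dict(doc, source=str(path)))
    seen: set[str] = set()
    for m in models:
        if m.model_id in seen:
            raise ModelValidationError(f"duplicate model_id {m.model_id!r} in registry")
        seen.add(m.model_id)
    return models


def write_registry(models: Iterable[PopPKModel], path: str | Path) -> None:
    """Write a panel as a multi-document YAML file (round-trips numerically
    exactly: floats are serialized via repr)."""
    docs = [_model_to_dict(m) for m in models]
    with open(path, "w") as fh:
        yaml.safe_dump_all(docs, fh, sort_keys=False)


def default_registry_path() -> Path:
    """Directory holding the shipped registry files."""
    return Path(__file__).parent / "registry"


def load_default_panel(include_synthetic: bool = True) -> list[PopPKModel]:
    """Shipped panel: the Goti reference model plus, optionally, two
    synthetic filler models that stand in for additional published panel
    members so the multi-model machinery is exercised out of the box."""
    reg = default_registry_path()
    models = load_model_registry(reg / "goti.yaml")
    if include_synthetic:
        models += load_model_registry(reg / "panel_fillers_synthetic.yaml")
    return models
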