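"""Seeded generator of virtual hospital-wide vancomycin TDM cohorts.

The generator emulates the design of a hospital-wide adult TDM evaluation:
154 patients (95 intermittent / 59 continuous infusion, ICU and non-ICU),
log-normal covariate marginals calibrated to the study population (median
age 63 y, weight 76 kg, serum creatinine 0.83 mg/dL; 66.9% male, 39% ICU,
7.5% on renal replacement therapy), a rule-based standard-TDM dose
adjustment emulator standing in for unobservable clinician behaviour, and
two randomly selected non-overlapping pairs of consecutive concentrations
per patient (four concentrations each; consecutive samples <= 72 h apart).

Everything is a pure function of (config, seed): rerunning with the same
seed reproduces the cohort bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import DoseEvent, Regimen, predict_profile
from .models import CovariateRecord, PopPKModel, crcl_cockcroft_gault, individual_parameters

__all__ = [
    "CohortConfig",
    "VirtualPatient",
    "ConcentrationPair",
    "StudyDataset",
    "sample_covariates",
    "simulate_course",
    "sample_observations",
    "emulate_standard_tdm",
    "select_pairs",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design constants of the virtual cohort.

    Log-normal sigmas are calibrated so the sampled median/IQR match the
    study population's marginals (sigma = ln(q3/q1) / (2 * 0.6745)).
    """

    n_patients: int = 154
    n_intermittent: int = 95  # remainder are continuous infusion
    frac_male: float = 0.669
    frac_icu: float = 0.39
    frac_dialysis: float = 0.075
    age_median: float = 63.0
    age_sigma: float = 0.2271
    age_range: tuple[float, float] = (18.0, 99.0)
    weight_median: float = 76.0
    weight_sigma: float = 0.2850
    scr_median: float = 0.83
    scr_sigma: float = 0.4782
    # targets and course design
    target_intermittent: float = 15.0  # mg/L trough
    target_continuous: float = 22.5  # mg/L plateau
    mg_per_kg: float = 15.0  # initial dose heuristic
    infusion_h_per_g: float = 1.0  # intermittent infusion duration per 1000 mg
    n_samples: int = 5  # TDM samples per course
    # standard-TDM emulator
    dose_grid: float = 250.0  # mg, intermittent rounding
    rate_grid_daily: float = 100.0  # mg/24h, continuous rounding
    inertia: float = 0.10  # no change within +/-10% of target
    clinician_noise_sd: float = 0.2  # log-scale sd of the adjustment
    dose_bounds: tuple[float, float] = (250.0, 3000.0)
    daily_rate_bounds: tuple[float, float] = (500.0, 6000.0)
    # scales for degenerate study conditions (1.0 = study conditions)
    iiv_scale: float = 1.0
    residual_scale: float = 1.0
    lloq: float = 0.05  # mg/L; non-positive noisy draws are redrawn


@dataclass
class VirtualPatient:
    patient_id: str
    cov: CovariateRecord
    mode: str
    true_model_id: str
    true_eta: np.ndarray | None
    events: list[DoseEvent]
    interval: float | None  # h, intermittent maintenance
    inf_duration: float | None  # h, intermittent infusion duration
    obs_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    obs_values: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def regimen(self, until: float | None = None) -> Regimen:
        events = self.events
        if until is not None:
            events = [e for e in events if e.start_time < until]
        return Regimen(self.mode, list(events), self.interval, self.inf_duration)

    def prescribed_q12h_after(self, t: float) -> float:
        """Standard-TDM dose (mg per 12 h) in effect after time t, i.e. the
        dose the emulated clinician prescribed after seeing the sample at t."""
        later = [e for e in self.events if e.start_time > t]
        if not later:
            raise ValueError(f"no prescribed dose after t={t:.1f} h")
        e = later[0]
        if self.mode == "intermittent":
            return e.amount * 12.0 / self.interval
        return e.rate * 12.0


@dataclass(frozen=True)
class ConcentrationPair:
    """Two consecutive observations; the first informs the fit, the second
    evaluates the prediction."""

    pair_id: str
    patient_id: str
    first_index: int
    second_index: int
    t_first: float
    y_first: float
    t_second: float
    y_second: float


@dataclass
class StudyDataset:
    patients: list[VirtualPatient]
    pairs: list[ConcentrationPair]
    config: CohortConfig
    seed: int | None = None


# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def sample_covariates(n: int, seed_or_rng, config: CohortConfig = CohortConfig()) -> list[CovariateRecord]:
    """Draw n covariate records from the calibrated marginals (independent
    log-normals for age/weight/creatinine, Bernoulli flags)."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = []
    for _ in range(n):
        lo, hi = config.age_range
        age = _lognormal(rng, config.age_median, config.age_sigma)
        while not (lo <= age <= hi):
            age = _lognormal(rng, config.age_median, config.age_sigma)
        out.append(
            CovariateRecord(
                age=age,
                sex="male" if rng.random() < config.frac_male else "female",
                total_body_weight=_lognormal(rng, config.weight_median, config.weight_sigma),
                serum_creatinine=_lognormal(rng, config.scr_median, config.scr_sigma),
                dialysis=bool(rng.random() < config.frac_dialysis),
                icu=bool(rng.random() < config.frac_icu),
            )
        )
    return out


def _round_to(x: float, grid: float, bounds: tuple[float, float]) -> float:
    return float(np.clip(round(x / grid) * grid, bounds[0], bounds[1]))


def emulate_standard_tdm(
    current_dose: float,
    observed: float,
    target: float,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    continuous: bool = False,
) -> float:
    """Rule-based stand-in for clinician dose adjustment after a TDM sample:
    proportional correction ``dose * target/observed`` with an inertia band
    (no change within +/- ``config.inertia`` of target), optional log-normal
    clinician noise, and rounding to the formulary grid.

    For continuous infusion ``current_dose`` is the rate in mg/h and the
    grid/bounds are expressed per 24 h.
    """
    if abs(observed - target) / target <= config.inertia:
        return current_dose
    new = current_dose * target / observed
    if rng is not None and config.clinician_noise_sd > 0:
        new *= math.exp(config.clinician_noise_sd * rng.standard_normal())
    if continuous:
        daily = _round_to(new * 24.0, config.rate_grid_daily, config.daily_rate_bounds)
        return daily / 24.0
    return _round_to(new, config.dose_grid, config.dose_bounds)


def _observe(f: float, model: PopPKModel, config: CohortConfig, rng: np.random.Generator) -> float:
    """y = f (1 + b eps1) + a eps2; non-positive draws redrawn above the LLOQ."""
    a = model.residual_additive * config.residual_scale
    b = model.residual_proportional * config.residual_scale
    for _ in range(1000):
        y = f * (1.0 + b * rng.standard_normal()) + a * rng.standard_normal()
        if y > config.lloq:
            return float(y)
    return max(float(f), config.lloq)  # pathological noise configuration


def sample_observations(
    noiseless: Sequence[float] | np.ndarray,
    model: PopPKModel,
    seed_or_rng,
    config: CohortConfig = CohortConfig(),
) -> np.ndarray:
    """Apply the measurement model ``y = f(1 + b eps1) + a eps2`` to a
    noiseless concentration profile, using the generating model's residual
    parameters; non-positive draws are redrawn above the quantification
    floor."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return np.array([_observe(float(f), model, config, rng) for f in noiseless])


def _draw_eta(model: PopPKModel, config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    if model.n_eta == 0:
        return np.zeros(0)
    L = np.linalg.cholesky(model.omega + 1e-12 * np.eye(model.n_eta))
    return config.iiv_scale * (L @ rng.standard_normal(model.n_eta))


def simulate_course(
    patient_id: str,
    cov: CovariateRecord,
    mode: str,
    model: PopPKModel,
    rng: np.random.Generator,
    config: CohortConfig = CohortConfig(),
) -> VirtualPatient:
    """Forward-simulate one treatment course under the standard-TDM loop:
    initial dosing by a weight/renal-function heuristic, noisy samples at
    routine times, and emulated clinician adjustments after each sample."""
    eta = _draw_eta(model, config, rng)
    params = individual_parameters(model, cov, eta)
    crcl = crcl_cockcroft_gault(cov)

    if mode == "intermittent":
        tau = 12.0 if crcl >= 60 else (24.0 if crcl >= 30 else 48.0)
        dose = _round_to(config.mg_per_kg * cov.total_body_weight, config.dose_grid,
                         (config.dose_bounds[0], 2000.0))
        dur = max(1.0, dose / 1000.0 * config.infusion_h_per_g)
        step = max(tau, 24.0)
        first_sample = 36.0 if tau == 12.0 else 2.0 * tau
        sample_times = [first_sample + k * step for k in range(config.n_samples)]
        t_end = sample_times[-1]
        events: list[DoseEvent] = []
        obs_t, obs_y = [], []
        staged: float | None = None
        t = 0.0
        while t <= t_end:
            if staged is not None:
                dose = staged
                staged = None
            if t in sample_times and events:
                f = float(predict_profile(params, Regimen(mode, list(events), tau, dur), np.array([t]))[0])
                y = _observe(f, model, config, rng)
                obs_t.append(t)
                obs_y.append(y)
                staged = emulate_standard_tdm(dose, y, config.target_intermittent, config, rng)
            dur = max(1.0, dose / 1000.0 * config.infusion_h_per_g)
            events.append(DoseEvent(t, dose, dur))
            t += tau
        return VirtualPatient(patient_id, cov, mode, model.model_id, eta, events, tau, dur,
                              np.array(obs_t), np.array(obs_y))

    # continuous infusion
    load = _round_to(config.mg_per_kg * cov.total_body_weight, config.dose_grid,
                     (config.dose_bounds[0], 2000.0))
    load_dur = max(1.0, load / 1000.0 * config.infusion_h_per_g)
    cl_pop = individual_parameters(model, cov, None)["CL"]  # clinician's population guess
    rate = _round_to(config.target_continuous * cl_pop * 24.0, config.rate_grid_daily,
                     config.daily_rate_bounds) / 24.0
    sample_times = [24.0 * (k + 1) for k in range(config.n_samples)]
    t_end = sample_times[-1] + 12.0
    events = [DoseEvent(0.0, load, load_dur)]
    obs_t, obs_y = [], []
    seg_start = load_dur
    for t_s in sample_times:
        events_now = events + [DoseEvent(seg_start, rate * (t_s - seg_start), t_s - seg_start)]
        f = float(predict_profile(params, Regimen(mode, events_now), np.array([t_s]))[0])
        y = _observe(f, model, config, rng)
        obs_t.append(t_s)
        obs_y.append(y)
        new_rate = emulate_standard_tdm(rate, y, config.target_continuous, config, rng,
                                        continuous=True)
        events.append(DoseEvent(seg_start, rate * (t_s - seg_start), t_s - seg_start))
        rate, seg_start = new_rate, t_s
    events.append(DoseEvent(seg_start, rate * (t_end - seg_start), t_end - seg_start))
    return VirtualPatient(patient_id, cov, mode, model.model_id, eta, events, None, None,
                          np.array(obs_t), np.array(obs_y))


def select_pairs(
    patient: VirtualPatient, rng: np.random.Generator, max_gap: float = 72.0
) -> list[ConcentrationPair]:
    """Uniformly select two non-overlapping pairs of consecutive samples
    whose within-pair gap is <= ``max_gap`` h."""
    t = patient.obs_times
    eligible = [i for i in range(len(t) - 1) if t[i + 1] - t[i] <= max_gap]
    combos = [(i, j) for i in eligible for j in eligible if j >= i + 2]
    if not combos:
        raise ValueError(f"{patient.patient_id}: no two non-overlapping eligible pairs")
    i, j = combos[int(rng.integers(len(combos)))]
    out = []
    for k, idx in enumerate((i, j)):
        out.append(
            ConcentrationPair(
                pair_id=f"{patient.patient_id}-p{k + 1}",
                patient_id=patient.patient_id,
                first_index=idx,
                second_index=idx + 1,
                t_first=float(t[idx]),
                y_first=float(patient.obs_values[idx]),
                t_second=float(t[idx + 1]),
                y_second=float(patient.obs_values[idx + 1]),
            )
        )
    return out


def generate_cohort(
    model: PopPKModel, config: CohortConfig = CohortConfig(), seed: int = 0
) -> StudyDataset:
    """Generate the full virtual study dataset from (config, seed)."""
    rng = np.random.default_rng(seed)
    covs = sample_covariates(config.n_patients, rng, config)
    patients: list[VirtualPatient] = []
    pairs: list[ConcentrationPair] = []
    for i, cov in enumerate(covs):
        mode = "intermittent" if i < config.n_intermittent else "continuous"
        patient = simulate_course(f"pt{i + 1:03d}", cov, mode, model, rng, config)
        patients.append(patient)
        pairs.extend(select_pairs(patient, rng))
    return StudyDataset(patients=patients, pairs=pairs, config=config, seed=seed)
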