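"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the threat conditioning and extinction task (4 / 10 /
8 presentations per CS across the three phases, 80% CS+ reinforcement),
UCS responses that diminish across acquisition, trial-level Gaussian noise
and missingness, and planted associations between anxiety severity and the
safety-learning parameter, moderated by nucleus accumbens gray-matter
volume.  It shares one forward model with the fitter
(:func:`threatlearn.models.predict_series`), so noiseless simulation is
bit-identical to model prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .exceptions import ParameterError
from .models import get_spec, predict_series
from .series import SubjectRecord, TrialSeries
from .task import TaskSchedule, build_task_schedule


@dataclass(frozen=True)
class UcsProfile:
    """UCS-response amplitudes diminishing exponentially across acquisition.

    The expected amplitude on the j-th reinforced trial (j = 1, 2, ...) is
    ``initial_amplitude * exp(-decay_rate * (j - 1))``, with additive
    Gaussian noise of sd ``noise_sd`` clamped at 0 (amplitudes are
    square-root transformed and therefore non-negative).  Units: µS^0.5.
    """

    initial_amplitude: float = 1.0
    decay_rate: float = 0.12
    noise_sd: float = 0.10

    def __post_init__(self):
        if self.initial_amplitude < 0 or self.decay_rate < 0 \
                or self.noise_sd < 0:
            raise ParameterError("UcsProfile fields must be non-negative")


#: plausible generating ranges per parameter: (mean, sd, low, high)
DEFAULT_PARAM_DISTRIBUTION: dict[str, tuple[float, float, float, float]] = {
    "alpha_csp": (0.40, 0.18, 0.05, 0.90),
    "alpha_csm": (0.35, 0.18, 0.05, 0.90),
    "phi_csp": (0.25, 0.15, 0.00, 0.80),
    "phi_csm": (0.25, 0.15, 0.00, 0.80),
    "gamma_csp": (0.50, 0.20, 0.05, 0.95),
    "gamma_csm": (0.50, 0.20, 0.05, 0.95),
    "kappa_csp": (0.45, 0.18, 0.05, 0.90),
    "kappa_csm": (0.40, 0.18, 0.05, 0.90),
    "beta0": (0.00, 0.20, -0.50, 0.50),
    "beta1": (0.80, 0.35, 0.10, 2.00),
    "beta2": (0.30, 0.20, -0.50, 1.00),
}

#: FreeSurfer-style subcortical segmentation: mean volume (mm^3) and CV
SUBCORTICAL_STRUCTURES: dict[str, float] = {
    "amygdala_l": 1600.0, "amygdala_r": 1650.0,
    "hippocampus_l": 4250.0, "hippocampus_r": 4300.0,
    "thalamus_l": 7600.0, "thalamus_r": 7500.0,
    "diencephalon_l": 4300.0, "diencephalon_r": 4250.0,
    "caudate_l": 3700.0, "caudate_r": 3750.0,
    "putamen_l": 5300.0, "putamen_r": 5250.0,
    "pallidum_l": 1900.0, "pallidum_r": 1850.0,
    "accumbens_l": 620.0, "accumbens_r": 600.0,
    "brainstem": 21000.0,
}

#: structure whose volume moderates the anxiety/safety-learning coupling
MODERATING_STRUCTURE = "accumbens_l"


def safety_parameter(model_id: int) -> str:
    """Name of the safety-learning parameter for a model.

    In habituation models the CS- response decline is governed by the CS-
    habituation/decay rate φ_CS-; in the remaining variants the CS-
    learning rate plays that role.
    """
    spec = get_spec(model_id)
    if "phi_csm" in spec.params:
        return "phi_csm"
    if "alpha_csm" in spec.params:
        return "alpha_csm"
    return "gamma_csm" if "gamma_csm" in spec.params else spec.params[-1]


@dataclass
class CohortDesign:
    """Generative design of a synthetic cohort.

    Defaults are the study conditions the pipeline is meant to operate
    under: a cohort the size of the source sample, a moderate negative
    standardized coupling between anxiety severity and the safety-learning
    parameter, and a moderation of that coupling by left accumbens volume.
    """

    n_subjects: int = 215
    true_model_id: int = 7
    param_distribution: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_DISTRIBUTION))
    anxiety_slope_on_safety_lr: float = -0.3
    gmv_moderation_slope: float = 0.5
    coupled_param: str | None = None     # default: safety_parameter(model)
    missing_rate: float = 0.05
    obs_noise_sd: float = 0.12
    v_init_range: tuple[float, float] = (0.05, 0.45)
    ucs: UcsProfile = field(default_factory=UcsProfile)
    age_range: tuple[float, float] = (8.0, 50.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ParameterError("missing_rate must lie in [0, 1]")
        if self.obs_noise_sd < 0:
            raise ParameterError("obs_noise_sd must be >= 0")
        for name, (_, sd, lo, hi) in self.param_distribution.items():
            if sd < 0 or hi < lo:
                raise ParameterError(f"bad distribution for {name}")


def simulate_ucs_responses(profile: UcsProfile, schedule: TaskSchedule,
                           seed) -> np.ndarray:
    """One UCS SCR per reinforced trial, decaying across acquisition."""
    rng = np.random.default_rng(seed)
    n = len(schedule.reinforced_trials())
    j = np.arange(n)
    mean = profile.initial_amplitude * np.exp(-profile.decay_rate * j)
    r = mean + rng.normal(0.0, profile.noise_sd, size=n) \
        if profile.noise_sd > 0 else mean
    return np.clip(r, 0.0, None)


def simulate_subject(model, params: dict[str, float],
                     schedule: TaskSchedule,
                     ucs: UcsProfile = UcsProfile(),
                     obs_noise_sd: float = 0.0,
                     seed=0,
                     subject_id: str = "sim",
                     v_init: float = 0.2,
                     missing_rate: float = 0.0) -> TrialSeries:
    """Simulate one subject's TrialSeries under a generating model.

    Observed SCR per CS trial is the model-predicted value plus Gaussian
    noise, clamped at 0.  Pre-conditioning trials fluctuate around the
    initial associative strength (so the fitter's anchor is observable);
    extinction continues from the per-cue end-of-conditioning state.
    """
    spec = get_spec(model)
    rng = np.random.default_rng(seed)
    ucs_values = simulate_ucs_responses(ucs, schedule, rng)

    pred_cond = predict_series(spec, params, schedule, "conditioning",
                               ucs_values=ucs_values, v_init=v_init)
    rows = []
    cond_trials = schedule.phase_trials("conditioning")

    for tr in schedule.phase_trials("pre"):
        rows.append([tr.phase, tr.cs, tr.index, tr.reinforced, v_init,
                     math.nan])
    ridx = 0
    for tr, pred in zip(cond_trials, pred_cond):
        u = math.nan
        if tr.reinforced:
            u = float(ucs_values[ridx])
            ridx += 1
        rows.append([tr.phase, tr.cs, tr.index, tr.reinforced, float(pred),
                     u])

    if "extinction" in spec.phases:
        v_end = _end_of_conditioning_values(spec, params, schedule,
                                            ucs_values, v_init)
        pred_ext = predict_series(spec, params, schedule, "extinction",
                                  v_init=v_end)
        for tr, pred in zip(schedule.phase_trials("extinction"), pred_ext):
            rows.append([tr.phase, tr.cs, tr.index, tr.reinforced,
                         float(pred), math.nan])
    else:
        for tr in schedule.phase_trials("extinction"):
            rows.append([tr.phase, tr.cs, tr.index, tr.reinforced,
                         math.nan, math.nan])

    df = pd.DataFrame(rows, columns=["phase", "cs", "trial", "reinforced",
                                     "scr", "ucs_scr"])
    scr = df["scr"].to_numpy(dtype=float)
    if obs_noise_sd > 0:
        scr = scr + rng.normal(0.0, obs_noise_sd, size=len(scr))
    scr = np.clip(scr, 0.0, None)
    missing = np.zeros(len(df), dtype=bool)
    if missing_rate > 0:
        missing = rng.random(len(df)) < missing_rate
    scr[missing] = math.nan
    df["scr"] = scr
    df["missing"] = missing
    return TrialSeries(subject_id=subject_id, trials=df,
                       order_id=schedule.order_id)


def _end_of_conditioning_values(spec, params, schedule, ucs_values, v_init):
    """Per-cue associative strength carried from conditioning to extinction,
    clamped at 0 (square-root amplitudes are non-negative)."""
    v = models.final_values(spec, params, schedule, "conditioning",
                            ucs_values=ucs_values, v_init=v_init)
    return {c: max(val, 0.0) for c, val in v.items()}


def simulate_cohort(design: CohortDesign) -> list[SubjectRecord]:
    """Generate a full synthetic cohort with planted covariate structure.

    Each subject's safety-learning parameter is coupled to its anxiety
    z-score with the design's standardized slope, and that coupling is
    itself moderated by (z-scored) left accumbens volume.  Structure-wise
    gray-matter volumes carry intracranial-volume and sex effects so the
    nuisance regression downstream is exercised.  Ground-truth parameters
    are stored on each record for recovery tests.
    """
    rng = np.random.default_rng(design.seed)
    spec = get_spec(design.true_model_id)
    coupled = design.coupled_param or safety_parameter(design.true_model_id)
    if coupled not in spec.params:
        raise ParameterError(
            f"coupled parameter {coupled!r} not in model {spec.model_id}")

    n = design.n_subjects
    age = rng.uniform(*design.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    anxiety = rng.standard_normal(n)
    group = np.where(anxiety > 0.25, "anxiety", "healthy")

    # intracranial volume with a sex effect; structure volumes scale with it
    icv = rng.normal(1.45e6, 1.1e5, size=n) + 8.0e4 * sex
    icv_z = (icv - icv.mean()) / icv.std()
    gmv = {}
    # ICV explains roughly a third of between-subject volume variance;
    # the rest is structure-specific
    for struct, mean_vol in SUBCORTICAL_STRUCTURES.items():
        noise = rng.normal(0.0, 0.08, size=n)
        gmv[struct] = mean_vol * (1.0 + 0.06 * icv_z + 0.02 * sex + noise)
    # the planted moderation rides on the structure-specific part of the
    # accumbens volume (residual of ICV and sex), not on global head size:
    # other structures share only the global component and stay null
    mod_gmv = np.asarray(gmv[MODERATING_STRUCTURE])
    nuis = np.column_stack([np.ones(n), icv_z, sex])
    coef, *_ = np.linalg.lstsq(nuis, mod_gmv, rcond=None)
    mod_res = mod_gmv - nuis @ coef
    mod_z = (mod_res - mod_res.mean()) / mod_res.std()

    rho = design.anxiety_slope_on_safety_lr
    gam = design.gmv_moderation_slope
    resid_sd = math.sqrt(max(1.0 - rho * rho, 0.05))

    records = []
    for i in range(n):
        params = {}
        for name in spec.params:
            mean, sd, lo, hi = design.param_distribution[name]
            if name == coupled:
                z = (rho * anxiety[i] + gam * anxiety[i] * mod_z[i]
                     + resid_sd * rng.standard_normal())
            else:
                z = rng.standard_normal()
            params[name] = float(np.clip(mean + sd * z, lo, hi))
        schedule = build_task_schedule("A" if i % 2 == 0 else "B",
                                       design.seed)
        v_init = float(rng.uniform(*design.v_init_range))
        series = simulate_subject(
            spec, params, schedule, ucs=design.ucs,
            obs_noise_sd=design.obs_noise_sd,
            seed=rng.integers(0, 2**31 - 1),
            subject_id=f"S{i:04d}", v_init=v_init,
            missing_rate=design.missing_rate)
        records.append(SubjectRecord(
            series=series, age=float(age[i]), sex=int(sex[i]),
            group=str(group[i]), anxiety_z=float(anxiety[i]),
            icv=float(icv[i]),
            gmv={s: float(v[i]) for s, v in gmv.items()},
            true_params=params, true_model_id=spec.model_id))
    return records
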