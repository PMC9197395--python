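"""Forward models of trial-by-trial threat learning.

Fourteen variants of associative-learning models predict the
square-root-transformed skin-conductance response (SCR) to the threat cue
(CS+) and safety cue (CS-) across conditioning and extinction:

* models 1-8: Rescorla-Wagner (RW) models in which the CS+ associative
  strength v is updated by the prediction error δ = r − v on reinforced
  trials (r being the observed SCR to the UCS) and the CS- strength is
  updated from the same error (threat generalization).  Optional features
  are a learning-inertia term (the error summed over the km most recent
  update events), a Bayesian learning-rate decay α(t) = α/√t, and a
  multiplicative habituation term e^(−φ·[t−t0]⁺) applied to the emitted
  prediction;
* model 9: RW / Pearce-Hall hybrid with an adaptive associability
  α_PH(t+1) = γ|δ| + (1−γ)α_PH(t) and value update v += κ·α_PH·δ;
* models 10-12: hybrid models with a binary outcome (b_UCS ∈ {0, 1}) and a
  linear read-out of value and/or associability onto SCR
  (β0 + β1·V [+ β2·α_PH]);
* models 13-14: a Beta-Bernoulli uncertainty model whose counts (α_B, β_B)
  track UCS occurrences per cue; SCR is read out linearly from
  z = h + E[θ] with h = −ln(α_B + β_B), optionally habituated.

During extinction no UCS is ever delivered: each cue's value is updated by
its own error δ = 0 − v on every trial (responses extinguish), with no
cross-cue generalization.  The uncertainty models are conditioning-only,
since without any UCS their counts carry no outcome information.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ConfigurationError, InputError, ParameterError
from .series import TrialSeries
from .task import TaskSchedule

#: inertia window (number of *past* update events summed in addition to the
#: current one); a population-level constant shared by all subjects
KM = 2

#: habituation onset trial; habituation only acts from trial t0 onward
T0 = 2

CSP, CSM = "CS+", "CS-"


@dataclass(frozen=True)
class ModelSpec:
    """Identity and feature flags of one model variant."""

    model_id: int
    name: str
    params: tuple[str, ...]
    inertia: bool = False
    decay: bool = False
    habituation: bool = False
    hybrid: bool = False               # model 9 value update via κ·α_PH·δ
    readout: str = "none"              # 'none' | 'V' | 'alpha' | 'V+alpha' | 'uncertainty'
    binary_outcome: bool = False       # b_UCS in {0,1} instead of UCS SCR
    phases: tuple[str, ...] = ("conditioning", "extinction")
    #: parameters initialized from the 0.1-0.8 grid during fitting
    grid_params: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        """Number of free parameters (BIC complexity term)."""
        return len(self.params)


_A = ("alpha_csp", "alpha_csm")
_APHI = _A + ("phi_csp", "phi_csm")
_H = ("gamma_csp", "gamma_csm", "kappa_csp", "kappa_csm")
_K = ("kappa_csp", "kappa_csm")

MODEL_REGISTRY: dict[int, ModelSpec] = {
    1: ModelSpec(1, "RW", _A, grid_params=_A),
    2: ModelSpec(2, "RW+inertia", _A, inertia=True, grid_params=_A),
    3: ModelSpec(3, "RW+decay", _A, decay=True, grid_params=_A),
    4: ModelSpec(4, "RW+habituation", _APHI, habituation=True,
                 grid_params=_A),
    5: ModelSpec(5, "RW+inertia+decay", _A, inertia=True, decay=True,
                 grid_params=_A),
    6: ModelSpec(6, "RW+inertia+habituation", _APHI, inertia=True,
                 habituation=True, grid_params=_A),
    7: ModelSpec(7, "RW+decay+habituation", _APHI, decay=True,
                 habituation=True, grid_params=_A),
    8: ModelSpec(8, "RW+inertia+decay+habituation", _APHI, inertia=True,
                 decay=True, habituation=True, grid_params=_A),
    9: ModelSpec(9, "RW-PH hybrid", _H, hybrid=True, grid_params=_K),
    10: ModelSpec(10, "Hybrid(V)", _H + ("beta0", "beta1"), hybrid=True,
                  readout="V", binary_outcome=True, grid_params=_K),
    11: ModelSpec(11, "Hybrid(alpha)", _H + ("beta0", "beta1"), hybrid=True,
                  readout="alpha", binary_outcome=True, grid_params=_K),
    12: ModelSpec(12, "Hybrid(V+alpha)", _H + ("beta0", "beta1", "beta2"),
                  hybrid=True, readout="V+alpha", binary_outcome=True,
                  grid_params=_K),
    13: ModelSpec(13, "Uncertainty", ("beta0", "beta1"),
                  readout="uncertainty", binary_outcome=True,
                  phases=("conditioning",), grid_params=("beta1",)),
    14: ModelSpec(14, "Uncertainty+habituation",
                  ("beta0", "beta1", "phi_csp", "phi_csm"),
                  habituation=True, readout="uncertainty",
                  binary_outcome=True, phases=("conditioning",),
                  grid_params=("beta1",)),
}


def get_spec(model: int | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODEL_REGISTRY[int(model)]
    except (KeyError, TypeError):
        raise ConfigurationError(f"unknown model id {model!r}") from None


def registry_json() -> str:
    """The model registry serialized as JSON (for export / provenance)."""
    return json.dumps({mid: asdict(s) for mid, s in MODEL_REGISTRY.items()},
                      indent=1)


def validate_params(spec: ModelSpec, params: dict[str, float]) -> None:
    have, want = set(params), set(spec.params)
    if have != want:
        raise ParameterError(
            f"model {spec.model_id} expects parameters {sorted(want)}, "
            f"got {sorted(have)}")


# ---------------------------------------------------------------------------
# learning primitives

def prediction_error(r: float, v_csp: float) -> float:
    """δ = r − v, computed on reinforced CS+ trials only (models 1-9)."""
    return r - v_csp


def inertia_error(delta_history, km: int = KM) -> float:
    """δ_in(t) = Σ_{k=0..km} δ(t−k); terms before the first trial are 0.

    ``delta_history`` holds past errors in chronological order with the
    current trial's error last.
    """
    return float(sum(delta_history[-(km + 1):]))


def decayed_rate(alpha: float, t: int) -> float:
    """Bayesian learning-rate decay α(t) = α/√t (t = 1, 2, ...)."""
    return alpha / math.sqrt(t)


def habituation_factor(t: int, t0: int = T0, phi: float = 0.0) -> float:
    """Multiplicative habituation e^(−φ·[t−t0]⁺) on the emitted response."""
    return math.exp(-phi * max(t - t0, 0))


def ph_update(alpha_ph: float, delta: float, gamma: float) -> float:
    """Pearce-Hall associability update α' = γ|δ| + (1−γ)α."""
    return gamma * abs(delta) + (1.0 - gamma) * alpha_ph


def beta_update(alpha_b: float, beta_b: float, u: int
                ) -> tuple[float, float]:
    """Beta-count update: α' = α + u, β' = β − u + 1 (u = 1 iff UCS)."""
    return alpha_b + u, beta_b - u + 1.0


# ---------------------------------------------------------------------------
# latent state

@dataclass
class LatentState:
    """Latent model state at phase onset."""

    v: dict[str, float]
    alpha_ph: dict[str, float] = field(
        default_factory=lambda: {CSP: 1.0, CSM: 1.0})
    beta_counts: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {CSP: (1.0, 1.0), CSM: (1.0, 1.0)})
    delta_history: dict[str, list] = field(
        default_factory=lambda: {CSP: [], CSM: []})


def anchor_value(series: TrialSeries, phase: str) -> float:
    """The SCR value that initializes v for a phase's fit.

    Conditioning starts from the last valid pre-conditioning
    (habituation) SCR; extinction starts from the first valid
    extinction-phase SCR.
    """
    if phase == "conditioning":
        frame = series.phase_frame("pre")
        order = frame.iloc[::-1]
    elif phase == "extinction":
        order = series.phase_frame("extinction")
    else:
        raise ConfigurationError(f"no anchor defined for phase {phase!r}")
    for row in order.itertuples(index=False):
        if not row.missing and np.isfinite(row.scr):
            return float(row.scr)
    raise InputError(
        f"subject {series.subject_id}: no valid anchor trial for "
        f"{phase} initialization")


def init_state(spec: int | ModelSpec, series: TrialSeries,
               phase: str) -> LatentState:
    """Initialize the latent state for fitting/simulating one phase.

    Both cues start at the same associative strength v_i (anchored to the
    data); the Pearce-Hall associability starts at 1 and the uncertainty
    model's Beta counts at (1, 1) (a uniform prior, E[θ] = 0.5).
    """
    spec = get_spec(spec)
    if phase not in spec.phases:
        raise ConfigurationError(
            f"model {spec.model_id} is not applicable to the {phase} phase"
            " (without any UCS the uncertainty model would never update)"
            if phase == "extinction" else
            f"model {spec.model_id} not applicable to phase {phase!r}")
    v_i = anchor_value(series, phase)
    return LatentState(v={CSP: v_i, CSM: v_i})


# ---------------------------------------------------------------------------
# forward prediction

def predict_series(model: int | ModelSpec,
                   params: dict[str, float],
                   schedule: TaskSchedule,
                   phase: str,
                   ucs_values=None,
                   v_init: float | dict[str, float] = 0.0,
                   km: int = KM,
                   t0: int = T0,
                   habituation_on_latent: bool = False,
                   surprise: str = "literal") -> np.ndarray:
    """Predicted SCR for every CS trial of a phase, in presentation order.

    Parameters
    ----------
    ucs_values
        SCR amplitudes to the UCS on reinforced trials, in order; required
        for models 1-9 during conditioning (their reinforcement term),
        ignored for binary-outcome models 10-14.
    v_init
        Initial associative strength, either a scalar applied to both cues
        or a per-cue mapping (the generator continues extinction from the
        per-cue end-of-conditioning state; fits always anchor a scalar to
        the data).
    habituation_on_latent
        Sensitivity switch: if True the habituation factor also scales the
        latent value carried into later updates, instead of only the
        emitted prediction (the default).
    surprise
        'literal' uses h = −ln(α_B + β_B) exactly as specified for the
        uncertainty models; 'variance' uses −ln Var[θ] of the Beta belief
        as a documented alternative.
    """
    spec = get_spec(model)
    validate_params(spec, params)
    if phase not in spec.phases:
        raise ConfigurationError(
            f"model {spec.model_id} is not applicable to the {phase} phase")
    if surprise not in ("literal", "variance"):
        raise ConfigurationError(f"unknown surprise form {surprise!r}")

    trials = schedule.phase_trials(phase)
    if isinstance(v_init, dict):
        v = {CSP: float(v_init[CSP]), CSM: float(v_init[CSM])}
    else:
        v = {CSP: float(v_init), CSM: float(v_init)}

    if spec.readout == "uncertainty":
        return _predict_uncertainty(spec, params, trials, t0, surprise)
    if spec.binary_outcome:
        return _predict_hybrid_readout(spec, params, trials, v)
    return _predict_rw_family(spec, params, trials, phase, ucs_values, v,
                              km, t0, habituation_on_latent)


def final_values(model: int | ModelSpec, params: dict[str, float],
                 schedule: TaskSchedule, phase: str,
                 ucs_values=None,
                 v_init: float | dict[str, float] = 0.0
                 ) -> dict[str, float]:
    """Per-cue latent associative strength after a phase's last update.

    Used by the generator to continue extinction from the end of
    conditioning.  Habituation scales only the emitted prediction, so the
    latent trajectory equals that of the unhabituated sibling model.
    """
    spec = get_spec(model)
    validate_params(spec, params)
    trials = schedule.phase_trials(phase)
    v = (dict(v_init) if isinstance(v_init, dict)
         else {CSP: float(v_init), CSM: float(v_init)})
    if spec.readout == "uncertainty":
        raise ConfigurationError(
            "uncertainty models carry no per-cue value state")
    if spec.binary_outcome:
        _predict_hybrid_readout(spec, params, trials, v)
        return v
    _predict_rw_family(spec, params, trials, phase, ucs_values, v,
                       KM, T0, False)
    return v


def _predict_rw_family(spec, params, trials, phase, ucs_values, v,
                       km, t0, hab_on_latent) -> np.ndarray:
    p = params
    preds = np.empty(len(trials))
    hist = {CSP: [], CSM: []}
    aph = {CSP: 1.0, CSM: 1.0}
    n_updates = {CSP: 0, CSM: 0}
    ridx = 0
    if phase == "conditioning" and not spec.binary_outcome:
        n_reinf = sum(1 for tr in trials if tr.reinforced)
        if ucs_values is None or len(ucs_values) < n_reinf:
            raise InputError(
                "models 1-9 need one UCS SCR per reinforced trial")

    for i, tr in enumerate(trials):
        cs = tr.cs
        if spec.habituation:
            f = habituation_factor(tr.index, t0, p[f"phi_{_sfx(cs)}"])
            if hab_on_latent:
                v[cs] *= f
                pred = v[cs]
            else:
                pred = v[cs] * f
        else:
            pred = v[cs]
        preds[i] = pred

        if phase == "conditioning":
            # the error is computed only on reinforced CS+ trials and
            # drives both cues (CS- generalization)
            if cs == CSP and tr.reinforced:
                r = float(ucs_values[ridx])
                ridx += 1
                delta = prediction_error(r, v[CSP])
                hist[CSP].append(delta)
                n_updates[CSP] += 1
                n_updates[CSM] += 1
                d = inertia_error(hist[CSP], km) if spec.inertia else delta
                if spec.hybrid:
                    for c in (CSP, CSM):
                        s = _sfx(c)
                        v[c] += p[f"kappa_{s}"] * aph[c] * delta
                        aph[c] = ph_update(aph[c], delta, p[f"gamma_{s}"])
                else:
                    t = n_updates[CSP]
                    for c in (CSP, CSM):
                        a = p[f"alpha_{_sfx(c)}"]
                        rate = decayed_rate(a, t) if spec.decay else a
                        v[c] += rate * d
        else:  # extinction: no UCS, each cue extinguishes via its own error
            delta = prediction_error(0.0, v[cs])
            hist[cs].append(delta)
            n_updates[cs] += 1
            d = inertia_error(hist[cs], km) if spec.inertia else delta
            s = _sfx(cs)
            if spec.hybrid:
                v[cs] += p[f"kappa_{s}"] * aph[cs] * delta
                aph[cs] = ph_update(aph[cs], delta, p[f"gamma_{s}"])
            else:
                a = p[f"alpha_{s}"]
                rate = decayed_rate(a, n_updates[cs]) if spec.decay else a
                v[cs] += rate * d
    return preds


def _predict_hybrid_readout(spec, params, trials, v) -> np.ndarray:
    """Models 10-12: binary outcome, per-cue PH updates, linear read-out."""
    p = params
    preds = np.empty(len(trials))
    aph = {CSP: 1.0, CSM: 1.0}
    for i, tr in enumerate(trials):
        cs = tr.cs
        if spec.readout == "V":
            preds[i] = p["beta0"] + p["beta1"] * v[cs]
        elif spec.readout == "alpha":
            preds[i] = p["beta0"] + p["beta1"] * aph[cs]
        else:  # V+alpha
            preds[i] = (p["beta0"] + p["beta1"] * v[cs]
                        + p["beta2"] * aph[cs])
        b = 1.0 if tr.reinforced else 0.0
        delta = b - v[cs]
        s = _sfx(cs)
        v[cs] += p[f"kappa_{s}"] * aph[cs] * delta
        aph[cs] = ph_update(aph[cs], delta, p[f"gamma_{s}"])
    return preds


def _predict_uncertainty(spec, params, trials, t0, surprise) -> np.ndarray:
    """Models 13-14: Beta-Bernoulli counts per cue, z = h + E[θ] read-out."""
    p = params
    preds = np.empty(len(trials))
    counts = {CSP: (1.0, 1.0), CSM: (1.0, 1.0)}
    for i, tr in enumerate(trials):
        cs = tr.cs
        a_b, b_b = counts[cs]
        total = a_b + b_b
        if surprise == "literal":
            h = -math.log(total)
        else:
            var = a_b * b_b / (total * total * (total + 1.0))
            h = -math.log(var)
        if spec.habituation:
            h *= habituation_factor(tr.index, t0, p[f"phi_{_sfx(cs)}"])
        z = h + a_b / total
        preds[i] = p["beta0"] + p["beta1"] * z
        counts[cs] = beta_update(a_b, b_b, 1 if tr.reinforced else 0)
    return preds


def _sfx(cs: str) -> str:
    return "csp" if cs == CSP else "csm"
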