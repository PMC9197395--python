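import math

import numpy as np
import pytest

from threatlearn import (MODEL_REGISTRY, beta_update, build_task_schedule,
                         decayed_rate, get_spec, habituation_factor,
                         inertia_error, init_state, ph_update,
                         prediction_error, predict_series)
from threatlearn.exceptions import ConfigurationError, ParameterError
from threatlearn.models import CSP, CSM

from _oracles import rw_reference


# ---------------------------------------------------------------------------
# learning primitives: closed forms

@pytest.mark.parametrize("r, v, expected", [(1.0, 0.0, 1.0),
                                            (0.7, 0.7, 0.0),
                                            (0.8, 0.3, 0.5)])
def test_prediction_error(r, v, expected):
    assert prediction_error(r, v) == pytest.approx(expected)


@pytest.mark.parametrize("history, km, expected", [
    ([1.0], 2, 1.0),                # partial window at phase start
    ([0.2, 0.3, 0.5], 2, 1.0),      # full 3-term window
    ([0.2, 0.3, 0.5], 0, 0.5),      # km=0 reduces to the current error
    ([0.1, 0.2, 0.3, 0.5], 2, 1.0)  # oldest term falls out of the window
])
def test_inertia_error(history, km, expected):
    assert inertia_error(history, km) == pytest.approx(expected)


@pytest.mark.parametrize("alpha, t, expected", [
    (0.6, 1, 0.6), (0.6, 4, 0.3), (0.0, 9, 0.0)])
def test_decayed_rate(alpha, t, expected):
    assert decayed_rate(alpha, t) == pytest.approx(expected)


@pytest.mark.parametrize("t, phi, expected", [
    (1, 0.7, 1.0), (2, 0.7, 1.0),        # rectified at t <= t0
    (5, 0.0, 1.0),                       # habituation off
    (4, 0.5, math.exp(-1.0))])           # phi=0.5, t=t0+2
def test_habituation_factor(t, phi, expected):
    assert habituation_factor(t, t0=2, phi=phi) == pytest.approx(expected)


@pytest.mark.parametrize("alpha, delta, gamma, expected", [
    (0.8, 0.5, 0.0, 0.8), (0.8, -0.4, 1.0, 0.4),
    (1.0, -0.5, 0.5, 0.75)])
def test_ph_update(alpha, delta, gamma, expected):
    assert ph_update(alpha, delta, gamma) == pytest.approx(expected)


def test_beta_update_and_conservation():
    assert beta_update(1.0, 1.0, 1) == (2.0, 1.0)
    assert beta_update(1.0, 1.0, 0) == (1.0, 2.0)
    a, b = 1.0, 1.0
    rng = np.random.default_rng(0)
    for i in range(1, 21):
        a, b = beta_update(a, b, int(rng.integers(0, 2)))
        assert a + b == pytest.approx(2.0 + i)  # one count added per trial


# ---------------------------------------------------------------------------
# initialization

def test_init_state_anchors(schedule_a, make_series_fn):
    pre = [0.1, 0.2, 0.3, 0.15, 0.25, 0.35, 0.3, 0.4]
    series = make_series_fn(schedule_a, {"pre": pre})
    st = init_state(1, series, "conditioning")
    assert st.v[CSP] == st.v[CSM] == pytest.approx(0.4)
    assert st.alpha_ph == {CSP: 1.0, CSM: 1.0}
    assert st.beta_counts[CSP] == (1.0, 1.0)  # uniform prior, E[theta]=0.5

    ext = [0.7] + [0.5] * 15
    series2 = make_series_fn(schedule_a, {"extinction": ext})
    st2 = init_state(3, series2, "extinction")
    assert st2.v[CSP] == pytest.approx(0.7)


def test_uncertainty_model_rejected_for_extinction(schedule_a,
                                                   make_series_fn):
    series = make_series_fn(schedule_a)
    for mid in (13, 14):
        with pytest.raises(ConfigurationError):
            init_state(mid, series, "extinction")
        with pytest.raises(ConfigurationError):
            predict_series(mid, {n: 0.5 for n in get_spec(mid).params},
                           schedule_a, "extinction")


def test_bad_model_and_params_rejected(schedule_a):
    with pytest.raises(ConfigurationError):
        get_spec(99)
    with pytest.raises(ParameterError):
        predict_series(1, {"alpha_csp": 0.5}, schedule_a, "conditioning",
                       ucs_values=np.ones(8))


# ---------------------------------------------------------------------------
# forward predictions

def csp_values(schedule, phase, pred):
    return [p for p, t in zip(pred, schedule.phase_trials(phase))
            if t.cs == "CS+"]


def test_rw_geometric_approach(schedule_a):
    """Base RW with constant r=1, alpha=0.5, v0=0: CS+ predictions climb
    0, 0.5, 0.75, ... on successive reinforced trials."""
    pred = predict_series(1, {"alpha_csp": 0.5, "alpha_csm": 0.0},
                          schedule_a, "conditioning",
                          ucs_values=np.ones(8), v_init=0.0)
    csp = csp_values(schedule_a, "conditioning", pred)
    reinforced = [t.reinforced for t in schedule_a.phase_trials("conditioning")
                  if t.cs == "CS+"]
    v, expected = 0.0, []
    for r in reinforced:
        expected.append(v)
        if r:
            v = v + 0.5 * (1.0 - v)
    assert csp == pytest.approx(expected, abs=1e-12)


def test_generalization_off_keeps_csm_constant(schedule_a):
    pred = predict_series(1, {"alpha_csp": 0.5, "alpha_csm": 0.0},
                          schedule_a, "conditioning",
                          ucs_values=np.ones(8), v_init=0.2)
    csm = [p for p, t in zip(pred, schedule_a.phase_trials("conditioning"))
           if t.cs == "CS-"]
    assert csm == pytest.approx([0.2] * 10)


def test_zero_learning_rates_flat(schedule_a):
    pred = predict_series(1, {"alpha_csp": 0.0, "alpha_csm": 0.0},
                          schedule_a, "conditioning",
                          ucs_values=np.ones(8), v_init=0.33)
    assert pred == pytest.approx([0.33] * 20)


@pytest.mark.parametrize("model_id", [1, 3])
def test_monotone_convergence_to_constant_reinforcer(schedule_a, model_id):
    """With constant r=R and 0<alpha<=1, CS+ predictions approach R
    monotonically on reinforced trials (no habituation)."""
    R = 0.9
    rng = np.random.default_rng(4)
    for _ in range(5):
        a = float(rng.uniform(0.05, 1.0))
        pred = predict_series(model_id,
                              {"alpha_csp": a, "alpha_csm": 0.1},
                              schedule_a, "conditioning",
                              ucs_values=np.full(8, R), v_init=0.0)
        csp = csp_values(schedule_a, "conditioning", pred)
        gaps = [R - p for p in csp]
        assert all(g >= -1e-12 for g in gaps)
        assert all(g2 <= g1 + 1e-12 for g1, g2 in zip(gaps, gaps[1:]))


@pytest.mark.parametrize("habituated, base", [(7, 3), (8, 5), (4, 1),
                                              (6, 2)])
def test_habituation_nesting(schedule_a, habituated, base, make_series_fn):
    """phi=0 reduces each habituation variant to its unhabituated sibling."""
    rng = np.random.default_rng(7)
    r = rng.uniform(0.2, 1.2, size=8)
    params_h = {"alpha_csp": 0.45, "alpha_csm": 0.3,
                "phi_csp": 0.0, "phi_csm": 0.0}
    params_b = {"alpha_csp": 0.45, "alpha_csm": 0.3}
    for phase, kw in (("conditioning", {"ucs_values": r}),
                      ("extinction", {})):
        ph = predict_series(habituated, params_h, schedule_a, phase,
                            v_init=0.3, **kw)
        pb = predict_series(base, params_b, schedule_a, phase,
                            v_init=0.3, **kw)
        np.testing.assert_array_equal(ph, pb)


def test_inertia_nesting_km0(schedule_a):
    """Inertia with a zero-length window is the base RW model."""
    r = np.linspace(1.2, 0.4, 8)
    params = {"alpha_csp": 0.4, "alpha_csm": 0.25}
    p2 = predict_series(2, params, schedule_a, "conditioning",
                        ucs_values=r, v_init=0.1, km=0)
    p1 = predict_series(1, params, schedule_a, "conditioning",
                        ucs_values=r, v_init=0.1)
    np.testing.assert_array_equal(p2, p1)


def test_uncertainty_habituation_nesting(schedule_a):
    params14 = {"beta0": 0.1, "beta1": 0.5, "phi_csp": 0.0, "phi_csm": 0.0}
    params13 = {"beta0": 0.1, "beta1": 0.5}
    p14 = predict_series(14, params14, schedule_a, "conditioning")
    p13 = predict_series(13, params13, schedule_a, "conditioning")
    np.testing.assert_array_equal(p14, p13)


def test_uncertainty_first_trial_value(schedule_a):
    """At Beta(1,1) the read-out is beta0 + beta1*(-ln 2 + 0.5) on each
    cue's first trial."""
    pred = predict_series(13, {"beta0": 0.0, "beta1": 1.0},
                          schedule_a, "conditioning")
    cond = schedule_a.phase_trials("conditioning")
    first = {}
    for p, t in zip(pred, cond):
        first.setdefault(t.cs, p)
    for cs in ("CS+", "CS-"):
        assert first[cs] == pytest.approx(-math.log(2.0) + 0.5)


@pytest.mark.parametrize("model_id", sorted(rw_reference.__globals__
                                            ["RW_FEATURES"]))
@pytest.mark.parametrize("phase", ["conditioning", "extinction"])
def test_forward_model_matches_brute_force(model_id, phase):
    """Models 1-8 agree with an independent literal re-iteration of the
    update equations on random inputs, to 1e-10."""
    rng = np.random.default_rng(model_id * 100 + (phase == "extinction"))
    spec = get_spec(model_id)
    for rep in range(5):
        schedule = build_task_schedule("A" if rep % 2 else "B",
                                       int(rng.integers(0, 1000)))
        params = {"alpha_csp": float(rng.uniform(0, 1)),
                  "alpha_csm": float(rng.uniform(0, 1))}
        if spec.habituation:
            params["phi_csp"] = float(rng.uniform(0, 1))
            params["phi_csm"] = float(rng.uniform(0, 1))
        r = rng.uniform(0.0, 1.5, size=8)
        v0 = float(rng.uniform(0, 0.5))
        pred = predict_series(model_id, params, schedule, phase,
                              ucs_values=r, v_init=v0)
        tuples = [(t.cs, t.index, t.reinforced)
                  for t in schedule.phase_trials(phase)]
        ref = rw_reference(model_id, params, tuples, phase,
                           r_values=list(r), v0=v0)
        np.testing.assert_allclose(pred, ref, atol=1e-10, rtol=0)


def test_forward_model_deterministic(schedule_a):
    params = {"gamma_csp": 0.4, "gamma_csm": 0.6, "kappa_csp": 0.5,
              "kappa_csm": 0.3}
    a = predict_series(9, params, schedule_a, "conditioning",
                       ucs_values=np.linspace(1, 0.5, 8), v_init=0.2)
    b = predict_series(9, params, schedule_a, "conditioning",
                       ucs_values=np.linspace(1, 0.5, 8), v_init=0.2)
    np.testing.assert_array_equal(a, b)


def test_readout_models_emit_regression_of_state(schedule_a):
    """Model 10's first emitted value is beta0 + beta1*v_init; model 11's
    is beta0 + beta1 (associability starts at 1)."""
    base = {"gamma_csp": 0.5, "gamma_csm": 0.5, "kappa_csp": 0.4,
            "kappa_csm": 0.4, "beta0": 0.2, "beta1": 0.7}
    p10 = predict_series(10, base, schedule_a, "conditioning", v_init=0.3)
    assert p10[0] == pytest.approx(0.2 + 0.7 * 0.3)
    p11 = predict_series(11, base, schedule_a, "conditioning", v_init=0.3)
    assert p11[0] == pytest.approx(0.2 + 0.7 * 1.0)
    p12 = predict_series(12, {**base, "beta2": 0.1}, schedule_a,
                         "conditioning", v_init=0.3)
    assert p12[0] == pytest.approx(0.2 + 0.7 * 0.3 + 0.1 * 1.0)


def test_registry_parameter_counts():
    """Free-parameter counts drive the BIC complexity term."""
    expected = {1: 2, 2: 2, 3: 2, 4: 4, 5: 2, 6: 4, 7: 4, 8: 4, 9: 4,
                10: 6, 11: 6, 12: 7, 13: 2, 14: 4}
    assert {m: s.k for m, s in MODEL_REGISTRY.items()} == expected
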