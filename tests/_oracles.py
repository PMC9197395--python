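"""Independent brute-force re-iteration of the RW-family update equations.

Deliberately written as a literal, flat transcription of the update rules
(no shared code with the package) so it can serve as an oracle for the
forward model.
"""

import math

# model id -> (inertia, bayesian decay, habituation)
RW_FEATURES = {
    1: (False, False, False),
    2: (True, False, False),
    3: (False, True, False),
    4: (False, False, True),
    5: (True, True, False),
    6: (True, False, True),
    7: (False, True, True),
    8: (True, True, True),
}


def rw_reference(model_id, params, trial_tuples, phase, r_values=None,
                 v0=0.0, km=2, t0=2):
    """Predicted SCR per trial for models 1-8, by direct iteration.

    ``trial_tuples`` is a list of (cs, within_phase_index, reinforced)
    with cs in {'CS+', 'CS-'}.
    """
    inertia, decay, habituation = RW_FEATURES[model_id]
    a = {"CS+": params["alpha_csp"], "CS-": params["alpha_csm"]}
    phi = {"CS+": params.get("phi_csp", 0.0),
           "CS-": params.get("phi_csm", 0.0)}
    v = {"CS+": float(v0), "CS-": float(v0)}
    out = []

    if phase == "conditioning":
        deltas = []
        n_up = 0
        ridx = 0
        for cs, idx, reinforced in trial_tuples:
            pred = v[cs]
            if habituation:
                pred = pred * math.exp(-phi[cs] * max(idx - t0, 0))
            out.append(pred)
            if cs == "CS+" and reinforced:
                delta = r_values[ridx] - v["CS+"]
                ridx += 1
                deltas.append(delta)
                n_up += 1
                if inertia:
                    d = 0.0
                    for k in range(0, km + 1):
                        j = len(deltas) - 1 - k
                        if j >= 0:
                            d += deltas[j]
                else:
                    d = delta
                for c in ("CS+", "CS-"):
                    rate = a[c] / math.sqrt(n_up) if decay else a[c]
                    v[c] = v[c] + rate * d
    else:  # extinction: no UCS; each cue extinguishes via its own error
        deltas = {"CS+": [], "CS-": []}
        n_up = {"CS+": 0, "CS-": 0}
        for cs, idx, reinforced in trial_tuples:
            pred = v[cs]
            if habituation:
                pred = pred * math.exp(-phi[cs] * max(idx - t0, 0))
            out.append(pred)
            delta = 0.0 - v[cs]
            deltas[cs].append(delta)
            n_up[cs] += 1
            if inertia:
                d = 0.0
                for k in range(0, km + 1):
                    j = len(deltas[cs]) - 1 - k
                    if j >= 0:
                        d += deltas[cs][j]
            else:
                d = delta
            rate = a[cs] / math.sqrt(n_up[cs]) if decay else a[cs]
            v[cs] = v[cs] + rate * d
    return out
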