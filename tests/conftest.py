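import numpy as np
import pandas as pd
import pytest

from threatlearn import TrialSeries, build_task_schedule


@pytest.fixture(scope="session")
def schedule_a():
    return build_task_schedule("A", 1)


@pytest.fixture(scope="session")
def schedule_b():
    return build_task_schedule("B", 1)


def make_series(schedule, scr_by_phase=None, default=0.5,
                ucs_value=1.0, subject_id="t"):
    """Build a TrialSeries over a schedule with given per-phase SCR arrays.

    ``scr_by_phase`` maps phase name -> iterable of SCR values in
    presentation order (NaN for missing); phases not listed get
    ``default`` on every trial.
    """
    scr_by_phase = scr_by_phase or {}
    rows = []
    cursors = {p: 0 for p in ("pre", "conditioning", "extinction")}
    for tr in schedule:
        vals = scr_by_phase.get(tr.phase)
        if vals is None:
            scr = default
        else:
            scr = float(vals[cursors[tr.phase]])
        cursors[tr.phase] += 1
        ucs = ucs_value if tr.reinforced else np.nan
        rows.append([tr.phase, tr.cs, tr.index, tr.reinforced, scr, ucs,
                     not np.isfinite(scr)])
    df = pd.DataFrame(rows, columns=["phase", "cs", "trial", "reinforced",
                                     "scr", "ucs_scr", "missing"])
    return TrialSeries(subject_id=subject_id, trials=df,
                       order_id=schedule.order_id)


@pytest.fixture
def make_series_fn():
    return make_series
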