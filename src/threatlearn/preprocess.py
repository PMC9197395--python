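"""Trial-level SCR scoring, cleaning, interpolation and exclusion rules.

The canonical pipeline input is the square-root-transformed base-to-peak
SCR amplitude per trial; :func:`score_trial_amplitude` derives it from a
raw conductance segment when waveforms are available.  Cleaning flags
within-subject outliers as missing (against the subject's pooled trial
distribution — see :func:`_flag_outliers_to_fixpoint` for why not per
cell), then, per CS type within the conditioning and extinction phases
separately, linearly interpolates runs of up to three consecutive
missing values, linearly extrapolates trailing missing values during
conditioning and leading missing values during extinction, and excludes
subjects missing more than 50% of a modeled phase's trial values
(counted before interpolation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError
from .series import TrialSeries

#: maximum run length of consecutive missing values that is interpolated
MAX_INTERP_RUN = 3

#: fraction of missing trial values (per modeled phase) that triggers exclusion
EXCLUSION_FRACTION = 0.5

MODELED_PHASES = ("conditioning", "extinction")


@dataclass
class CleaningReport:
    subject_id: str
    n_outliers_within: int = 0
    n_interpolated: int = 0
    n_extrapolated: int = 0
    missing_fraction: dict[str, float] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str | None = None


def score_trial_amplitude(waveform, sample_rate_hz: float,
                          onset_index: int,
                          window: tuple[float, float] = (1.0, 5.0)) -> float:
    """Square-root base-to-peak SCR amplitude within a post-onset window.

    ``base`` is the conductance at the window start (``onset + window[0]``
    seconds) and ``peak`` the maximum within the window; negative
    deflections score 0.
    """
    waveform = np.asarray(waveform, dtype=float)
    lo = onset_index + int(round(window[0] * sample_rate_hz))
    hi = onset_index + int(round(window[1] * sample_rate_hz))
    if lo < 0 or hi >= len(waveform) or hi <= lo:
        raise InputError("waveform segment does not cover the scoring window")
    seg = waveform[lo:hi + 1]
    return math.sqrt(max(float(seg.max() - seg[0]), 0.0))


def _flag_outliers_to_fixpoint(values: np.ndarray, miss: np.ndarray,
                               outlier_sd: float) -> int:
    """Flag within-subject outliers as missing, iterating to a fixed point.

    The |z| > outlier_sd rule is applied to the subject's *pooled* trial
    distribution rather than within each 8-10 trial (CS, phase) cell: an
    include-self z in so small a cell can never exceed ~2.9 (the rule
    would be vacuous), while a leave-one-out cell rule chases the genuine
    monotone learning/extinction trend and flags real data.  Pooling
    keeps the rule sensitive to recording artifacts (which dwarf any
    trial) but blind to ordinary learning dynamics.  One value — the most
    deviant — is flagged per pass; iteration to a fixed point makes the
    whole cleaning pass idempotent.  Zero-variance distributions flag
    nothing.
    """
    if not math.isfinite(outlier_sd):
        return 0
    n_flagged = 0
    while True:
        valid = ~miss & np.isfinite(values)
        m = int(valid.sum())
        if m < 4:
            return n_flagged
        x = values[valid]
        sd = x.std()
        if sd == 0 or not np.isfinite(sd):
            return n_flagged
        z = np.abs(x - x.mean()) / sd
        if z.max() <= outlier_sd:
            return n_flagged
        idx = np.flatnonzero(valid)[int(np.argmax(z))]
        miss[idx] = True
        n_flagged += 1


def _interpolate_runs(values: np.ndarray, miss: np.ndarray,
                      max_run: int = MAX_INTERP_RUN) -> int:
    """Linearly interpolate interior missing runs of length <= max_run."""
    n = len(values)
    filled = 0
    i = 0
    while i < n:
        if not miss[i]:
            i += 1
            continue
        j = i
        while j < n and miss[j]:
            j += 1
        run = j - i
        interior = i > 0 and j < n and not miss[i - 1] and not miss[j]
        if interior and run <= max_run:
            left, right = values[i - 1], values[j]
            for k in range(run):
                values[i + k] = left + (right - left) * (k + 1) / (run + 1)
            filled += run
        i = j
    return filled


def _extrapolate_edge(values: np.ndarray, miss: np.ndarray,
                      trailing: bool) -> int:
    """Extrapolate a trailing (or leading) missing run from the line
    through the last (first) two interpolation-filled or valid points;
    with a single anchor the value is carried flat.  Results are clamped
    at 0 (amplitudes are non-negative)."""
    n = len(values)
    anchors = np.flatnonzero(np.isfinite(values))
    if len(anchors) == 0:
        return 0
    filled = 0
    if trailing:
        last = anchors[-1]
        if last == n - 1:
            return 0
        if len(anchors) >= 2:
            a, b = anchors[-2], anchors[-1]
            slope = (values[b] - values[a]) / (b - a)
        else:
            slope = 0.0
        for i in range(last + 1, n):
            if not np.isfinite(values[i]):
                values[i] = max(values[last] + slope * (i - last), 0.0)
                filled += 1
    else:
        first = anchors[0]
        if first == 0:
            return 0
        if len(anchors) >= 2:
            a, b = anchors[0], anchors[1]
            slope = (values[b] - values[a]) / (b - a)
        else:
            slope = 0.0
        for i in range(first - 1, -1, -1):
            if not np.isfinite(values[i]):
                values[i] = max(values[first] + slope * (i - first), 0.0)
                filled += 1
    return filled


def clean_series(series: TrialSeries, outlier_sd: float = 3.0
                 ) -> tuple[TrialSeries, CleaningReport]:
    """Apply outlier flagging, interpolation, extrapolation and exclusion.

    Returns a cleaned copy plus a report.  The exclusion decision uses
    missingness *before* interpolation (after outlier flagging): a subject
    missing more than half of a modeled phase's trial values is excluded.
    Interpolated/extrapolated positions remain marked in ``missing`` so the
    pass is idempotent and downstream code can tell filled from observed
    values.
    """
    out = series.copy()
    rep = CleaningReport(subject_id=series.subject_id)
    df = out.trials
    values = df["scr"].to_numpy(dtype=float)
    miss = df["missing"].to_numpy(dtype=bool) | ~np.isfinite(values)

    rep.n_outliers_within = _flag_outliers_to_fixpoint(values, miss,
                                                       outlier_sd)

    # exclusion is decided on pre-interpolation missingness, per phase
    for phase in MODELED_PHASES:
        sel = (df["phase"] == phase).to_numpy()
        if sel.sum() == 0:
            continue
        frac = float(miss[sel].mean())
        rep.missing_fraction[phase] = frac
        if frac > EXCLUSION_FRACTION and not rep.excluded:
            rep.excluded = True
            rep.exclusion_reason = (
                f">{EXCLUSION_FRACTION:.0%} missing trial values in "
                f"{phase} ({frac:.0%})")

    values[miss] = np.nan
    for phase in df["phase"].unique():
        for cs in df.loc[df["phase"] == phase, "cs"].unique():
            sel = ((df["phase"] == phase) & (df["cs"] == cs)).to_numpy()
            cell_vals = values[sel]
            cell_miss = miss[sel]
            rep.n_interpolated += _interpolate_runs(cell_vals, cell_miss)
            if phase == "conditioning":
                rep.n_extrapolated += _extrapolate_edge(cell_vals, cell_miss,
                                                        trailing=True)
            elif phase == "extinction":
                rep.n_extrapolated += _extrapolate_edge(cell_vals, cell_miss,
                                                        trailing=False)
            values[sel] = cell_vals

    if rep.excluded and not np.isfinite(values).any():
        rep.exclusion_reason = "all trial values missing"

    df["scr"] = values
    df["missing"] = miss
    return out, rep


def flag_group_outliers(cs_means: pd.DataFrame, outlier_sd: float = 3.0
                        ) -> pd.Series:
    """Flag subjects whose per-CS mean SCR is a group-level outlier.

    ``cs_means`` has one row per subject and one column per CS type
    (e.g. ``mean_csp``, ``mean_csm``).  A subject is flagged when any
    column's value lies beyond ``outlier_sd`` group standard deviations of
    that column's mean; zero-variance columns flag nobody.
    """
    if len(cs_means) < 3:
        raise InputError("group-outlier detection needs >= 3 subjects")
    flagged = pd.Series(False, index=cs_means.index)
    if not math.isfinite(outlier_sd):
        return flagged
    for col in cs_means.columns:
        x = cs_means[col].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0 or not np.isfinite(sd):
            continue
        flagged |= np.abs(x - x.mean()) > outlier_sd * sd
    return flagged


def subject_cs_means(series: TrialSeries) -> dict[str, float]:
    """Overall CS+ and CS- mean SCR for one subject (modeled phases)."""
    df = series.trials
    sel = df["phase"].isin(MODELED_PHASES)
    out = {}
    for cs, key in (("CS+", "mean_csp"), ("CS-", "mean_csm")):
        vals = df.loc[sel & (df["cs"] == cs), "scr"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        out[key] = float(vals.mean()) if len(vals) else math.nan
    return out
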