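"""Per-subject least-squares model fitting, BIC, and model comparison.

Each model's free parameters are estimated per subject by minimizing the
summed squared error between predicted and observed SCR over the fitted
phase's CS+ and CS- trials, using a derivative-free simplex search
restarted from a grid of learning-rate initial values between 0.1 and 0.8.
Conditioning fits are unconstrained; extinction fits constrain learning
rates to [-1, +1] (enforced by clipping inside the objective, so estimates
pinned at a bound are detectable).

Model fit is scored with a Gaussian-residual Bayesian Information
Criterion,

    BIC = -k ln(n) + n ln(variance),   variance = RSS / n,

whose complexity term carries the opposite sign of the conventional
+k ln(n) penalty (it *rewards* parameters; see the methods note for why
this form is the default); ``convention="standard"`` switches to the
conventional form.  Population-level comparison runs a
repeated-measures ANOVA on BIC (model fixed, subject random) plus
Bonferroni-corrected pairwise t-tests, preferring the simpler model when
its difference from the best-scoring one is non-significant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConfigurationError, InputError
from .models import ModelSpec, anchor_value, get_spec, predict_series
from .series import TrialSeries
from .task import TaskSchedule, schedule_from_frame

#: initial learning-rate values for the multi-start search
LEARNING_RATE_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)

#: default initial values for non-grid parameters
DEFAULT_INITS = {"phi_csp": 0.1, "phi_csm": 0.1,
                 "gamma_csp": 0.5, "gamma_csm": 0.5,
                 "kappa_csp": 0.5, "kappa_csm": 0.5,
                 "beta0": 0.0, "beta1": 1.0, "beta2": 0.0}

#: extinction learning-rate bounds
EXTINCTION_BOUNDS = (-1.0, 1.0)

#: parameters treated as learning rates for bounding purposes
LEARNING_RATE_PARAMS = ("alpha_csp", "alpha_csm", "kappa_csp", "kappa_csm")

_BOUND_TOL = 1e-6
_VARIANCE_FLOOR = 1e-12


@dataclass
class FitResult:
    model_id: int
    phase: str
    params: dict[str, float]
    rss: float
    n: int
    k: int
    variance: float
    bic: float
    predicted: np.ndarray
    converged: bool
    pinned_at_bound: dict[str, bool] = field(default_factory=dict)
    n_restarts: int = 0
    variance_floored: bool = False


def compute_bic(k: int, n: int, variance: float,
                convention: str = "negative-penalty") -> float:
    """Gaussian-residual BIC.

    ``negative-penalty`` evaluates -k ln(n) + n ln(variance) exactly; the
    ``standard`` convention uses +k ln(n).  A non-positive variance is
    floored at a machine-epsilon-scaled value (the caller flags this).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    variance = max(variance, _VARIANCE_FLOOR)
    sign = -1.0 if convention == "negative-penalty" else 1.0
    if convention not in ("negative-penalty", "standard"):
        raise ConfigurationError(f"unknown BIC convention {convention!r}")
    return sign * k * math.log(n) + n * math.log(variance)


@dataclass
class FitOptions:
    max_evals: int = 2000
    tol: float = 1e-6
    lr_grid: tuple[float, ...] = LEARNING_RATE_GRID
    bic_convention: str = "negative-penalty"
    km: int = 2
    t0: int = 2


def _clip_extinction(params: dict[str, float]) -> dict[str, float]:
    lo, hi = EXTINCTION_BOUNDS
    return {k: (min(max(v, lo), hi) if k in LEARNING_RATE_PARAMS else v)
            for k, v in params.items()}


def fit_subject(model: int | ModelSpec, series: TrialSeries,
                schedule: TaskSchedule | None = None, phase: str = "conditioning",
                options: FitOptions | None = None) -> FitResult:
    """Fit one model to one subject's cleaned series for one phase.

    The observed vector covers the phase's CS trials in presentation
    order; trials still missing after cleaning are dropped from the
    objective (n reflects the points actually fit).  For models 1-9 the
    reinforcement term is the subject's observed UCS SCR sequence.  When
    ``schedule`` is omitted it is reconstructed from the series' own trial
    table, guaranteeing the fit aligns with the sequence the subject saw.
    """
    spec = get_spec(model)
    options = options or FitOptions()
    if schedule is None:
        schedule = schedule_from_frame(series.trials, series.order_id)
    if phase not in spec.phases:
        raise ConfigurationError(
            f"model {spec.model_id} is not applicable to the {phase} phase")

    observed = series.phase_values(phase)
    valid = np.isfinite(observed)
    if valid.sum() < spec.k + 1:
        raise InputError(
            f"subject {series.subject_id}: too few valid {phase} trials "
            f"({int(valid.sum())}) to fit model {spec.model_id}")
    ucs = series.ucs_values() if not spec.binary_outcome else None
    if ucs is not None:
        ucs = np.nan_to_num(ucs, nan=0.0)
    v_init = anchor_value(series, phase)
    constrain = phase == "extinction"
    names = spec.params

    def objective(x: np.ndarray) -> float:
        params = dict(zip(names, x.tolist()))
        if constrain:
            params = _clip_extinction(params)
        try:
            pred = predict_series(spec, params, schedule, phase,
                                  ucs_values=ucs, v_init=v_init,
                                  km=options.km, t0=options.t0)
        except (OverflowError, FloatingPointError):
            return float("inf")
        resid = pred[valid] - observed[valid]
        sse = float(resid @ resid)
        return sse if math.isfinite(sse) else float("inf")

    best = None
    converged = False
    for g in options.lr_grid:
        x0 = np.array([g if name in spec.grid_params
                       else DEFAULT_INITS[name] for name in names])
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxfev": options.max_evals,
                     "xatol": options.tol * 1e-3,
                     "fatol": options.tol * 1e-6})
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    params = dict(zip(names, best.x.tolist()))
    pinned = {name: False for name in names}
    if constrain:
        lo, hi = EXTINCTION_BOUNDS
        for name in names:
            if name in LEARNING_RATE_PARAMS:
                pinned[name] = (params[name] <= lo + _BOUND_TOL
                                or params[name] >= hi - _BOUND_TOL)
        params = _clip_extinction(params)

    pred = predict_series(spec, params, schedule, phase, ucs_values=ucs,
                          v_init=v_init, km=options.km, t0=options.t0)
    resid = pred[valid] - observed[valid]
    rss = float(resid @ resid)
    n = int(valid.sum())
    variance = rss / n
    floored = variance <= _VARIANCE_FLOOR
    bic = compute_bic(spec.k, n, variance, options.bic_convention)
    return FitResult(model_id=spec.model_id, phase=phase, params=params,
                     rss=rss, n=n, k=spec.k, variance=variance, bic=bic,
                     predicted=pred, converged=converged,
                     pinned_at_bound=pinned,
                     n_restarts=len(options.lr_grid),
                     variance_floored=floored)


# ---------------------------------------------------------------------------
# population-level model comparison

@dataclass
class ModelComparisonReport:
    models: list[int]
    mean_bic: dict[int, float]
    se_bic: dict[int, float]
    best_model_per_subject: dict[str, int]
    best_fraction: dict[int, float]
    anova_F: float
    anova_p: float
    anova_df: tuple[int, int]
    pairwise: pd.DataFrame          # model_a, model_b, t, p, p_bonferroni
    winning_model_id: int


def compare_models(fits: dict[str, dict[int, FitResult]],
                   model_subset: list[int] | None = None,
                   alpha: float = 0.05) -> ModelComparisonReport:
    """Compare models across subjects on their BIC distributions.

    ``fits`` maps subject id -> model id -> FitResult; every subject must
    have a result for every compared model.  The winner is the model with
    the best (lowest) mean BIC, except that a simpler model whose pairwise
    difference from it is non-significant (Bonferroni-corrected) is
    preferred.
    """
    subjects = sorted(fits)
    models = sorted(model_subset or
                    set.intersection(*(set(f) for f in fits.values())))
    if len(models) < 2 or len(subjects) < 2:
        raise InputError("need >= 2 models and >= 2 subjects to compare")
    bic = pd.DataFrame(
        {m: [fits[s][m].bic for s in subjects] for m in models},
        index=subjects)

    best_per_subject = bic.idxmin(axis=1)
    frac = (best_per_subject.value_counts() / len(subjects))
    best_fraction = {m: float(frac.get(m, 0.0)) for m in models}

    # repeated-measures ANOVA: model fixed, subject random
    grand = bic.to_numpy().mean()
    ss_model = len(subjects) * ((bic.mean(axis=0) - grand) ** 2).sum()
    ss_subj = len(models) * ((bic.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((bic.to_numpy() - grand) ** 2).sum()
    ss_err = ss_tot - ss_model - ss_subj
    df_model = len(models) - 1
    df_err = (len(models) - 1) * (len(subjects) - 1)
    ms_model = ss_model / df_model
    ms_err = ss_err / df_err
    F = float(ms_model / ms_err) if ms_err > 0 else float("inf")
    p = float(stats.f.sf(F, df_model, df_err)) if math.isfinite(F) else 0.0

    rows = []
    n_tests = len(models) * (len(models) - 1) // 2
    for a, b in itertools.combinations(models, 2):
        diff = bic[a] - bic[b]
        if float(diff.abs().max()) == 0.0:
            t, pt = 0.0, 1.0
        else:
            t, pt = stats.ttest_rel(bic[a], bic[b])
        rows.append({"model_a": a, "model_b": b, "t": float(t),
                     "p": float(pt),
                     "p_bonferroni": min(float(pt) * n_tests, 1.0)})
    pairwise = pd.DataFrame(rows)

    top = int(bic.mean(axis=0).idxmin())
    tied = {top}
    for r in rows:
        other = None
        if r["model_a"] == top:
            other = r["model_b"]
        elif r["model_b"] == top:
            other = r["model_a"]
        if other is not None and r["p_bonferroni"] > alpha:
            tied.add(int(other))
    winner = min(tied, key=lambda m: (get_spec(m).k,
                                      float(bic.mean(axis=0)[m])))

    return ModelComparisonReport(
        models=models,
        mean_bic={m: float(bic[m].mean()) for m in models},
        se_bic={m: float(bic[m].std(ddof=1) / math.sqrt(len(subjects)))
                for m in models},
        best_model_per_subject={s: int(best_per_subject[s])
                                for s in subjects},
        best_fraction=best_fraction,
        anova_F=F, anova_p=p, anova_df=(df_model, df_err),
        pairwise=pairwise, winning_model_id=int(winner))


def fits_to_frame(fits: dict[str, dict[int, FitResult]]) -> pd.DataFrame:
    """Tidy per-subject, per-model fit table (fits.csv layout)."""
    rows = []
    for sid, per_model in fits.items():
        for mid, fr in per_model.items():
            row = {"subject_id": sid, "model_id": mid, "phase": fr.phase,
                   "rss": fr.rss, "n": fr.n, "k": fr.k, "bic": fr.bic,
                   "converged": fr.converged}
            row.update(fr.params)
            row.update({f"pinned_{k}": v
                        for k, v in fr.pinned_at_bound.items() if v})
            rows.append(row)
    return pd.DataFrame(rows)
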