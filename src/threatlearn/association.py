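"""Associations among learning parameters, anxiety severity, age and
structure-level brain anatomy.

Anxiety severity is harmonized across age groups by z-scoring the
age-appropriate questionnaire within its own sample (SCARED in youth,
averaging child and parent report; STAI-trait in adults).  Each fitted
learning parameter is regressed on anxiety, age and their interaction
(all variables z-scored, so coefficients are standardized betas), with
Bonferroni thresholds per parameter family.  Structure-level gray-matter
moderation uses a permutation max-statistic over all subcortical
structures to control the family-wise error rate, permuting the anxiety
scores residualized on the nuisance terms (Freedman-Lane style) to build
the null of the anxiety x GMV interaction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InputError

log = logging.getLogger(__name__)

#: Bonferroni-corrected per-test thresholds: family-wise 0.05 over the
#: winning model's parameters (4 conditioning parameters; 2 extinction rates)
ALPHA_CONDITIONING = 0.05 / 4        # = 0.0125
ALPHA_EXTINCTION = 0.05 / 2          # = 0.025

DEFAULT_N_PERMUTATIONS = 10_000


def _inlier_mask(y: np.ndarray, sd: float | None) -> np.ndarray:
    """Mask of values within sd standard deviations, iterated to a
    fixed point so mutually-masking extremes are resolved."""
    keep = np.isfinite(y)
    if sd is None or not math.isfinite(sd):
        return keep
    while keep.sum() > 3:
        x = y[keep]
        sigma = x.std()
        if sigma == 0:
            break
        new = keep & (np.abs(y - x.mean()) > sd * sigma)
        if not new.any():
            break
        keep &= ~new
    return keep


def _winsorize(y: np.ndarray, sd: float | None) -> np.ndarray:
    """Cap extreme values at the mean ± sd·σ fence of the inlier set.

    Unconstrained first-level fits occasionally return degenerate
    parameter estimates orders of magnitude outside the plausible range;
    a few such values dominate least-squares second-level models.
    Capping (rather than dropping) bounds their leverage while keeping
    the subjects — and whatever ordinal information their extremity
    carries — in the analysis.  Affine-invariant; NaNs pass through.
    """
    if sd is None or not math.isfinite(sd):
        return y
    keep = _inlier_mask(y, sd)
    if keep.sum() < 4:
        return y
    mu, sigma = y[keep].mean(), y[keep].std()
    if sigma == 0:
        return y
    return np.clip(y, mu - sd * sigma, mu + sd * sigma)


def _z(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise InputError("cannot z-score a constant variable")
    return (x - x.mean()) / sd


@dataclass
class TermResult:
    beta: float
    se: float
    t: float
    p: float
    significant: bool = False
    p_fwe: float | None = None


@dataclass
class AssociationResult:
    outcome: str
    terms: dict[str, TermResult]
    alpha: float
    n: int
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# anxiety harmonization

def combine_anxiety(scores: pd.DataFrame,
                    youth_age_cutoff: float = 18.0) -> pd.Series:
    """Harmonize SCARED (youth) and STAI-trait (adult) into one z-score.

    ``scores`` needs columns ``age`` plus, per subject, either
    ``scared_child`` and ``scared_parent`` (age < cutoff) or
    ``stai_trait`` (age >= cutoff).  Child and parent SCARED reports are
    averaged, each instrument is z-scored within its own age sample, and
    the z-scores are concatenated.  Subjects missing their age-appropriate
    instrument are dropped (logged); a nonempty instrument group with
    fewer than two subjects makes the z-score undefined and raises.
    """
    age = scores["age"].to_numpy(dtype=float)
    youth = age < youth_age_cutoff
    out = pd.Series(np.nan, index=scores.index, name="anxiety_z")

    for is_youth, label in ((True, "SCARED"), (False, "STAI")):
        grp = scores.index[youth if is_youth else ~youth]
        if len(grp) == 0:
            continue
        if is_youth:
            child = scores.loc[grp, "scared_child"]
            parent = scores.loc[grp, "scared_parent"]
            raw = (child + parent) / 2.0
        else:
            raw = scores.loc[grp, "stai_trait"]
        have = raw.notna()
        dropped = grp[~have]
        if len(dropped):
            log.info("combine_anxiety: dropping %d subjects missing %s",
                     len(dropped), label)
        raw = raw[have]
        if len(raw) < 2:
            raise InputError(
                f"need >= 2 subjects with {label} scores to z-transform")
        out.loc[raw.index] = (raw - raw.mean()) / raw.std()
    return out


# ---------------------------------------------------------------------------
# parameter ~ anxiety regressions

def param_anxiety_regression(param_values, anxiety_z, age,
                             alpha_family: float = ALPHA_CONDITIONING,
                             covariates: pd.DataFrame | None = None,
                             outcome_name: str = "parameter",
                             winsor_sd: float | None = 3.0
                             ) -> AssociationResult:
    """Regress a learning parameter on anxiety, age and their interaction.

    All variables are z-scored before fitting, so the reported betas are
    standardized.  ``covariates`` (e.g. the CS+ habituation rate for
    specificity analyses) are z-scored and entered additively.  Extreme
    outcome values (degenerate first-level fits) are winsorized at the
    ``winsor_sd``-standard-deviation fence first; ``winsor_sd=None``
    disables capping.
    """
    y = _winsorize(np.asarray(param_values, dtype=float), winsor_sd)
    a = np.asarray(anxiety_z, dtype=float)
    g = np.asarray(age, dtype=float)
    mask = np.isfinite(y) & np.isfinite(a) & np.isfinite(g)
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        mask &= np.isfinite(cov.to_numpy(dtype=float)).all(axis=1)
    y, a, g = y[mask], a[mask], g[mask]
    n = len(y)
    n_terms = 3 + (0 if cov is None else cov.shape[1])
    if n <= n_terms + 1:
        raise InputError(f"need more than {n_terms + 1} complete cases")

    yz, az, gz = _z(y), _z(a), _z(g)
    inter = az * gz
    inter = (inter - inter.mean()) / (inter.std() or 1.0)
    cols = {"anxiety": az, "age": gz, "anxiety_x_age": inter}
    if cov is not None:
        for c in cov.columns:
            cols[str(c)] = _z(cov.loc[mask, c].to_numpy(dtype=float))
    X = sm.add_constant(pd.DataFrame(cols))
    fit = sm.OLS(yz, X).fit()

    terms = {}
    for name in cols:
        terms[name] = TermResult(
            beta=float(fit.params[name]), se=float(fit.bse[name]),
            t=float(fit.tvalues[name]), p=float(fit.pvalues[name]),
            significant=bool(fit.pvalues[name] < alpha_family))
    return AssociationResult(outcome=outcome_name, terms=terms,
                             alpha=alpha_family, n=n)


# ---------------------------------------------------------------------------
# structure-level GMV moderation with permutation FWE

def _fwl_tstats(y_r: np.ndarray, W_r: np.ndarray, df: int) -> np.ndarray:
    """t statistics of each column of W_r (already residualized on the
    nuisance block) for the outcome y_r (likewise residualized)."""
    wtw = np.einsum("ij,ij->j", W_r, W_r)
    wtw = np.where(wtw <= 0, np.nan, wtw)
    beta = (W_r.T @ y_r) / wtw
    rss = float(y_r @ y_r) - beta**2 * wtw
    rss = np.clip(rss, 1e-300, None)
    return beta * np.sqrt(wtw * df / rss)


def gmv_moderation(param_values, anxiety_z, gmv: pd.DataFrame, sex, icv,
                   n_perm: int = DEFAULT_N_PERMUTATIONS, seed: int = 0,
                   alpha: float = 0.05,
                   outcome_name: str = "parameter",
                   winsor_sd: float | None = 3.0
                   ) -> dict[str, AssociationResult]:
    """Test, per subcortical structure, whether GMV moderates the
    anxiety-parameter association, with max-statistic permutation FWE.

    Per structure the model is ``parameter ~ anxiety * gmv + sex + icv``
    (all z-scored; sex and intracranial volume as nuisance).  The family
    for the correction is the interaction test across all structures: each
    permutation shuffles the anxiety scores residualized on the nuisance
    terms, rebuilds the interaction, and records the maximum |t| across
    structures.  Significant interactions are decomposed by the anxiety
    simple slope at low/high GMV (+/- 1 SD).
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    y0 = _winsorize(np.asarray(param_values, dtype=float), winsor_sd)
    keep = np.isfinite(y0)
    y = _z(y0[keep])
    a = _z(np.asarray(anxiety_z, dtype=float)[keep])
    s = np.asarray(sex, dtype=float)[keep]
    s = s - s.mean()
    v = _z(np.asarray(icv, dtype=float)[keep])
    gmv = pd.DataFrame(gmv).loc[np.asarray(keep)]
    n = len(y)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    structures = []
    obs_t = {}
    null_t = np.full((n_perm, gmv.shape[1]), np.nan)
    details = {}
    for j, struct in enumerate(gmv.columns):
        gcol = gmv[struct].to_numpy(dtype=float)
        if gcol.std() == 0 or not np.isfinite(gcol.std()):
            log.info("gmv_moderation: skipping constant column %r", struct)
            continue
        g = _z(gcol)
        structures.append(struct)
        Z = np.column_stack([np.ones(n), a, g, s, v])
        Q, _ = np.linalg.qr(Z)
        resid = lambda M: M - Q @ (Q.T @ M)
        df = n - Z.shape[1] - 1
        y_r = resid(y)
        w_obs = resid((a * g)[:, None])
        t_obs = float(_fwl_tstats(y_r, w_obs, df)[0])
        obs_t[struct] = t_obs

        # Freedman-Lane: permute anxiety residualized on the nuisances
        Zn = np.column_stack([np.ones(n), g, s, v])
        Qn, _ = np.linalg.qr(Zn)
        a_res = a - Qn @ (Qn.T @ a)
        W = a_res[perms].T * g[:, None]          # n x n_perm
        W_r = resid(W)
        null_t[:, j] = _fwl_tstats(y_r, W_r, df)

        full = sm.OLS(y, sm.add_constant(pd.DataFrame(
            {"anxiety": a, "gmv": g, "anxiety_x_gmv": a * g,
             "sex": s, "icv": v}))).fit()
        details[struct] = full

    max_null = np.nanmax(np.abs(null_t), axis=1)
    results = {}
    for struct in structures:
        t_obs = obs_t[struct]
        p_fwe = float((1 + np.sum(max_null >= abs(t_obs))) / (1 + n_perm))
        full = details[struct]
        terms = {}
        for name in ("anxiety", "gmv", "anxiety_x_gmv", "sex", "icv"):
            terms[name] = TermResult(
                beta=float(full.params[name]), se=float(full.bse[name]),
                t=float(full.tvalues[name]), p=float(full.pvalues[name]))
        terms["anxiety_x_gmv"].p_fwe = p_fwe
        terms["anxiety_x_gmv"].significant = p_fwe <= alpha
        extras = {}
        if p_fwe <= alpha:
            b_anx = terms["anxiety"].beta
            b_int = terms["anxiety_x_gmv"].beta
            extras["simple_slopes"] = {"low_gmv": b_anx - b_int,
                                       "high_gmv": b_anx + b_int}
        results[struct] = AssociationResult(
            outcome=outcome_name, terms=terms, alpha=alpha, n=n,
            extras=extras)
    return results


def moderation_to_frame(results: dict[str, AssociationResult]
                        ) -> pd.DataFrame:
    rows = []
    for struct, res in results.items():
        t = res.terms["anxiety_x_gmv"]
        rows.append({"structure": struct, "beta": t.beta, "t": t.t,
                     "p": t.p, "p_fwe": t.p_fwe,
                     "significant": t.significant})
    return pd.DataFrame(rows).sort_values("p_fwe").reset_index(drop=True)


# ---------------------------------------------------------------------------
# raw-SCR repeated-measures ANOVA

def raw_scr_anova(cell_means: pd.DataFrame, anxiety_z, age) -> pd.DataFrame:
    """2 (Phase) x 2 (CS) within-subject ANOVA with anxiety and age as
    continuous between-subject covariates.

    ``cell_means`` has one row per subject and columns
    ``conditioning_csp``, ``conditioning_csm``, ``extinction_csp``,
    ``extinction_csm`` (per-subject mean SCR per cell).  Implemented via
    per-subject within-subject contrasts regressed on the z-scored
    covariates: the contrast intercept tests the within-subject effect and
    the covariate slopes its moderation.  Follow-ups report the CS effect
    within each phase.
    """
    need = ["conditioning_csp", "conditioning_csm",
            "extinction_csp", "extinction_csm"]
    missing_cols = [c for c in need if c not in cell_means.columns]
    if missing_cols:
        raise InputError(f"cell_means lacks columns {missing_cols}")
    cm = cell_means[need].astype(float)
    complete = cm.notna().all(axis=1).to_numpy()
    dropped = int((~complete).sum())
    if dropped:
        log.info("raw_scr_anova: dropping %d subjects with missing cells",
                 dropped)
    cm = cm.loc[complete]
    a = np.asarray(anxiety_z, dtype=float)[complete]
    g = np.asarray(age, dtype=float)[complete]
    n = len(cm)
    if n < 4:
        raise InputError("need >= 4 complete subjects")
    az, gz = _z(a), _z(g)

    cond_p, cond_m = cm["conditioning_csp"], cm["conditioning_csm"]
    ext_p, ext_m = cm["extinction_csp"], cm["extinction_csm"]
    contrasts = {
        "Mean": (cond_p + cond_m + ext_p + ext_m) / 4.0,
        "Phase": ((cond_p + cond_m) - (ext_p + ext_m)) / 2.0,
        "CS": ((cond_p + ext_p) - (cond_m + ext_m)) / 2.0,
        "Phase_x_CS": (cond_p - cond_m) - (ext_p - ext_m),
        "CS_within_conditioning": cond_p - cond_m,
        "CS_within_extinction": ext_p - ext_m,
    }

    rows = []
    X = sm.add_constant(pd.DataFrame({"anxiety": az, "age": gz}))
    for name, c in contrasts.items():
        c = c.to_numpy(dtype=float)
        if name == "Mean":
            # the grand-mean contrast carries the between-subject effects
            labels = (("anxiety", "Anxiety"), ("age", "Age"))
        else:
            labels = (("const", name), ("anxiety", f"{name}_x_Anxiety"),
                      ("age", f"{name}_x_Age"))
        if np.allclose(c - (c.mean() if name == "Mean" else 0.0), 0.0):
            for term, label in labels:
                rows.append({"effect": label, "F": 0.0, "df1": 1,
                             "df2": n - 3, "p": 1.0})
            continue
        fit = sm.OLS(c, X).fit()
        for term, label in labels:
            t = float(fit.tvalues[term])
            rows.append({"effect": label, "F": t * t, "df1": 1,
                         "df2": int(fit.df_resid),
                         "p": float(fit.pvalues[term])})
    return pd.DataFrame(rows)


def cohort_cell_means(series_map: dict[str, "pd.DataFrame | object"]
                      ) -> pd.DataFrame:
    """Per-subject phase x CS mean SCR table from TrialSeries objects."""
    rows = {}
    for sid, series in series_map.items():
        df = series.trials if hasattr(series, "trials") else series
        row = {}
        for phase in ("conditioning", "extinction"):
            for cs, key in (("CS+", "csp"), ("CS-", "csm")):
                vals = df.loc[(df["phase"] == phase) & (df["cs"] == cs),
                              "scr"].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                row[f"{phase}_{key}"] = (float(vals.mean()) if len(vals)
                                         else np.nan)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")
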