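# Methods

`threatlearn` implements a trial-level computational analysis of threat
conditioning and extinction measured with skin-conductance responses
(SCR): preprocessing, a family of fourteen associative-learning models,
per-subject least-squares fitting with BIC model comparison, parameter
and model recovery, and second-level associations with anxiety severity
and subcortical anatomy. This note records the model assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Task and data model

The task has three phases per subject: pre-conditioning (4 presentations
per conditioned stimulus), conditioning (10 per CS; 8 of the 10 CS+
presentations co-terminate with the aversive UCS — an 80% reinforcement
schedule), and extinction (8 per CS, unreinforced). CS+/CS−
presentations are interleaved pseudo-randomly in two counterbalanced
orders; we constrain interleavings to at most two consecutive same-CS
trials (the original design is described only as "pseudo-randomized").
The two unreinforced CS+ conditioning positions are fixed per order, and
the first CS+ conditioning trial is always reinforced so the contingency
is learnable from the outset. Inter-trial timing is not modeled; the
pipeline is trial-indexed.

The unit observation is the square-root-transformed base-to-peak SCR
amplitude (µS^0.5) in a 1–5 s post-onset window; amplitudes are
non-negative by construction and every simulated or cleaned value is
clamped at 0.

## Learning models

All models describe the trial-by-trial associative strength v between
each CS and the aversive outcome.

**Models 1–8 (Rescorla–Wagner family).** On reinforced CS+ trials the
prediction error is δ(t) = r(t) − v_CS+(t), where r(t) is the *observed*
SCR to the UCS (UCS responses diminish across acquisition, and a binary
reinforcer would have the wrong scale). Both cues update from this
error: v_CS+ += α_CS+·δ and v_CS− += α_CS−·δ, so α_CS− captures threat
generalization during acquisition and, in habituation models, φ_CS−
captures safety learning. Optional features, combined factorially:

- *learning inertia* (models 2, 5, 6, 8): the update uses
  δ_in(t) = Σ_{k=0..km} δ(t−k), with km = 2 fixed population-wide;
- *Bayesian learning-rate decay* (3, 5, 7, 8): α(t) = α/√t, with t
  counting update events within the phase from 1;
- *habituation* (4, 6, 7, 8): the emitted prediction is multiplied by
  e^(−φ_CS·[t−t0]⁺), t0 = 2 fixed, where t is the emitting cue's
  within-phase trial index. Habituation scales only the emission; the
  latent value used in later updates is unscaled (a switch exposes the
  alternative for sensitivity checks).

**Model 9 (RW–Pearce–Hall hybrid).** Associability is adaptive,
α_PH(t+1) = γ|δ| + (1−γ)α_PH(t) with α_PH(0) = 1, and the value update
is v += κ·α_PH·δ with signed δ (the printed update omits δ; we follow
the hybrid-model literature and use |δ| only in the associability
update). Separate γ and κ per cue.

**Models 10–12 (hybrid with regression read-out).** The outcome is
binary (b_UCS ∈ {0,1}), each cue updates on its own trials, and SCR is
read out linearly: β0 + β1·V (model 10), β0 + β1·α_PH (11), or
β0 + β1·V + β2·α_PH (12).

**Models 13–14 (Beta-Bernoulli uncertainty).** Per-cue Beta counts
update as α_B += u, β_B += 1 − u (u = 1 iff UCS), starting from a
uniform Beta(1,1). SCR is read out from z = h + E[θ] with
h = −ln(α_B + β_B) exactly as specified; since this h depends only on
trial count, a variance-based alternative (−ln Var[θ]) is provided
behind a `surprise="variance"` flag but the literal form is the default.
Model 14 multiplies h by the habituation factor. These models apply to
conditioning only: without any UCS their counts carry no outcome
information.

**Extinction.** No UCS is delivered; each cue's value is updated by its
own error δ = 0 − v_CS on each of its trials (no cross-cue
generalization), so responses extinguish at the cue's learning rate and
model 3's α/√t yields the diminishing extinction rate used downstream.
A literal reading of the conditioning rule (updates only on reinforced
trials) would leave extinction dynamics frozen and the rates
unidentifiable, which contradicts the fitted-and-bounded extinction
rates the procedure reports; the per-cue zero-outcome error is the
standard resolution.

**Initialization.** Both cues start at v_i, the last valid
pre-conditioning SCR (conditioning) or the first valid extinction SCR
(extinction).

## Fitting and model comparison

Parameters are estimated per subject by minimizing the summed squared
error between predicted and observed SCR over the phase's CS+ and CS−
trials (conditioning n = 20, extinction n = 16; trials still missing
after cleaning are dropped). The optimizer is Nelder–Mead restarted from
learning-rate initial values {0.1, …, 0.8}; other parameters start at
φ = 0.1, γ = 0.5, κ = 0.5, β0 = 0, β1 = 1, β2 = 0 (for the uncertainty
models, which have no learning rate, the grid is applied to β1).
Convergence tolerances are 1e-6 on parameters with at most 2000
objective evaluations per restart. Conditioning fits are unconstrained;
extinction fits clip learning rates to [−1, +1] inside the objective so
that estimates pinned at a bound are detectable and flagged.

Fit quality is scored with the Gaussian-residual BIC in the form

    BIC = −k ln(n) + n ln(RSS/n),

whose −k ln(n) term carries the opposite sign of the conventional
penalty and therefore *rewards* parameters. This negative-penalty form
is the default because it is the form the procedure this pipeline
reproduces uses, anomaly included; a `bic_convention="standard"` switch
restores +k ln(n). The consequence is documented and tested: in nested
pairs that fit equally well (e.g. model 9 with γ = 0 reproduces model 1
exactly), the negative-penalty score always prefers the richer model,
so model-recovery self-selection holds only under the standard
convention.

Population comparison: per-model mean BIC and SE, per-subject best
model and best-model fractions, a repeated-measures ANOVA on BIC (model
fixed, subject random; cross-checked against `statsmodels.AnovaRM`), and
Bonferroni-corrected pairwise paired t-tests. The winning model is the
best-scoring one, except that a simpler model statistically
indistinguishable from it is preferred.

## Preprocessing

Cleaning operates per subject, per CS, within conditioning and
extinction separately:

1. *Within-subject outliers* are flagged as missing using |z| > 3
   against the subject's pooled trial distribution, iterated to a fixed
   point (most deviant value per pass). A per-cell rule is unusable
   here: in cells of 8–10 trials an include-self z mathematically
   cannot exceed ≈2.9 (the cut would never fire), while a leave-one-out
   cell z chases the genuine monotone learning/extinction trend and
   flags real data. The pooled rule stays sensitive to recording
   artifacts, which dwarf any trial, and blind to ordinary learning
   dynamics.
2. *Exclusion*: subjects missing more than 50% of a modeled phase's
   trial values — counted before any interpolation — are excluded.
3. *Interpolation*: interior runs of up to three consecutive missing
   values are linearly interpolated; longer runs stay missing.
4. *Extrapolation*: trailing missing values in conditioning and leading
   missing values in extinction continue the line through the two
   nearest valid points (flat if only one exists), clamped at 0.

Interpolated positions remain marked in the missingness mask, which
makes the pass idempotent and lets downstream code distinguish observed
from filled values. Group-level outliers on per-CS mean SCR use the
same |z| > 3 rule across subjects.

## Synthetic cohorts

The generator shares the forward model with the fitter, so noiseless
simulation is bit-identical to prediction. Defaults define the study
conditions the pipeline is meant to operate under:

- n = 215 subjects, generating model 7 (decay + habituation), ages 8–50;
- per-parameter truncated-normal distributions (e.g. learning rates
  ≈ N(0.4, 0.18) in [0.05, 0.9]; habituation rates ≈ N(0.25, 0.15) in
  [0, 0.8]);
- UCS amplitudes decaying exponentially across reinforced trials
  (initial 1.0 µS^0.5, rate 0.12 per trial, noise sd 0.10, clamped at 0);
- trial-level Gaussian observation noise (sd 0.12 µS^0.5, clamped at 0)
  and 5% random missingness;
- anxiety severity z coupled to the safety-learning parameter (φ_CS−
  for habituation models) with standardized slope −0.3, and that
  coupling moderated by left nucleus accumbens volume with standardized
  slope +0.5 — strong enough to be detectable through first-level
  estimation noise at the default cohort size, which is the point of a
  power simulation;
- structure-wise gray-matter volumes with FreeSurfer-scale means, ~35%
  of variance explained by intracranial volume plus a small sex effect.
  The planted moderation rides on the structure-specific (ICV- and
  sex-independent) component of accumbens volume, so the remaining 16
  structures are genuinely null rather than null-by-name: a moderation
  planted on the raw volume would leak into every structure through the
  shared global component.

What the generator does *not* emulate: continuous SCR waveforms,
autocorrelated trial noise, age-related amplitude decline, informative
missingness, and instrument-specific anxiety measurement error. Passing
tests therefore demonstrate that the pipeline recovers the structure it
assumes, not that real SCR data satisfy those assumptions.

## Second-level analyses

Anxiety harmonization averages child and parent SCARED reports in youth,
then z-scores each instrument within its own age sample. Each fitted
parameter of the winning model is regressed on anxiety, age, and
anxiety×age with all variables z-scored (standardized β), with
Bonferroni familywise thresholds 0.05/4 = 0.0125 (conditioning) and
0.05/2 = 0.025 (extinction; both CS rates are tested). Extreme
fitted-parameter values are winsorized at the 3-standard-deviation
fence of the iterated inlier set before regression: unconstrained
first-level fits occasionally return degenerate estimates (habituation
rates of ~7 were observed) that dominate least squares. Capping rather
than excluding bounds their leverage while keeping those subjects — and
the ordinal information in their extremity — in the analysis; the rule
is affine-invariant and can be disabled (`winsor_sd=None`).

Structure-level moderation fits parameter ~ anxiety × GMV + sex + ICV
per structure (all z-scored) and controls the family-wise error of the
interaction across all 17 subcortical structures with a permutation
max-statistic: anxiety is residualized on the nuisance terms
(Freedman–Lane style), permuted, the interaction rebuilt, and the
maximum |t| over structures recorded per permutation (10,000 by
default); p_FWE = (1 + #{maxT ≥ |t_obs|})/(1 + n_perm). Significant
interactions are decomposed by the anxiety simple slope at ±1 SD GMV.
Vertex-wise cortical analyses are out of scope; the structure-level
family is the substitute.

The raw-SCR analysis is a 2 (Phase) × 2 (CS) within-subject ANOVA with
anxiety and age as continuous between-subject covariates, implemented
through per-subject within-subject contrasts regressed on the z-scored
covariates (the contrast intercept tests the within-subject effect, the
covariate slope its moderation), plus per-phase CS follow-ups.

## Recovery

Parameter recovery simulates n_sim subjects from parameters drawn
uniformly over plausible ranges, refits, and reports per-parameter
Pearson correlations; a model is *recoverable* when every correlation
reaches 0.20 (undefined correlations count as failures). Model recovery
tallies a BIC-selection confusion matrix. Because the generating noise
level is a free choice, absolute correlations are meaningful only
relative to the stated noise; the acceptance checks pin noise to 25% of
the simulated signal range.

## Numerical choices and limitations

- Variance floor 1e-12 in the BIC (flagged) for noiseless fits.
- Ties toward the simpler model in comparison; ties toward α = 0 on
  degenerate flat data arise naturally from the restart grid.
- Problem sizes in the test suite (cohort replicates, permutation
  counts, simulation counts) are scaled to desk-top runtimes; the
  calibration test uses 200 replicate cohorts at n = 100 with 300
  permutations, and the full-pipeline planted-effect check uses 5
  replicate cohorts at the default n = 215.
- Per-subject estimates from 36 modeled trials are noisy by design;
  the habituation/safety-learning rate φ_CS− recovers with r ≈ 0.4–0.8
  depending on the cohort, which attenuates second-level effect sizes
  (the regression of fitted on generating parameters is the reference
  for interpreting any second-level β).
- Hierarchical (multi-level) estimation is deliberately out of scope.
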