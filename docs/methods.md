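# Methods

This note documents the model, the estimation scheme, the synthetic
data, and the numerical and design choices behind `pedcm`, in enough
detail to reimplement or audit each stage.

## The microcircuit model

One cortical source is modelled as six neural-mass populations with
laminar assignments: spiny stellate cells (`ss`, granular layer),
superficial pyramidal cells (`sp`) and interneurons (`si`), deep
regular-firing (`dp`) and burst-firing (`tp`) pyramidal cells and deep
interneurons (`di`).  The state of population *p* is its membrane
potential `V_p` (mV) and three conductances `g_{p,k}` for k ∈
{AMPA, NMDA, GABA}, giving 24 states.  Dynamics (time in ms):

    C dV_p/dt = cL (V_L − V_p) + g_{p,A} (V_E − V_p)
                + g_{p,N} m(V_p) (V_E − V_p) + g_{p,G} (V_I − V_p) + u_p
    dg_{p,k}/dt = (σ_{p,k} − g_{p,k}) / τ_k
    σ_{p,k}    = Σ_q γ_eff(p,q,k) f(V_q)

* firing function: logistic, `f(V) = 1/(1+exp(−(V−V_T)/8))` with
  threshold `V_T = −40 mV` (slope 0.125 /mV);
* magnesium gate: `m(V) = 1/(1 + β exp(−αV))`, α = 0.062 /mV, β = 0.1;
* reversal potentials `V_L = −70`, `V_E = +60`, `V_I = −90 mV`;
  capacitance-like constant `C = 8`, leak `cL = 1`;
* time constants `τ_AMPA = 4`, `τ_GABA = 16`, `τ_NMDA = 100 ms`.

The wiring couples the laminae in a feedforward/feedback loop:
excitatory projections (each through AMPA *and* NMDA)
`ss→sp, ss→si, sp→ss, sp→dp, sp→di, dp→tp, tp→di, tp→ss`, and
intra-laminar inhibition `si→{sp,ss,si}`, `di→{dp,tp,di}` — 22 directed
gains in total.  The template is fully configurable; the default gains
are AMPA 0.3, NMDA 1.0, GABA 5.0.

**Why these defaults.**  Two constraints shaped them.  First, the
resting fixed point must remain stable over the whole range of gain
shifts the cohort generator produces (log-gain displacements up to
about ±0.9), which requires inhibition-dominated coupling.  Second, the
NMDA gains must be identifiable from an evoked response: near rest the
magnesium gate suppresses NMDA current (m(−70 mV) ≈ 0.1 at β = 0.1),
so with a conventional small NMDA gain the Jacobian column of an NMDA
parameter is two orders of magnitude smaller than an AMPA column and
the second level can never detect NMDA effects.  Raising the NMDA gain
and easing the gate (β = 0.1) brings NMDA sensitivity to within an
order of magnitude of AMPA while keeping the circuit damped.  These are
deliberate electrophysiological design choices of this package, made
once and frozen, not fitted quantities.

**Condition effects.**  The deviant condition multiplies every flagged
(by default: every excitatory) edge by `exp(b)`; `b` are log-gains, zero
meaning no mismatch effect.  Each condition is integrated from *its
own* resting fixed point and baseline-corrected by its own resting
observation, so pre-stimulus samples are exactly at baseline in both
conditions; with all `b = 0` the two conditions are identical to
machine precision.

**Free parameters.**  Positive parameters θ (gains, time constants,
input amplitude, observation gain) are estimated as log-scale factors,
θ = θ_default·exp(λ); condition log-gains `b` enter additively.  The
map is bijective on the free subset.

## Simulation

The epoch is −100 to 400 ms at 500 Hz (2 ms step, 251 samples), with
the stimulus at 0 ms; the exogenous drive is a Gaussian bump (onset
60 ms, SD 16 ms, amplitude 32) entering the stellate population, zero
before 0 ms.  Integration is fixed-step RK4 at 1 ms, decimated onto the
output grid; halving the step changes the ERF by < 0.1 % RMS.  Samples
before 0 ms are set to the resting state rather than integrated (the
input is identically zero there).  The observed ERF is
`gain · Σ_p w_p (V_p(t) − V_p(rest)) + baseline` with default weights
0.2/0.8/0/0.2/0.2/0 (pyramidal-dominated).  The mismatch amplitude
`Y_max` is the largest |deviant − standard| over samples with
130 ≤ t ≤ 180 ms, endpoints inclusive.

The resting state is found by damped Newton on the 6-dimensional
reduced system (at a fixed point g = σ(V)), to a residual below 1e−9;
if Newton from `V = V_L` fails, the solver relaxes the full dynamics
along pseudo-time and polishes the endpoint, erroring only when the
state diverges (no resting state exists).  A numba-compiled batched
RK4 kernel integrates many parameter vectors at once (this is what
makes finite-difference Jacobians affordable); a pure-numpy
implementation of the same kernel is the fallback and is held to agree
with it at machine precision by the test suite.

## First level: variational Laplace

Data are the concatenated standard and deviant amplitude vectors
(502 samples).  The model is `y = f(λ) + ε`, ε i.i.d. Gaussian with
precision `exp(h)`; priors are λ ~ N(0, 1/16·I) on the log scale and
h ~ N(0, 16) (a fixed-precision mode with zero hyperprior variance is
available and is used by the conjugate-oracle tests).  Each iteration:

1. central finite-difference Jacobian J at the current mean
   (step 1e−4, one batched forward pass);
2. Gauss–Newton/Levenberg–Marquardt candidate
   `Δλ = (πJ'J + P₀ + δ·diag(πJ'J+P₀))⁻¹ (πJ'e − P₀(λ−μ₀))`, with
   damping δ initialized at 1/32, halved on acceptance, doubled on
   rejection;
3. noise update: 1-D Newton on h given the residuals and the curvature
   trace, with posterior variance from the negative inverse curvature;
4. the candidate is evaluated with its own fresh Jacobian and accepted
   only if F increases — the recorded F trace is therefore
   non-decreasing by construction.

Convergence: an accepted gain < 0.01 nats, at most 64 iterations, or 8
consecutive rejections (flagged `local_optimum`, not an exception).  A
forward-model failure at a candidate (e.g. a diverging circuit) counts
as a rejection.

**Free-energy decomposition.**  F is reported in six named parts whose
sum is exactly F:

| term | definition |
|---|---|
| accuracy(states) | −N/2·ln 2π + N/2·m_h − ½ e^{m_h} ‖e‖² |
| accuracy(parameters) | −½ e^{m_h} tr(JΣJ') (posterior-uncertainty correction) |
| accuracy(precision) | −½ (e^{m_h+s_h/2} − e^{m_h})(‖e‖² + tr JΣJ') |
| complexity(states) | 0 (the hidden states are deterministic) |
| complexity(parameters) | KL of the parameter posterior from its prior |
| complexity(precision) | KL of the noise-log-precision posterior from its hyperprior |

The assignment of the curvature terms to the accuracy side is a
declared convention of this package.  complexity(states) is identically
zero because the model has no state noise; the reliability report marks
such zero-variance components "undefined" rather than erroring.  For a
linear-Gaussian forward model with fixed noise, F at the converged
posterior equals the analytic log evidence (verified to 1e−3, posterior
moments to 1e−6).

**Which parameters are estimated.**  Cohort-level analyses free the 22
connection gains — precisely the set the second level models — holding
condition gains, time constants and observation parameters at their
generative defaults.  This keeps the first level well conditioned and
the second level fully informed; freeing `b` as well is supported for
single-subject work.

## Second level: PEB, model space, BMR

Subject posteriors (means and covariances over the 22 gains) enter

    θ̂_n ~ N((X_n ⊗ I) β, Σ_n + e^{−γ} I)

with X the design matrix (ones column + mean-centered covariate),
β ~ N(0, I) and a single between-subject log-precision γ with prior
N(0, 1/16).  Given γ the model is linear-Gaussian and β's posterior and
the marginal evidence are closed-form; γ is chosen by a bounded 1-D
search on the evidence plus its prior, with a Laplace correction from
the numeric curvature.  Empirical priors per subject are
`(X_n ⊗ I)β̂` with covariance `e^{−γ̂}I + A_n Σ_β A_nᵀ`.

The six parameter groups are {superficial, deep} × {AMPA, NMDA, GABA},
where a connection is "superficial" when its postsynaptic target lies
in the superficial or granular layer (`sp`, `si`, `ss`) and "deep"
otherwise.  The 63 models are all non-empty group subsets (bit *i* of
the model index = inclusion of group *i*); each is scored by Bayesian
model reduction from the full fit — covariate-effect priors of excluded
groups are pinned to zero variance (numerically 1e−8; the reduction is
insensitive to this value and the BMR/refit agreement test uses the
same pinning).  Softmax over the 63 free energies gives posterior model
probabilities; ties resolve to the lowest index.  Group-level evidence
is reported as the free energy of each single-group model relative to
the worst group (minimum 0 by construction).  Pruning removes, one at a
time, the individual covariate effect whose exclusion most increases F,
until no removal gains; inclusion probabilities are softmaxes of
(with, without) at the final model.

## Reliability

Trials are split by 1-based position parity and each half averaged; the
whole first level is rerun per half.  ICC(2,1) follows the two-way
random-effects ANOVA decomposition

    ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

with the F test MS_R/MS_E on (n−1, (n−1)(k−1)) degrees of freedom; the
report labels entries at p < 0.05 / 0.005 / 0.0001.  Parameter-level
ICCs use posterior means only.  The implementation is checked to 1e−12
against a sums-of-squares oracle and cross-checked against an
independent statistics package, and its null type-I rate is calibrated
(0.05 ± 0.02 over 2000 simulated null matrices).

## Synthetic cohorts

The generator draws a standardized covariate c_n (uniform, then
z-scored), sets each subject's log-gains to
`β_g·c_n·1[param ∈ g] + N(0, re_sd²)`, simulates the noiseless ERF pair
from the subject's circuit, and adds white Gaussian noise per trial.
Two realism features matter for what the tests can show:

* **Per-subject noise levels** (`noise_heterogeneity_sd`, default 0.3):
  each subject's trial-noise SD is scaled by a log-normal factor.
  Without it every subject has the same SNR, the accuracy term of F
  carries no subject identity, and split-half ICC of F is near zero *by
  construction* — a property of the idealized generator, not of the
  method.  Real cohorts always differ in SNR.
* **White noise only**: trial noise is independent across samples.
  Real MEG noise is autocorrelated and shares power between conditions;
  passing recovery tests here does not demonstrate robustness to
  structured noise, only correctness of the estimation machinery under
  its own assumptions.

Ground truth (per-subject λ, β, generating mask) is stored alongside
the cohort and is never read by inference code — a file-access audit in
the test suite enforces this.

## Problem sizes and default study conditions

Chosen once, as this package's desk-scale study design:

* model identification: 20 cohorts, n = 12 subjects, 24 trials per
  condition, β = 0.5 on superficial AMPA + NMDA, trial noise SD 1.0
  (≈ 1.6 % of the evoked peak after averaging), random-effect SD 0.1;
* reliability analogue: n = 12, 24 trials, no covariate effect,
  random-effect SD 0.25, trial noise SD 0.5, noise heterogeneity 0.5;
* recovery: one subject, one gain perturbed +0.3, measurement noise SD
  0.05 (≈ 0.4 % of the peak);
* determinism: the full pipeline twice, n = 6, 8 trials.

## Known limitations

* Single cortical source; no conduction delays, no extrinsic
  connections, no lead-field model — the observation is an abstract
  weighted sum of membrane-potential excursions.
* The free-energy decomposition's accuracy/complexity split beyond the
  two KL terms is a convention; only the total F is a bound on log
  evidence.
* The greedy BMR prune is a deterministic local search; it can in
  principle stop at a local optimum of the effect-subset lattice.
* Between-session (as opposed to split-half) reliability is out of
  scope.
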