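# Methods

## Model structure and assumptions

Both circuits are rate models on a discrete trial axis: a trial is an
event (CS present or absent, US intensity ≥ 0), activities are linear
functions of the current weights, and all plasticity is applied once per
trial.  There is no intra-trial time, no inter-trial-interval effect, no
neural noise, and a single CS.  Activities are firing-rate-like and
therefore floored at zero by default (`rectify_activities=True`); the
unclamped variant is exposed for sensitivity analysis because the fear
unit's drive `w_F·CS − w_FE·E` can go negative when inhibition is strong.
The clamped fear activity is also the `F` used inside the safety learning
signal, so a fully suppressed fear response generates no further safety
learning — this gating is what terminates extinction learning and leaves a
latent fear memory (`w_F` is never unlearned; extinction is inhibitory
learning, not erasure).

Updates are synchronous: activities and all learning signals are evaluated
on the pre-update weights, then every weight steps together.  Sequential
updating would change trajectories; the trial-indexed form of the update
rules (all terms at trial *t*) implies the synchronous reading.

Initial weights are zero (a naive animal) unless a state is supplied.

## Parameters

All quantities are dimensionless; activities are in units of the US
intensity used at conditioning (1 by default).

| parameter | default | role |
|---|---|---|
| `alpha_F`, `alpha_P` | 0.5 | acquisition rates of the fear/persistent (CEA/LA) weights |
| `alpha_E` (basic), `alpha_E1`, `alpha_E2` (extended) | 0.05 | safety-learning rates of the extinction units |
| `w_FE` / `w_F_E2` | 2.0 | extinction→fear (ITC→CEA) inhibition weight |
| `w_E2_E1` | 0.02 | vmPFC→ITC drive |
| `beta_E2`, `beta_E2_inf` | 0.005 | relaxation (consolidation) rates between `w_E2` and its capacity |
| `alpha_E2_inf` | 0.02 | vmPFC-gated growth rate of the capacity `w_E2∞` |

Default trial counts: 60 conditioning, 50 extinction, 20 resting, 5
retrieval, 50 re-extinction (all configurable).

Rationale.  The defaults place the circuit in the regime where the graded
uncertainty effect exists at all:

* acquisition must converge within the conditioning phase at every
  reinforcement probability on the sweep grid (hence `alpha_F = 0.5` with
  60 conditioning trials — at p = 0.3 only ~18 trials are reinforced);
* safety learning must be slow enough that the extinction unit is *not*
  saturated when extinction begins (hence `alpha_E = 0.05`).  If safety
  learning is fast relative to the conditioning phase, the extinction unit
  reaches its ceiling during conditioning at every p < 1 and both the
  residual fear and the extinction time constant lose their monotone
  dependence on p.  The robustness grid used by the acceptance tests spans
  this operating regime: `alpha_F = alpha_P ∈ {0.5, 0.7, 0.9}`,
  `alpha_E ∈ {0.03, 0.04, 0.05}`, `w_FE ∈ {2, 3}`;
* the consolidation rates sit an order of magnitude below `alpha_E2`
  (early- vs late-phase plasticity requires a fast/slow separation), with
  `beta_E2_inf` small enough that the capacity is built chiefly by the
  vmPFC-gated term rather than by passive relaxation — otherwise
  consolidation would proceed even with the vmPFC silenced and the
  silencing dissociation would vanish;
* the direct vmPFC→ITC drive `w_E2_E1` is deliberately weak: the vmPFC
  shapes fear mainly through the slow capacity pathway.  This is what makes
  retrieval of the extinction memory effectively vmPFC-independent while
  its consolidation is vmPFC-dependent.

## Perturbations (optogenetic-style clamps of the vmPFC)

A perturbation overrides the vmPFC unit's *output firing* over a window
(a phase label or a trial range): silencing clamps `E1 = 0`; activation
clamps `E1` to a drive level, by default the current LA activity `P(t)`
(a saturating "strong activation").  The clamped `E1` is what propagates to
the ITC (`E2 = w_E2·CS + w_E2,E1·E1`) and to the capacity dynamics
(`alpha_E2_inf·CS·E1`).

Plasticity at the CS→vmPFC synapse itself follows the postsynaptic
activity: a silenced unit is not depolarized and undergoes no Hebbian
change, so `w_E1` is frozen while `E1` is clamped to 0.  (The alternative —
letting `w_E1` learn from the signal `[F·(P − US − 0)]₊` while the unit is
silent — makes silencing *enhance* CS→vmPFC potentiation, and the enlarged
vmPFC→ITC drive at retrieval then masks the consolidation deficit the
silencing experiment demonstrates.)  Under activation the clamped `E1`
enters the learning signal `[F·(P − US − E1)]₊`, which is typically zero
because the drive exceeds the safety prediction error.

Measurement convention: "fear at retrieval" is the fear-unit activity on
the **first** retrieval trial (the probe before any within-phase
re-extinction).

A structural note on the retrieval-silencing contrast.  With the vmPFC
silenced at retrieval, fear differs from control by exactly
`w_F,E2 · w_E2,E1 · w_E1` (2 × 0.02 × w_E1 ≈ 0.02 at defaults) whenever the
control fear is positive.  Exact equality with control is impossible in
this architecture while retrieval-activation still has an effect, because
both run through the same `w_E2,E1` coupling; the model's claim is that the
retrieval-silencing effect is *small* — here a fifth of the
extinction-silencing effect — not identically zero.

## Consolidation and spontaneous recovery

During resting trials only the relaxation terms act: the gap
`w_E2 − w_E2∞` decays geometrically at rate `beta_E2 + beta_E2_inf` while
the combination `beta_E2_inf·w_E2 + beta_E2·w_E2∞` is conserved (the tests
assert this analytic solution to 1e-10).  After extinction the fast weight
exceeds the capacity, so resting pulls `w_E2` down toward it — partial loss
of the extinction memory, i.e. spontaneous recovery, whose size is set by
how much capacity the vmPFC built during extinction.  Weights are floored
at zero after each update, as relaxation from asymmetric states could
otherwise drive a weight slightly negative.

## Schedules

Builders produce full-reinforcement, seeded Bernoulli partial
reinforcement, evenly interleaved ("deterministic interleave")
partial reinforcement, extinction, resting, retrieval, concatenations and
the shock procedure (re-conditioning at a multiple of the base conditioning
intensity followed by re-extinction).  The interleave mode reinforces trial
*i* iff `floor((i+1)p) > floor(ip)` — `floor(np)` US trials spread as
evenly as possible — and exists to make sweeps and worked examples exactly
reproducible without a seed; Bernoulli mode is the realistic protocol.
US-alone (unsignaled shock) trials, variable inter-trial intervals and
schedules with decaying US frequency are out of scope.

These generators emulate the *structure* of behavioral protocols, not their
biology: passing the suite shows the circuit reproduces the qualitative
phenomenology (PREE and its grading, consolidation dissociations,
shock-procedure contrast) under idealized stimulus streams, and says
nothing about freezing rates of real animals, session timing, or context.

## Extinction-fit and uncertainty metrics

The extinction time constant comes from a bounded nonlinear least-squares
fit of `F₁·exp(−t/τ) + F₀` (`scipy.optimize.curve_fit`), with `t = 0` at
the first extinction trial, `F₀, F₁ ≥ 0`, `τ > 0`, initialized at
`F₀ ← last value`, `F₁ ← first − last`, `τ ← length/3`.  The fit is flagged
non-converged when the optimizer fails or the fitted amplitude is below
1e-8 (a flat series carries no time constant).  Waiting-time uncertainty is
the Shannon entropy of the geometric waiting time to the next US,
`H = h₂(p)/p` in bits (base-2 by default; a nats option is exposed), which
the tests check against a truncated brute-force sum to 1e-9.

## The statistical observer

The surprise module is a Bayesian logistic regression over features
(intercept, CS) with a Gaussian prior (zero mean, unit variance per weight
by default), updated sequentially.  Because the feature vector is identical
on every CS trial, the likelihood constrains the weights only through the
scalar score `a = w₀ + w₁`, and the exact posterior is the prior tilted
along that direction by `σ(a)^n₁ σ(−a)^n₀` with `(n₁, n₀)` the US/no-US
counts.  The per-trial update increments the counts and recomputes the
exact first two score moments by Gauss–Hermite quadrature (81 nodes)
centred on the 1-D posterior mode found by Newton iteration — robust even
after hundreds of observations, when the likelihood dominates the prior.
Weight-space mean and covariance then follow exactly from the
linear-Gaussian conditional structure.  A dense-grid exact-Bayes oracle
(`GridBayesOracle`, 321² points over ±8 prior SDs) validates the update;
agreement is at quadrature precision.

The predictive probability uses the standard probit approximation
`σ(m/√(1 + πs²/8))`; surprise is reported in nats by default (base-2
option) and capped at 30 to keep degenerate predictives finite.  Note that
a static-weight observer converges to the empirical US rate: during
extinction the estimated probability declines monotonically toward
`n₁/(n₁+n₀)`, not to zero, on finite protocols.

Learning-signal/surprise correlations are Pearson, pooling the fear- and
persistent-unit signals against the US surprise on reinforced trials and
pairing the extinction-unit signal with the no-US surprise on unreinforced
CS trials; unrealized branches (e.g. US surprise during extinction, where
both it and the fear learning signal are identically zero) are excluded,
and zero-variance sides are flagged undefined rather than returned as a
number.

## Known limitations

* The alternating conditioning/extinction protocol in the extended model
  shows the accumulating, saturating residual for the first sessions, after
  which consolidation slowly *reduces* the residual again; the monotone
  build-up claim holds strictly in the basic model.
* Gradual extinction (decaying US frequency) is deliberately out of scope:
  nothing in the plasticity rules integrates learning signals over trials.
* No dorsomedial PFC fear-promoting pathway, no reinstatement, no
  contextual/hippocampal input, no stimulus generalization.
* All reported dynamics are deterministic given the schedule; biological
  trial-to-trial variability is not modelled.
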