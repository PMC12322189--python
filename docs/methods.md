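# Methods

## Model

The 2-HT eyewitness identification model is a multinomial processing tree
over two trees per condition. For a culprit-present lineup, the culprit's
presence is detected with probability `dP` (→ culprit identification);
otherwise the suspect may be selected through bias `b`, or through guessing
`g` in which case the suspect is sampled with the fixed constant `c = 1/n`
(six-person lineups: `c = 0.16667`) and a filler with `1 - c`; with neither
detection, bias nor guessing the lineup is rejected. Culprit-absent lineups
mirror this with absence detection `dA` (→ correct rejection) and the same
`b` and `g` acting on the innocent suspect. Both trees' category
probabilities sum to one algebraically for any parameter values in the unit
box.

Assumptions worth stating explicitly:

- **Aggregation.** Each participant contributes two culprit-present and two
  culprit-absent trials; the likelihood treats all trials in a condition as
  independent draws from the condition's category probabilities (two
  multinomials per condition). Participant-level clustering is ignored, as
  is standard for aggregate MPT analyses. Standard errors are therefore
  conditional on that independence assumption.
- **Sampling constant.** `c` is fixed, not estimated. The default 0.16667
  is the conventional five-digit rounding of 1/6; the difference from the
  exact rational is numerically irrelevant (refitting with `c = 1/6`
  changes the packaged-study estimates by < 1e-6) but 0.16667 is kept as
  the default because it is the constant conventionally written into MPT
  model files for six-person lineups.

## Estimation

The multinomial log-likelihood kernel `Σ O·ln p` is maximised over the free
parameters in `[0,1]` by L-BFGS-B with hand-derived analytic gradients,
from 20 starts (one central start at 0.25 plus seeded uniform draws on
`[0.02, 0.98]`); the best converged solution wins, ties broken by first
occurrence. Optimisation runs on the raw probability scale rather than a
logit scale because `dA` estimates sit on or near the boundary of the
parameter space, where a logit transform degenerates. Convergence uses
`ftol = 1e-13` and `gtol = 1e-8`; the packaged-study optimum is stable to
~1e-11 in log-likelihood across starts.

Restrictions (equality classes across conditions and fixed values) are
resolved by union-find into a free-parameter map; degrees of freedom are
`4 × conditions − free parameters` (four independent category probabilities
per condition). Goodness of fit is `G² = 2 Σ O·ln(O/E)` against fitted
expected counts, zero-observed cells contributing zero, with an asymptotic
central-χ² p-value.

Wald 95% intervals use the observed information (central-difference Hessian
of the log-likelihood at the MLE, step 1e-5); intervals are clipped to
`[0,1]`, boundary estimates get one-sided intervals and a flag, and a
singular information matrix yields NaN standard errors with a warning. The
interval construction used by the original MPT software for this model
family is not documented; agreement on the packaged study is at the
two-decimal level for `b` (0.03–0.06), which is the precision anything
downstream relies on.

## Nested-model tests and the bootstrap

`ΔG²` between a base model and a model with one added restriction is
asymptotically χ² on the difference in free parameters — but this fails
when the restricted parameter (here `dA`) lies on the boundary, where the
central-χ² p-value is far too conservative (0.99 vs ~0.83 on the packaged
study). The parametric bootstrap therefore: fits the restricted model,
draws replicate datasets from its fitted probabilities at the observed
per-tree totals, refits **both** models to each replicate (5 starts each,
warm-started at the observed-data solutions; insensitivity to replicate
start count was checked at 12 starts), and reports the simple proportion of
replicate `ΔG²*` at or above the observed value. Defaults: 2,000
replicates. Every replicate uses an independent substream spawned from the
user seed, so the p-value is reproducible and independent of execution
order. Failed replicate fits are retried with fresh starts; more than 1%
unrecovered failures aborts.

## Forgetting curves

Three families describe the decline of `dP` with delay `t` in days (the
average actual delays 0, 1, 8, 33, not the nominal ones):

- modified power `λ(1+t)^−ψ` — fitted, by default, as exact OLS of
  `ln dP` on `ln(1+t)`, the standard estimation route for power-law
  retention data (which weights proportional errors equally across the
  delay range); direct raw-scale multi-start NLS is available via
  `objective="raw"`. The two objectives give visibly different coefficients
  on real data (ψ ≈ 0.73 vs ≈ 0.76 on the packaged study) while their
  raw-scale R² agree to two decimals;
- modified logarithmic `λ·ln(1+t) + ψ` — exact closed-form OLS;
- simplified Wickelgren power-exponential `m = λ(1+βt)^−ψ` with `λ` fixed
  to the no-delay `dP` estimate rounded to four decimals (the theory's
  boundary condition `m(0) = λ`), `β ≥ 0` and `ψ` fitted by raw-scale
  multi-start NLS.

`R²` and `SS_res` are always reported on the raw scale
(`R² = 1 − SS_res/SS_tot`; a constant input series reports `R² = 0`).
The full-precision `dP` estimates feed the curve fits; rounding them to
four decimals first moves the coefficients only in the fourth decimal.

## Sensitivity analysis

For a χ² test with effect size `w`, the statistic is noncentral χ² with
noncentrality `w²·N` over `N` total responses. `N` counts responses, not
participants (2,108 participants × 4 lineups = 8,432). Power is the
noncentral upper-tail mass above the central χ² critical value
(`scipy.stats.ncx2`, cross-checked in the tests against a Poisson-mixture
series to 1e-9); the minimal detectable `w` is found by Brent root solving
to 1e-8.

## Synthetic data

`simulate_study` draws, per condition, two multinomials of size
`2 × participants` from the model probabilities — exactly the process the
aggregated likelihood assumes. The default design mirrors the packaged
study: delays 0/1/8/33 days, 550/532/520/506 participants, `b = 0.04`,
`g = 0.45`, `dA = 0.02` constant, and `dP` evaluated from the fitted power
curve `0.2744(1+t)^−0.726` — values derived from the packaged study's own
estimates, so simulations are realistic for that paradigm rather than
ground truth. What the generator does **not** emulate: participant-level
heterogeneity and clustering (four responses per person), lineup-position
effects, and selective dropout. Passing recovery and calibration tests
therefore validate the estimation machinery under the model's own
assumptions, not robustness to violations of them.

## Numerical and design choices

- Probabilities are floored at 1e-300 inside logarithms during optimisation
  (a positive count against a structurally zero probability still drives
  the likelihood to −∞ in the user-facing `log_likelihood`).
- Condition ordering: datasets are sorted by actual delay at validation;
  fits are invariant to input order.
- Boundary estimates (within 1e-6 of 0 or 1) are flagged, not errors.
- The test suite's null-calibration and recovery checks run 200 simulated
  studies at the packaged study's sample sizes; the bootstrap check uses
  2,000 replicates — sizes chosen to keep Monte-Carlo error at or below
  the tolerances being asserted.

## Known limitations

- No participant-level (hierarchical) modelling; confidence intervals and
  tests assume independent responses.
- Wald intervals only; no profile-likelihood or bootstrap intervals for
  parameters.
- The EQN export writes this model family only; arbitrary MPT models are
  not parsed.
- Simultaneous six-person photo lineups are the modelled procedure;
  sequential lineups, confidence ratings and position effects are out of
  scope.
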