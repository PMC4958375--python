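# Methods

## Model

Incentive value is treated as the precision-weighted prediction error that a
reward elicits under a Gaussian generative model of its context. A context
variable C holds a belief about the mean of the reward distribution; when a
reward (or an option with expected value) R is observed, the belief update
shifts the posterior mean by

    V(R) = sigma_C^2 / (sigma_C^2 + sigma_R^2) * (R - mu_C)

and this shift *is* the incentive value. Two normalizations follow
immediately: the contextual expectation mu_C is subtracted from the reward
(subtractive normalization), and the residual is multiplied by a gain that
shrinks as reward variance sigma_R^2 grows relative to contextual precision
(divisive normalization).

Three generative models are implemented in `bcv.core`:

* **Flat** (`FlatContextModel`): a single Gaussian prior (mu_C, sigma_C^2)
  over the reward mean.
* **Cued** (`CuedContextModel`): the context has a zero-mean prior and is
  signalled by a noisy cue O ~ N(C, sigma_O^2) before the reward. Inference
  is sequential — P(C|O), then P(C|O,R) — because contextual information
  arrives before the reward; the incentive value is the mean shift of the
  second step. All link functions are identity.
* **Hierarchical** (`HierarchicalContextModel`): two nested context levels
  (HC above LC, e.g. deck-set above deck), each with its own cue (HO, LO),
  rewards drawn around LC. The chain is evaluated in the stated order
  P(HC|HO) -> P(LC|HO) -> P(LC|HO,LO) -> P(LC|HO,LO,R). Because every step
  is linear-Gaussian, the value collapses to the affine form

      V(R) = K * (R - tau_LO * LO - tau_HO * HO)

  with closed-form weights derived here from the chain:

      tau_LO = v1 / (v1 + sigma_LO^2)
      tau_HO = (1 - tau_LO) * sigma_HC^2 / (sigma_HC^2 + sigma_HO^2)
      K      = v2 / (v2 + sigma_R^2),   v2 = v1 * (1 - tau_LO)

  where v1 is the predictive variance over LC after the high cue
  (posterior HC variance plus sigma_LC^2). The equality of the affine form
  and the sequential chain is enforced as a tested invariant (tolerance
  1e-10 over randomized models), and both are checked against a brute-force
  quadrature oracle; the weights also satisfy the limiting behaviour
  expected on first principles (a perfectly observed low-level context is a
  Markov blanket for reward, so tau_HO -> 0 as sigma_LO^2 -> 0, and an
  uninformative high cue carries no weight). Sequential updating in the
  stated order is what is implemented; the scheme is order-sensitive in
  general and no claim of order-invariance is made.

Degenerate beliefs (perfect or absent information) are expressed by taking
limits with small or large finite variances (e.g. 1e-12, 1e12), never by
literal zero or infinite variances; the dataclasses reject non-positive
variances outright.

### Numerical oracle

The quadrature oracle (`tests/oracles.py`) integrates the generative-model
densities on a fixed grid spanning the relevant anchors plus/minus 10
standard deviations with 2001 points per dimension (trapezoidal rule; for
Gaussian integrands at this resolution the truncation and discretization
errors are far below the 1e-6 relative tolerance used in the checks). The
hierarchical posterior is obtained by integrating the high-level context
out of the two-dimensional joint.

## Task designs and the synthetic cohort

`bcv.synthetic` generates the two designs exactly at their printed
dimensions:

* **Variance task (exp1)**: 480 trials in eight blocks alternating between
  a low-variance context (40 trials over option EVs {3, 4} pounds) and a
  high-variance context (80 trials over {2, 3, 4, 5}), each EV equally
  frequent within its block, so the common EVs (3, 4) occur 80 times per
  context and both contexts share the mean EV of 3.5 pounds. The block
  order (LV-first / HV-first) is counterbalanced across simulated subjects.
  "Pseudo-random" trial order is implemented as a seeded balanced shuffle
  with runs of at most four identical EVs.
* **Deck task (exp2)**: 480 trials in 24 deck-set blocks of 20 trials
  (12 low-value: 5- and 7-pound decks; 12 high-value: 7- and 9-pound decks;
  run length at most two in the block order). Each deck-set block holds
  four 5-trial deck blocks with the member decks alternating (ABAB/BABA by
  seed), giving each deck equal exposure. Card amounts are dealt from
  per-deck session pools balanced over the deck's three values (uniform
  composition is an assumption; the printed design states the values, not
  their frequencies). chi_LO and chi_HO columns carry the deck and deck-set
  mean option EVs ({2.5, 3.5, 4.5} and {3, 4}).

Simulated subjects draw choices from the logistic rule below; a chosen
gamble pays the full amount or zero with equal probability, the sure option
pays half. Reaction times are a constant 1000 ms — simulated data are never
RT-filtered; the 400 ms–3 s window (`bcv.analysis.rt_filter`, boundary
values retained) exists for imported real data.

Cohort heterogeneity (`ParamDist`, truncated normals within the fitting
bounds): alpha ~ N(0, 1.5), rho ~ N(0, 1.5), log tau ~ N(0, 0.5),
tau_LO ~ N(0.3, 0.25), tau_HO ~ N(0.2, 0.25). Zero centres for alpha and
rho reproduce the observed split into subjects who gamble more with larger
vs smaller EVs; the value-scale SDs are chosen so that most subjects remain
stochastic (|z| a few units) rather than deterministic; the small positive
centres for the hierarchical weights match a cohort in which both context
levels exert a subtractive influence. The replication analyses for the
variance task additionally centre log tau at -0.3 (SD 0.3), i.e. a cohort
whose divisive gain is genuinely below one, which is the regime the
interaction analysis is about. What the generator does *not* emulate:
missed responses, reaction-time structure, learning or drift within the
session, and any departure from the logistic choice rule — so passing tests
show internal consistency of the pipeline under the model, not that real
cohorts behave this way.

## Choice models and fitting

The experiment-specific value transforms (`bcv.choice`):

* exp1 subtractive+divisive: V = tau^eps * (R - 3.5), eps = 1 in the
  high-variance context; divisive-only alternative V = tau^eps * R.
* exp2 hierarchical subtractive: V = R - chi_LO tau_LO - chi_HO tau_HO;
  divisive alternative V = R / (1 + chi_LO tau_LO + chi_HO tau_HO) (the
  denominator must stay positive; the fitting objective returns +inf
  outside that region).

Choice: P(gamble) = sigmoid(alpha V + rho). All model code works on option
EVs (half the on-screen amount); the data layer guarantees that scale.
Probabilities are clipped at 1e-12 before logs so saturated parameter
corners keep finite likelihoods.

Named model lattice: `full`, `no_rho`, `no_alpha`, `no_tau` (exp1),
`no_tau_lo`, `no_tau_hi` (exp2), `random`, `alt_divisive`. Inactive
parameters are pinned (tau = 1, others 0). Dropping alpha leaves every
context parameter without influence on choice, so `no_alpha` retains only
rho.

Per-subject MAP estimation (`bcv.fitting`): bounded Nelder–Mead from the
standard starts (0 everywhere, tau = 1) plus jittered restarts (default 5;
deterministic given the config seed and subject id), minimizing the
Bernoulli negative log-likelihood plus zero-mean Gaussian shrinkage priors
on log tau (SD 1) and on tau_LO/tau_HO (SD 0.5). The prior SDs are
package defaults exposed in `FitConfig` — weakly informative shrinkage
against outlier estimates. Convergence tolerance 1e-8 on the objective,
1e-4 on parameters; ties between restarts break toward the earlier start.
The likelihood component at the optimum is stored separately, because all
model-comparison arithmetic is on pure likelihoods.

Model comparison: nested likelihood-ratio tests with
2d = 2 (sum NLL_nested - sum NLL_full) against chi-square with
subjects x extra-parameters degrees of freedom; `compare_models` refits a
subject's full model from the nested estimate whenever the nested
likelihood beats the full one beyond 1e-3 (a local-minimum symptom), and
`nested_lrt` clips residual negative 2d to zero. The equal-complexity
subtractive-vs-divisive comparison uses the heuristic one-degree-of-freedom
chi-square on 2d, flagged as non-standard in the report, one-sided as
printed (a preferred model that fits worse reports p = 1 with a note).
Group-level inference on a parameter is a two-sided one-sample t-test
against zero, on the log scale for tau.

## Behavioural statistics and replication

Per-subject summaries (`bcv.analysis`): for the variance task, gamble rates
per (EV, context) cell restricted to the common EVs, the EV preference
(rate at 4 minus rate at 3, contexts pooled) and the context-by-EV
interaction term; for the deck task, the ML logistic slope of gambling on
option EV (a descriptive statistic, fitted by statsmodels without priors;
constant-choice or separated subjects are flagged and drop out pairwise),
the deck effect (lower- minus higher-value deck on the common card EVs of
each set — {2.5, 3.5} low set, {3.5, 4.5} high set — averaged as cell means
over the two sets) and the deck-set effect (low minus high set on the
shared 7-pound deck). Group statistics correlate each context effect with
the EV preference (Pearson with Spearman alongside, two-sided p-values) and
t-test the interaction and the overall rate against chance.

`replicate_by_simulation` re-simulates each subject's own trial sequence
from their fitted parameters under a chosen model variant (ablated
parameters pinned to inactive values) and averages the group statistics
over replicates (default 100). The ablation logic probes which parameter
carries each group-level pattern: removing alpha abolishes both
context-effect correlations, removing a context weight selectively
abolishes the matching one, and in the deck task removing rho creates a
rate/EV-slope correlation that the full model does not show. In the
variance task the rho ablation is uninformative by construction: with
rho = 0 the common-EV values are exactly symmetric around zero, so every
subject's expected gamble rate is 0.5 regardless of alpha and tau and the
rate/EV-preference correlation is identically zero — the package therefore
tests the bias dissociation in the deck task, where values are strictly
positive and the contrast is well defined.

## Problem sizes and known limitations

The test suite runs recovery on 20 cohorts per experiment at the study
sizes (36 and 32 subjects, 480 trials), replication with 100 replicates,
and LRT calibration with 200 replicates of 4-subject cohorts; the
acceptance script runs the same computations at 5 cohorts / 30 replicates /
100 replicates as its standing problem sizes. Recovery of alpha is
excellent and of rho near-perfect in the variance task; in the deck task
rho and tau_HO recover only moderately (mean correlations about 0.6 and
0.5): chi_LO equals chi_HO +/- 0.5 by design, so the bias trades off
against alpha (chi_LO tau_LO + chi_HO tau_HO) along a shallow likelihood
ridge that 480 Bernoulli trials cannot resolve — a design property worth
knowing before interpreting individual rho estimates in that task. MAP
shrinkage makes the calibrated LRT mildly conservative, which is the
intended direction. The package does not model learning of the generative
model's variances, non-Gaussian rewards, more than two context levels, or
effects of simultaneously presented options.
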