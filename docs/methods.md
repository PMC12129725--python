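# Methods

## Task and model family

The four-armed bandit pays a win token (O^r in {0,1}) and, independently,
a loss token (O^p in {0,-1}) per trial; both probabilities drift as
reflected Gaussian random walks. A session is 240 trials in 4 runs.
Q-values start at zero and are carried across run boundaries within a
session (the runs are contiguous blocks of one session); a
`reset_between_runs` switch exists for sensitivity analysis.

The per-trial order of operations is fixed: decay of all tracked values
(if active) -> choice probabilities from the current state -> likelihood
of the observed choice -> sensitivity-scaled prediction errors for the
chosen cue -> update of the chosen cue. Decay precedes the trial because
the forgetting rule references the previous trial's values.

The operative prediction error is delta = sensitivity * (outcome - Q), and
the update is Q += LR * delta. A consequence worth stating explicitly:
the value update relaxes Q toward the *outcome* at rate LR * sensitivity.
The sensitivity therefore scales the update step, not the asymptotic value
scale, and when LR * sensitivity exceeds ~2 the per-cue value oscillates
divergently, producing saturated, near-deterministic choice sequences.
This shapes several design choices below (simulation conditions for model
recovery, and the identifiability limits documented under
"Known limitations").

### Parameters

| parameter | meaning | range | neutral value when inactive |
|---|---|---|---|
| R, P | reward / punishment sensitivity (PE scaling) | [0, 30] | — |
| alpha, beta | coupled learning rates, LR^r = alpha+beta, LR^p = alpha-beta (Models 1-2) | LRs in [0,1] | beta = 0 |
| alpha_r, alpha_p | independent learning rates (Models 3-5) | [0, 1] | — |
| d | per-trial decay of all values (Models 1, 3) | [0, 1] | 0 |
| xi | uniform lapse mixture in the softmax (Models 1-4) | [0, 1] | 0 |

Coupled models are *fitted* on (LR^r, LR^p) in [0,1]^2 — algebraically
identical to (alpha+beta, alpha-beta) and always admissible — with
alpha = (LR^r+LR^p)/2 and beta = (LR^r-LR^p)/2 derived per draw for
reporting. Because the hierarchical priors are placed on the learning
rates themselves under both parameterizations, Models 1 and 3 (and 2 vs 4)
define the same fitted posterior in this implementation and differ only in
how composites are reported. The sensitivity upper bound of 30 is a
configuration knob; group-level estimates in the literature for this task
sit well inside it.

Numerical details: the softmax is stabilized by max-subtraction and choice
probabilities are floored at 1e-12 before logging; cues are 0-based
internally and 1-4 in all I/O. The likelihood hot path is a
numba-compiled kernel required (and tested) to agree with the pure-numpy
reference implementation to 1e-10.

## Hierarchical model and priors

For each free parameter k, subjects i have unconstrained values
raw_ik = mu_k + sigma_k * z_ik with z ~ N(0,1) (non-centered), mapped to
the admissible range by a probit transform (times the sensitivity bound
for R, P). Priors are convention-based, since the study protocol does not
print them: mu_k ~ Normal(0, 1), sigma_k ~ HalfNormal(1) on the
unconstrained scale.

Constrained-scale population summaries use closed forms: the population
mean of bound*Phi(mu + sigma*Z) is bound*Phi(mu / sqrt(1 + sigma^2)); the
population SD is computed by Gauss-Hermite quadrature (31 nodes).

### Reference sampler (`method="mcmc"`)

A blocked adaptive Metropolis-within-Gibbs sampler:

- all subject blocks are conditionally independent given the
  hyperparameters and are proposed jointly from one batched likelihood
  evaluation, with per-subject Laplace-preconditioned Gaussian proposals
  (scales adapted during warmup toward ~0.3 acceptance);
- hypermeans are updated by exact conjugate Gibbs draws;
- hyper-SDs move by scalar Metropolis on the log scale;
- an interweaved non-centered update moves each (mu_k, log sigma_k) pair
  with the subject z-scores held fixed, which keeps the hyper-SDs mixing
  when the centered steps stall;
- a global translation move shifts all subject raws and the hypermean
  together; its proposal covariance starts from the precision-averaged
  subject Hessians and switches to the empirical hypermean covariance
  during warmup (adaptive-Metropolis style), which is what lets the
  sampler travel along sensitivity/learning-rate likelihood ridges.

Chains are initialized from a multi-start penalized-ML fit (see below)
with Laplace dispersion. `n_chains` independent chains are run; kept
draws are thinned (internal thin of 25 sweeps) to `n_samples` per chain
after a warmup of max(3000, n_warmup) sweeps. Split-R-hat and ESS are
computed on the hyperparameter traces across chains and a fit is flagged
non-converged when max R-hat > 1.05 — expected occasionally at desk scale
for the weakly identified sensitivity/learning-rate directions; the flag
is carried in the results, never silenced.

### Fast path (`method="approx"`)

For screening and multi-replicate simulations: a small EM loop alternates
block penalized maximum likelihood for the subject raws (L-BFGS-B with
batched finite-difference gradients; multi-start, because the
lapse/sensitivity trade-off is multimodal, keeping the per-subject best)
with moment-matched hyperparameters. Subject-level uncertainty is a
Laplace approximation at the per-subject modes, with a saddle-free
eigenvalue repair (|eigenvalue|, floored at the prior precision scale)
because finite differences at sharp modes can flip curvature signs.
Population SDs are deconvolved for estimation noise (subtracting the mean
Laplace variance) so that probit-mapped population means are not dragged
toward mid-range; the hypermean standard error keeps both variance
components. Draws are then generated from these moments (chi-squared
scatter for the SDs). The MCMC path is the reference; the approx path is
used where many fits are needed.

## Model comparison

The pointwise LOO unit is the trial, pooled over the subjects of a group
(a subject-level aggregation is a flag away). PSIS-LOO is computed with
arviz; points whose log-likelihood is constant across draws contribute
that constant directly (their importance weights have zero variance), and
a result is flagged when more than 10% of points have Pareto k > 0.7 —
routine for approx-path draws, which is acceptable for ranking models but
not for absolute ELPD values. The SE of an ELPD difference is
sqrt(n * var(pointwise difference)); the sigma effect is the difference
over its SE, undefined (printed blank) for the best model. Comparison
output is invariant to the order in which models are supplied.

## Group contrasts

Groups are fitted independently, so their draws are exchangeable; the
difference distribution is formed by pairing draws after a seeded shuffle
of each side. The shuffle seed is derived from the seed *and* a
fingerprint of each side's own draws, which makes
`group_difference(A, B)` exactly the negation of `group_difference(B, A)`.
The interval is the shortest (highest-density) interval, and a difference
is called significant when the 95% HDI excludes zero. Contrasts are taken
on the constrained population-mean scale, matching how group-level
estimates are conventionally tabulated.

## Connectivity stage

Pearson correlation networks over parcel time series (task runs may first
be summed elementwise to be comparable with a rest run) are thresholded to
a fixed link density by keeping the strongest *signed* correlations
(`absolute=True` switches to magnitude); the edge count is the nearest
integer to density * n(n-1)/2 — exactly 1611 edges for 180 nodes at 10% —
with ties at the cutoff broken in lexicographic (i, j) order so the graph
is deterministic. Centralities: degree (raw counts), eigenvector (own
power iteration on A + I, tolerance 1e-10, scores normalized to unit
maximum; the identity shift guarantees convergence on bipartite
components), betweenness and load (unnormalized, via networkx), closeness
(classic definition scaled by the reachable fraction on disconnected
graphs). All five are cross-checked against exhaustive path-enumeration
oracles on small graphs in the test suite.

The Bayes-factor Pearson correlation uses the exact sampling density of r
given the population correlation and a symmetric stretched-beta prior of
width kappa (default 1, the common default of Bayesian-correlation
software), integrated by adaptive quadrature; it matches an independent
implementation to ~1e-4 in log BF. The log base of reported log-BFs is
configurable (natural log by default); the base does not affect retention
decisions, which depend on the BF itself. Posterior probabilities assume
equal prior odds, PEP = 1 - P(H1|data), and q-values are cumulative means
of PEPs ranked by ascending PEP, thresholded at 0.01 by default. Cells
with fewer than four complete subject pairs are marked untestable and
excluded from the ranking.

## Synthetic data

The generator's defaults are the study conditions: 240 trials in 4 runs,
reflected random walks with step SD 0.02 in [0.2, 0.8] (values chosen so
outcomes stay stochastic yet learnable; the protocol does not print the
true walk parameters), Bernoulli outcome sampling with independent win and
loss tokens, and two-group cohorts whose default group-level means and SDs
are the published arthritis and control estimates (punishment-sensitivity
gap 4.175). Model-recovery conditions (`MODEL5_RECOVERY`,
`MODEL1_RECOVERY`) use moderate sensitivities with LR * sensitivity <= ~1
— the stable stochastic regime discussed above — because the generating
parameters of the lapse-free model are not published and the saturated
regime is both unrealistic and numerically degenerate. Parcel time series
plant a hub that shares a private signal with each linked parcel (so
linked parcels stay mutually near-independent and the hub uniquely attains
maximal degree); clinical scores are built as
target_r * z(centrality) + sqrt(1 - target_r^2) * noise. Separate named
RNG streams (walks, outcomes, choices, ...) make each component
independently reproducible from one seed.

What the synthetic data do *not* emulate: BOLD haemodynamics, scanner
noise spectra, motion, autocorrelated physiological confounds, missing
clinical data patterns, or reaction-time processes. Passing recovery
tests therefore demonstrates correctness of the estimation machinery
under the model, not robustness to real-data artefacts.

## Problem sizes used in tests and the acceptance script

Recovery and contrast simulations run at 12 subjects per group with the
full 240-trial session; the reference-sampler recovery uses 2 chains of
500 kept draws after 500 warmup draws; multi-replicate checks (5 seeds per
condition) use the approx path; the network screen uses 30 subjects,
40 parcels, 300 volumes, a planted hub and a planted clinical correlation
of 0.6. These sizes were chosen as the smallest at which the pipeline's
qualitative claims are meaningful.

## Known limitations

- **Subject-level punishment sensitivity is weakly identified at the
  published group values.** Because LR * P >> 1 there, behaviour saturates
  and graded information about P is scarce: across many simulated cohorts
  the expected rank correlation between true and recovered subject-level P
  is ~0.35, and population-mean posteriors for the sensitivities at
  12 subjects are wide (coverage is good; precision is poor). Detection
  of the planted between-group punishment-sensitivity gap at 12 + 12
  subjects consequently has power of roughly one half, and the fast path's
  intervals are somewhat anti-conservative under the null because
  per-subject mode flips add non-Gaussian noise that a Laplace standard
  error cannot capture.
- **A planted correlation of 0.6 at n = 30 sits under the default
  Bayes-factor FDR bar at threshold 0.01**: BF10(r = 0.6, n = 30) ≈ 79, so
  its PEP (0.0125) exceeds 0.01 and retention requires a sample
  correlation above ~0.61 — a coin flip per replicate. The screen's hub
  recovery, q-value monotonicity and null-cell control are all robust;
  only the retention of an effect of exactly this size at exactly this
  threshold is borderline by construction.
- The ensemble-of-modes structure induced by the lapse parameter means
  desk-scale MCMC occasionally flags R-hat above 1.05 on the
  sensitivity/learning-rate hyper-SDs; such fits report themselves as
  non-converged rather than hiding it.
- Models 1/3 (and 2/4) are operationally identical fits here (see
  "Parameters"); published analyses that distinguish them must have done
  so through a prior parameterization that is not printed.
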