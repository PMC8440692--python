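# Methods

## Model

The speed–accuracy tradeoff (SAT) function is modelled as an exponential
approach to an asymptote.  Above-chance accuracy at processing time `t`
(seconds) is

    ψ(t; λ, γ, δ) = λ (1 − exp(−γ (t − δ)))   for t > δ,  else 0,

and probability correct is `pc(t) = chance + ψ(t)`.  `λ ∈ (0, 0.5]` is the
asymptotic *above-chance* accuracy (so `chance + λ ≤ 1` in 2AFC), `γ > 0`
the accrual rate in 1/s, and `δ ≥ 0` the intercept in s before which
performance is at chance.  The boundary `t = δ` is assigned to the chance
branch (ψ = 0); ψ is continuous there, so the choice only affects exact
grid-point evaluation.  Keeping ψ as the above-chance component and adding
the chance constant in one place (`TaskSpec.chance`) supports guessing
rates other than 0.5 without touching the model code.

## Virtual observers and simulated trials

A virtual observer couples true SAT parameters with an ex-Gaussian RT
distribution (Normal(μ, σ) + Exponential(τ); defaults μ = 0.3 s, σ = 0.06 s,
τ = 0.08 s, mean 0.38 s).  On a trial at a given SOA, the RT is drawn from
the ex-Gaussian *constrained* to the response window `[soa, soa + 0.2]`;
correctness is Bernoulli with probability `pc(rt)` evaluated at the realized
RT (the conditional accuracy function), not at the SOA.

Constraining is by rejection sampling from the unconstrained ex-Gaussian,
which preserves the conditional shape of the distribution inside the
window.  For long SOAs the window can carry essentially no mass (at
SOA = 1.2 s the default ex-Gaussian puts ~1e−5 of its mass above 1.2 s);
after 1,000 rejected proposals per trial the sampler falls back to a
uniform draw on the window and logs the event.  At such SOAs the SAT curve
is flat at its asymptote, so the fallback's shape mismatch has no material
effect on simulated accuracy.

The four standard observers span the parameter ranges of interest
(λ 0.45–0.495, γ 5–22, δ 0.22–0.36).  Observer 1's γ = 7.5 deliberately
falls between grid points; no grid refinement is performed, so reported
biases include this discretization component.

What the simulator does *not* emulate: lapses, response bias, sequential
dependencies, learning/fatigue, or deviations of real RT distributions from
the ex-Gaussian family.  Passing the validation suite therefore shows the
estimator recovers observers that obey the model; robustness to model
misspecification is a separate question.

## Grid-based Bayesian estimation

The posterior lives on a fixed product grid: 21 linear λ values on
[0.4, 0.5], 30 linear γ values on [1, 30], 25 linear δ values on
[0.02, 0.5] (15,750 points), with a uniform prior.  Each trial multiplies
in a Bernoulli likelihood (`pc(rt)` or `1 − pc(rt)`, clipped to
(1e−12, 1−1e−12)) and renormalizes.  Because every factor lies in (0, 1)
and the mass is renormalized after each trial, the sequential update equals
the joint-product update to better than 1e−10 (tested); no log-space
accumulation is needed.

Point estimates are marginal posterior means.  Precision per parameter is
the half-width of the shortest credible interval (HWCI) at level 0.682 on
the discrete marginal: the narrowest contiguous run of grid points whose
cumulative mass reaches the level, ties broken toward smaller width then
smaller lower bound.  On the uniform prior this gives λ: 0.035, γ: 10.0,
δ: 0.17 (ceil(0.682·n) grid points per axis).

The estimated SAT function is reconstructed by resampling: 1,000 parameter
triples drawn with replacement proportionally to posterior mass, each curve
evaluated at the evaluation times, then averaged; the per-time spread is
the shortest-interval half-width of the resampled values.  The exact
posterior-mixture curve (the n → ∞ limit of the resampling mean) is also
available and is used as its oracle in tests.

## Adaptive SOA selection

The response-signal paradigm changes SOA per block of n trials (default 16),
so selection is a multiple-step-ahead search: the outcome of the next block
at candidate SOA x is modelled as a binomial count of k correct out of n
with success probability `pc_θ(X)` at the *expected* RT `X = x + window/2`
(the window midpoint).  The selected SOA maximizes the mutual information

    I(R; Θ) = H(Σ_θ p(θ) Binom(k; n, pc_θ)) − Σ_θ p(θ) H(Binom(k; n, pc_θ))

over the 49-point stimulus space on [0, 1.2] s.  Entropies are in nats
(the base only rescales the argmax), `0·log 0 := 0`, and argmax ties break
toward the smallest SOA so selection is deterministic given the posterior.
With n = 1 this reduces to the standard one-step-ahead Bernoulli
information gain (tested against a direct two-outcome computation).

Within a block, the posterior is updated trial-by-trial on the realized
(rt, correct) pairs; the binomial model is used only to *predict* gain at
block start.  A block-granularity variant (one binomial update per block at
the expected RT) is available via `update_granularity="block"`.

Implementation note: the binomial outcome tensor over (SOA, k, θ) and the
per-θ conditional entropies depend only on grid, task, stimulus space and
block design, so `InformationGainPlanner` precomputes them once; each
selection is then a single matrix–vector product against the posterior
(~7 ms on the default grid) and replications share one planner.

## The four estimation procedures

All four consume the same trial schema and emit the same checkpointed
trajectory structure.

1. **MCS + binned MLE.**  The 8 SOA levels (0.06–1.20 s) are presented as
   16-trial blocks, each round presenting every level once in random order
   (so accumulated data stay balanced across conditions; a long-block mode
   with one 256-trial block per level is available via `mcs_mode="long"`).
   At each checkpoint the accumulated trials are averaged per SOA (mean RT,
   correct count) and the model fitted by maximizing the binomial
   likelihood at the per-SOA mean RTs.
2. **MCS + trial-wise MLE.**  Same data; the fit maximizes the product of
   per-trial Bernoulli likelihoods at realized RTs.
3. **MCS + Bayesian.**  Same data; per-trial grid updates, marginal-mean
   estimates and HWCIs recorded online.
4. **Adaptive Bayesian.**  Selection–simulation–update loop as above;
   records the selection trace, expected gain, and realized per-block
   entropy reduction.

MLE fits use L-BFGS-B with bounds equal to the Bayesian grid ranges
(λ ∈ [0.4, 0.5], γ ∈ [1, 30], δ ∈ [0.02, 0.5]) for comparability, with 8
Latin-hypercube starting points; the best of the converged restarts is
kept.  `pc` is clipped to (1e−10, 1−1e−10) inside the likelihood.  A
least-squares objective (sum of squared accuracy residuals) is available as
`fit_method="lse"`.  Checkpoints with fewer than 3 distinct time points
cannot identify 3 parameters and are recorded as missing; aggregate metrics
use the replications with valid fits and record the count.  Default
checkpoints are powers of two up to the run length plus the 100-trial
probe.

For matched generator states, Procedures 1–3 simulate byte-identical MCS
datasets (data are generated before any fitting), so procedure comparisons
are paired.

## Evaluation metrics

Over J replications and K = 8 evaluation times (0.06, 0.09, 0.12, 0.24,
0.36, 0.48, 0.60, 1.20 s, evaluated directly, not shifted by the window):

* **Parameter bias** — mean |estimate − truth| over replications.
* **Function average absolute bias** — per time point, |mean over
  replications of the signed error|, averaged over time points.  Signed
  errors may cancel across replications; the stricter per-cell
  mean-absolute-error is reported alongside (`function_mae`), and the two
  satisfy `bias ≤ mae` (triangle inequality, tested).
* **Function SD (precision)** — per-time SD of estimated-curve values
  across replications, averaged over time points.  A pooled RMS variant
  over all (replication, time) cells is reported alongside
  (`function_sd_pooled`); the two differ materially here because time
  points below the intercept have near-zero variance, and the averaged
  form is the one whose trials-to-precision crossings line up with the
  procedure comparisons this package reproduces.
* **Trials-to-precision** — the interpolated *downward* crossing of the SD
  trajectory below the threshold (default 0.020): Bayesian trajectories
  start with near-zero spread (every replication shares the same prior)
  and rise before falling, so the crossing is taken after the last
  checkpoint above threshold; for monotone-decreasing trajectories this
  coincides with the first crossing.  A trajectory that never exceeds the
  threshold reports its first checkpoint; one that ends above it reports
  "not reached" (∞).

## Problem sizes and reproducibility

The validation suite and `scripts/acceptance.py` run 200 replications per
condition (the original study used 10,000), which puts ~3-standard-error
uncertainty bands of a few percent around the replication means; the
trials-to-precision crossings additionally carry interpolation uncertainty
estimated by bootstrap over replications.  Run lengths are trimmed to what
each quantity needs (e.g. 128 trials for the 100-trial checkpoint, 768 for
the conventional procedure's precision crossing).  Every source of
randomness derives from a master seed through
`SeedSequence([master_seed, observer_id, procedure_id, replication])`, so
all outputs are bit-reproducible.

## Known limitations

* The grid bounds act as a strong prior: observers outside λ ∈ [0.4, 0.5]
  or γ ∈ [1, 30] cannot be represented, and estimates for parameters near a
  grid edge (e.g. λ = 0.495) are pulled inward.
* The expected-RT-at-midpoint assumption biases selection slightly at short
  SOAs (where true expected RT exceeds the midpoint) and long SOAs (where
  it falls below).
* Selection is myopic (one block ahead); no deeper lookahead is attempted.
* The MLE procedures can sit on bound constraints for small samples; such
  fits are kept (they are what the conventional analysis would report) but
  flagged through the convergence field.
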