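# Methods

## The learning model

Saccade amplitude is recalibrated from trial to trial by visual feedback
errors. We model the internal calibration state in *adaptation-gain*
coordinates: for a pre-saccadic target step `preTP` (8 dva throughout) and a
sinusoidal intra-saccadic step (ISS) of amplitude `P` (2 dva), the
adaptation gain of a saccade of amplitude `SA` is `g = (SA − preTP)/P`; 0
means perfect landing, 1 means an error of one full ISS amplitude. The
stimulus gain `s(n)` is the ISS normalized to ±1; on adaptation trials
`s(n) = sin(2πf·n/N)` with `f` integer cycles per block (cpb) and `N` the
block length, restarting at phase zero at each adaptation block; in
non-adaptation blocks `s = 0`.

The hidden state follows a noise-free linear time-invariant recursion:

    x(n+1) = A·x(n) + K·(s(n) − x(n)) + m + D·(s(n−1) − x(n−1))

with learning rate `K` (fraction of the last prediction error corrected per
trial), persistence rate `A` (fraction of the state retained; fixed at 1
when not estimated), drift `m` (non-error-based bias per trial, gain
units), distal learning rate `D` on the next-to-last error, and initial
condition `G`. Freeing any subset of {A, m, D, G} with K always present
gives 16 models in four groups: I (no m, no D), II (m only), III (D only),
IV (m and D). Sequence bootstrap: `s(0) = 0` and `x(0) = x(1)`, which makes
the first update identical to the single-error model; the choice decays
within a few trials. When `G` is not free it is fixed to the mean of the
first five observed gains; when free, that mean seeds the optimizer.

## Closed-form phenomenology

Under sinusoidal drive the steady state is a lagged sinusoid on a constant
baseline. Writing the transfer function of the recursion at `z = e^{iω}`:

* denominator magnitude `R` and bare lag `ϕ`:
  `R·e^{iϕ} = [cos ω − (A − K − D cos ω)] + i(1 − D) sin ω`
* numerator magnitude `Q` and extra lag `φ`:
  `Q·e^{−iφ} = (K + D cos ω) − i D sin ω`
* amplitude `a = Q/R` (reducing to `K/R` at `D = 0`, where `φ = 0`);
  the observable lag is `ϕ + φ`, reported in radians and in trials
  (`lag/ω`).
* baseline asymptote `B0 = m / (1 − (A − (K + D)))`; decay modes are the
  roots of `r² − (A−K)r + D = 0` (`e^{−λ} = root`). The dominant timescale
  is `−ln` of the largest-magnitude root; when the discriminant is
  negative the modes are complex and flagged oscillatory rather than
  raised (the real case is the physically relevant one for fitted
  parameters). For fixed `A − K`, a negative `D` moves the dominant root
  toward 1: double-error models decay their baseline with *smaller* λ,
  i.e. longer integration windows.

The printed forms `a = K/R`, `a = Q/R` are ratios; the whole block is
pinned against an independent oracle — least-squares sinusoid regression
on the post-transient half of 8000-trial noise-free simulations, and
steady-state/log-slope extraction from 10000-trial zero-stimulus runs —
with relative agreement better than 1e-4 across a grid of stable
(K, A, D) × frequency combinations (unstable combinations, identified by
the companion-matrix criterion, are excluded; large negative `D` with
`A − K` near 1 is genuinely unstable).

The exact two-learner rewriting uses `X± = (x(n) ± x(n−1))/2` driven by the
half-sum/half-difference stimulus channels with rates `κ = K + D` (slow)
and `η = K − D` (fast); reconstruction `x = X₊ + X₋` holds to machine
precision.

## Phenomenological fitting and evidence

The descriptive model is `g(n) = a·sin(ωn̂ − ϕ) + B·e^{−λn} + B0` with
`ω = 2πν/N`; the sinusoid starts at adaptation onset (its argument `n̂`
counts from the onset) while the exponential and asymptote span the whole
fitted segment, which includes the pre-adaptation block. Fitting is
Bayesian: Gaussian likelihood, noise scale σ integrated out under a
Jeffreys 1/σ prior, leaving a posterior ∝ RSS(θ)^(−n/2).

Numerical scheme: the sinusoid is parameterized by in-phase/quadrature
components (α, β), making the model linear in (α, β, B, B0). Those four
coordinates (and σ) are marginalized in closed form at every node of a
(ν, λ) grid (defaults: ν ∈ [0.5, 30] cpb step 0.1; λ ∈ [0.002, 0.5] step
0.02 — the lower λ bound keeps the decay column distinguishable from the
constant); the remaining two-dimensional integral is a trapezoid sum.
This grid handles the multimodal ν posterior without any mode-hopping
heuristics and makes marginal likelihoods exactly additive across the
nested chain full → drift-only (a = 0) → noise-only (block mean with
matched variance). Evidence is reported as `10·log10` of the
marginal-likelihood odds (decibels), with 3 db the conventional
significance threshold; it is antisymmetric and invariant under common
rescaling of the data and the amplitude priors.

Priors are uniform: α, β, B, B0 on [−2, 2] each, ν on [0.5, 30] cpb, λ on
[0.002, 0.5] per trial; all configurable. Placing the amplitude prior on
(α, β) rather than (amplitude, lag) keeps the marginalization analytic;
the induced amplitude coverage is the same.

Point estimates are the posterior mode — located by the grid scan and
polished by bounded least squares — which for the concentrated posteriors
at these trial counts (hundreds of trials per segment) coincides with the
posterior mean well within the reported sd, and is exact in the noise-free
limit. Marginal means and variances per parameter come from the grid
mixture (law of total variance, conditional multivariate-t for the linear
block; delta method for amplitude and lag).

Population pooling averages per-participant posterior means with inverse-
variance weights (1/sd²). A literal "weighted by their standard
deviations" would up-weight the noisiest estimates; inverse variance is
the standard precision weighting.

## Generative-model fitting and selection

Each of the 16 models is fit by nonlinear least squares between the
observed gains and the pure forward simulation driven by `s(n)` — no
teacher forcing. The optimizer is Levenberg–Marquardt with an analytic
Jacobian from forward sensitivity recursions, and 8 Latin-hypercube starts
over K ∈ [0.001, 0.3], A ∈ [0.9, 1.0], m ∈ [−0.02, 0.02], D ∈ [−0.3, 0.05],
G ∈ first-five mean ± 0.5 (multimodality is real when D is free). No
bounds are enforced at the solution. Diverging trajectories are clamped at
±1e6 and flagged, so unstable proposals are penalized rather than fatal.

95% confidence intervals are Jacobian-linearization intervals,
`θ̂ ± t(0.975, n−k)·se` with `se² = σ̂²[(JᵀJ)⁻¹]ᵢᵢ`; a rank-deficient
Jacobian marks the parameter unidentifiable (NaN interval). Models are
ranked per participant by Akaike weights from `AIC = n·ln(RSS/n) + 2k`
with `k` = free parameters + 1 (the noise scale; the +1 cancels in AIC
differences but keeps the count interpretable). AICc is available behind
a flag. Weights are averaged across participants per condition; group
support sums member-model weights; ties in best-model identification go
to fewer free parameters, then lexicographic name.

## Synthetic cohorts

Observers are generated as `g(n) = x(n) + ε(n)` with i.i.d. Gaussian ε;
the latent learner itself stays noise-free. Defaults: σ = 0.08 for Two-way
adaptation and σ = 0.15 for Global, reflecting the higher measurement
variability of random-direction saccades; recovery and selection
experiments in the tests use σ = 0.1. Two-way vs Global differ only by
the learning-rate jitter ranges (K ∈ [0.01, 0.035] vs [0.005, 0.015] for
single-error truths) and σ — saccade direction itself is not simulated.
The FREQ session is 2370 trials in 11 alternating blocks (6 × 75
non-adaptation, 5 × 384 adaptation at 1/3/6/12/24 cpb); the ORIG-style
session is built as one 75-trial pre block plus one 384-trial adaptation
block per frequency (3/4/6 cpb), the per-condition unit on which all fits
run. Cohort sizes follow the two designs: 13 and 10 participants.

For truth models without a free G the generator sets the initial state to
the unique value whose noise-free first-five-trial mean equals itself
(solved in closed form; the map is affine in G). This makes the generating
convention identical to the estimation convention, so noise-free recovery
is exact; with noise the adjustment is negligible relative to σ.

Seeding: a master seed spawns one child seed per participant (for the
parameter jitter) and one per observer session via `SeedSequence.spawn`,
participant-major; cohorts are byte-reproducible and extensible.

What the synthetic data do not emulate: trial-to-trial motor-noise
propagation into the state, saccade kinematics and latencies, slight
trial-to-trial variation of the pre-saccadic step, direction-specific
adaptation fields. Passing recovery tests therefore demonstrates that the
estimation chain is correct and calibrated under its own assumptions, not
that those assumptions hold for human data.

## Problem sizes used in the validation suite

Analytic-oracle grid: 24 stable (K, A, D) combinations × 5 frequencies
(8000-trial periodic runs; 10000-trial baseline runs). Recovery: 20
cohorts × 13 observers at σ = 0.1 (and one noise-free cohort). Selection:
20 cohorts × 13 observers × 3 frequencies × 16 models per truth scenario.
Evidence: 100 replicates of a 384-trial block. The acceptance script
reruns the same analyses at reduced Monte-Carlo counts (10 recovery
cohorts, 5 selection cohorts, 50 evidence replicates) chosen to keep a
single-CPU rerun short while leaving the estimated rates stable.

## Known limitations

* The marginal-likelihood grid trapezoid is a quadrature, not an exact
  integral; resolution defaults are adequate for 384-trial blocks (the ν
  peak width is about 1 cpb) but should be refined for much longer blocks.
* Laplace-free grid evidence covers only the three nested phenomenological
  models; the 16 generative models are compared by AIC, not evidence.
* Linearization CIs undercover when a parameter sits near a boundary of
  identifiability (e.g. D in weakly-informative conditions); coverage is
  verified by simulation only for the conditions exercised in the tests.
* At 1 cpb the stimulus is barely periodic; closed-form lag predictions
  are exact for the model but describe data poorly there, as expected.
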