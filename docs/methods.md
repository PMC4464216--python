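# Methods

## The model

A single mRNA molecule is modeled as a continuous-time Markov chain over a
small set of biochemical states with one absorbing "degraded" state. All
transitions are first-order with rates in min⁻¹. Every network used here is a
*star*: a central initial state 0 (the free message), an optional direct
degradation edge 0 → sink with rate µ, and independent one-hop branches — an
alternative, miRNA-independent pathway 0 → 1 (rate λ) with degradation
1 → sink (rate ν), and, depending on which silencing factors a cell line
expresses, a miRISC branch 0 → 2 (rate λ_X) with degradation 2 → sink
(rate µ_X), where X labels the complex that binds the message:

| network            | condition emulated     | branch rates        |
|--------------------|------------------------|---------------------|
| single_exponential | null model             | µ only              |
| control_negative   | no miRNA               | λ, µ, ν             |
| mirisc_only        | PAN3 & NOT1 knocked down (also used for NOT1 KD) | + λ_R, µ_R |
| pan3_kd            | PAN3 knocked down      | + λ_RN, µ_RN        |
| control_positive   | all factors expressed  | + λ_RNP, µ_RNP      |

What an experiment measures is the population-average fraction of mRNA
remaining after transcription shut-off. For a single molecule this is the
first-passage survival function S(t) = P(not yet degraded at age t), computed
from the transient-block generator Q as S(t) = p₀ᵀ e^{Qt} 𝟙. For star
topologies there is a closed form, re-derived here from the two-exponential
structure of the chain: with total initial exit rate R = µ + Σᵢ λᵢ,

    S(t) = e^{−Rt} + Σᵢ [λᵢ/(R − νᵢ)] (e^{−νᵢ t} − e^{−Rt}),

with the degenerate branch R = νᵢ handled by its limit λᵢ t e^{−Rt}. The
closed form is used as the fast path in fitting and is continuously
cross-checked against the matrix exponential (agreement demanded to 1e−10);
the matrix-exponential route supports arbitrary acyclic topologies.

Derived single-molecule quantities:

* hazard (age-dependent degradation rate) h(t) = −d ln S/dt, computed as
  degradation flux over surviving mass, Σᵢ aᵢ pᵢ(t) / S(t) with aᵢ the
  per-state sink rates. Note h(0) equals the *sink* rate of the initial
  state (µ), not its total exit rate: transitions into branch states move
  mass but degrade nothing. As t → ∞, h(t) tends to the smallest excited
  decay eigenvalue; when S(t) underflows, that limit is reported with a
  warning.
* mean lifetime p₀ᵀ(−Q)⁻¹𝟙, equal to ∫S dt; for the star topology
  1/R + Σᵢ (λᵢ/R)(1/νᵢ).
* branching fractions: the probability of degrading through each exit route,
  from the fundamental matrix ((−Q)⁻¹ weighted by sink rates); on the star
  this reduces to σ_X = λ_X/(λ_X + λ + µ).
* steady-state occupancy: under constant zeroth-order production into state 0
  with the network's first-order losses, the occupancy solves the flux
  balance N = P(−Qᵀ)⁻¹e₀; fractions are independent of P. Constant
  production into the free state is a declared assumption — it is the
  simplest model consistent with a steady expression level.

## Fitting

Fits minimize equally weighted least squares of log₁₀ S(t) against log₁₀
observed relative abundance. The fit scale is a declared choice: decay
patterns are conventionally read in linear-log scale, where exponential
phases are straight lines and the late, slow phase retains leverage.
Replicates enter as independent observations by default (averaging is
available as an option).

The optimizer is SciPy's trust-region reflective least squares with all
rates bounded below by 0, multi-started from five log-spaced initial guesses
spanning 10⁻⁴–10⁻¹ min⁻¹ (all free rates set equal per start); the start
with the lowest RSS wins, ties going to the smaller parameter norm.
Convergence tolerances are 1e−14 so that noiseless round trips recover
rates to well beyond three significant figures. Estimates below 10⁻¹² are
snapped to exactly 0 and flagged as boundary estimates; free rates whose
Jacobian column vanishes at the optimum are flagged unidentifiable (e.g. a
branch exit rate when the branch entry is estimated at 0).

The hierarchical strategy mirrors the experimental design: stage 1 fits
(λ, µ, ν) to the negative control; stage 2 freezes those three values and
fits exactly the two branch rates (λ_X, µ_X) of each remaining condition on
its own topology. Stage-2 results record the inherited baseline.

### Confidence intervals

Two methods are offered, both declared substitutes for the unpublished
original procedure:

* *asymptotic*: Wald intervals from the linearized Jacobian,
  estimate ± 1.96·SE with SE² from s²(JᵀJ)⁻¹, truncated at 0; falls back to
  the bootstrap (with a warning) if JᵀJ is numerically singular.
* *parametric bootstrap* (default, n_boot = 1000): residual SD s is
  estimated from RSS/(n−k); synthetic log₁₀ datasets are drawn as fitted
  values + N(0, s) noise and refit from the point estimate; intervals are
  the 2.5/97.5 percentiles. Because every measured replicate is normalized
  to 1 at its reference time, each bootstrap replicate is renormalized the
  same way (equivalently, the reference draw is subtracted from its
  replicate). This preserves the within-replicate error correlation that
  normalization induces; without it the intervals measurably undercover
  the well-identified rates. Calibration under the default noise model is
  verified by simulation (coverage ≈ 0.95–0.98 per rate at 100 replicates).

Intervals are widened, if necessary, to contain the point estimate, and
lower bounds below 10⁻¹² are reported as exactly 0.

### Model selection

Least-squares AIC, n·ln(RSS/n) + 2k, with AICc behind a flag (the
small-sample form is a convenience, not part of the original analysis).
Comparisons are only allowed between fits of the identical dataset (checked
by hashing the observations).

## The synthetic experiment

The generator emulates the five-condition knockdown design: per-condition
decay curves from the exact survival function (or, optionally, from
empirical Gillespie survival of n molecules), three replicates with
multiplicative lognormal measurement noise — each value multiplied by
10^ε, ε ~ N(0, σ_log) — and per-replicate renormalization to 1 at t = 0.
Defaults, fixed once:

* time grid 0–480 min in 30-min steps (17 points) — spans several initial
  lifetimes and resolves the slow tail at rate ν ≈ 0.003 min⁻¹; the source
  experiment's exact grid is not published alongside the rates.
* σ_log = 0.05 decades (≈ 12% multiplicative scatter) — chosen as typical
  replicate scatter for reporter decay assays; the real noise magnitude is
  unpublished. Exposed as a parameter.
* three replicates, matching the experimental design.
* the NOT1-KD condition is generated from the miRISC-only network: PAN3
  without NOT1 adds no identifiable destabilization, so no separate network
  exists for it.

What the generator does *not* emulate: transcription shut-off transients,
cell-to-cell variability, absolute copy numbers, figure-extraction error,
or non-lognormal/heteroscedastic measurement error. Passing tests therefore
demonstrate correctness of the machinery and calibration under the declared
noise model, not robustness to arbitrary real-data pathologies.

Exact stochastic simulation draws exponential waiting times with each
state's total exit rate and picks the next state proportionally to rates;
a vectorized variant processes all molecules per state in bulk. All
randomness flows through explicit `numpy.random.Generator` seeds; identical
seeds give bit-identical datasets.

## Numerical choices

* Degenerate closed-form branch: the limit term is used when
  |R − νᵢ| < 10⁻⁹·max(R, νᵢ), avoiding catastrophic cancellation.
* Survival values are clipped to [0, 1] against roundoff, and floored at
  10⁻³⁰⁰ before taking log₁₀ in the fit objective.
* Observations are sorted into a canonical (time, replicate) order before
  fitting, so permuting input rows cannot change estimates at all.
* Empirical survival curves floor at 0.5/n so values stay positive on the
  log fit scale.
* Problem sizes in the test suite and acceptance checks: 10⁵ molecules for
  survival-convergence and branching-frequency checks (3 binomial SEs),
  5 × 10⁴ trajectories for the exit-frequency reproduction, 20 seeded
  replicates for the AIC preference check, 100 replicates × 199 bootstrap
  draws for interval-coverage calibration.

## Known inconsistencies and limitations

* With the *rounded* published point estimates (λ_RN = 0.046, λ = 0.0008,
  µ = 0.0276), σ_RN evaluates to 0.618, not the printed "~0.64"; the
  original computation presumably used unrounded fits. The package always
  recomputes σ from the rates it is given and never hard-codes the printed
  values; the ~0.64 figure is documented here, not reproduced.
* The printed steady-state occupancy narrative ("state 1 decreases by
  almost 20% of the total, state 0 by only 5%") does not follow from the
  declared constant-production flux balance with the published rates, which
  instead gives shifts of roughly −7 and −21 percentage points for states 1
  and 0. A different normalization or state labeling may underlie the
  original figure; the flux-balance model here is the declared one and its
  outputs are reported as computed.
* Cycles back to the initial state, reversible miRISC binding, and
  time-dependent rates are out of scope; the reversible-binding variant is
  an open extension the data cannot distinguish from the present model.
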