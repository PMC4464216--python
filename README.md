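# mirdecay

Single-molecule Markov modeling of miRNA-mediated mRNA degradation.

## The problem

Knockdown experiments measure *decay patterns* — the population-average
fraction of a target mRNA remaining after transcription shut-off — under
different combinations of silencing factors (the miRISC complex and the
deadenylation scaffolds NOT1 and PAN3). The biological question lives at the
single-molecule level: through which network of biochemical states does one
message travel before it is degraded? The two are linked by first-passage
theory: if state transitions are first-order, the decay pattern equals the
survival function S(t) of an absorbing continuous-time Markov chain, and a
biphasic decay curve already implies at least two states from which
degradation can occur.

`mirdecay` implements that link end to end for star-shaped degradation
networks: a free message (state 0) that either degrades directly (rate µ),
enters a competing miRNA-independent pathway (state 1; rates λ in, ν out),
or is captured by a miRISC-containing complex X (state 2; rates λ_X in,
µ_X out). For total initial exit rate R = µ + Σλᵢ,

    S(t) = e^(−Rt) + Σᵢ λᵢ/(R−νᵢ) · (e^(−νᵢt) − e^(−Rt)),

and the fraction of messages silenced through the miRISC branch is the
branching fraction σ_X = λ_X/(λ_X + λ + µ). Decay curves for five knockdown
conditions are fitted hierarchically — the baseline rates (λ, µ, ν) come
from the negative control and are frozen while each condition's two branch
rates are estimated — with bootstrap confidence intervals and AIC model
comparison. A Gillespie simulator and a replicate-noise model generate
synthetic experiments so the whole pipeline is testable without any
external data. It is intended for researchers modeling mRNA turnover
kinetics from decay time courses.

## Worked example

Generate the five-condition synthetic experiment and run the analysis
scripts (equivalently: `mirdecay report --run results/run --seed 1`):

```sh
python analysis/01_simulate_experiment.py
python analysis/02_hierarchical_fit.py
python analysis/03_derived_quantities.py
python analysis/04_model_selection.py
```

Stage 1 of the hierarchical fit recovers the baseline rates from the noisy
negative control, and stage 2 the branch rates of the all-factors condition
(output of `02_hierarchical_fit.py`, seed 1):

```
fit[control_negative] network=control_negative n=51 k=3
  lambda = 0.0006935 min^-1  95% CI [0.0005667, 0.0008446]
  mu = 0.02777 min^-1  95% CI [0.02613, 0.02995]
  nu = 0.00241 min^-1  95% CI [0.001897, 0.002894]
  ...
fit[control_positive] network=control_positive n=51 k=2
  lambda_RNP = 0.148 min^-1  95% CI [0.1252, 0.1788]
  mu_RNP = 0.04884 min^-1  95% CI [0.04676, 0.0511]
  lambda = 0.0006935 min^-1 (fixed)
  ...
```

The generating truth was λ = 0.0008, µ = 0.0276, ν = 0.0028,
λ_RNP = 0.1501, µ_RNP = 0.0493 min⁻¹ — every estimate's 95% interval covers
it. From the fitted rates, `03_derived_quantities.py` recomputes the
headline biology:

```
fraction of mRNA degraded through the miRISC branch, per condition:
       condition          network  sigma_mirisc  percent
control_positive control_positive         0.839       84
         pan3_kd          pan3_kd         0.590       59
    pan3_not1_kd      mirisc_only         0.096       10
```

With miRISC alone (~10% here; 7% at the exact reference rates) almost no
mRNA is silenced through the miRNA route — the original, sequential
recruitment hypothesis cannot explain strong miRNA regulation — whereas the
preformed miRISC+NOT1+PAN3 complex captures ~84% of all messages. The
steady-state occupancy shift shows PAN3's role is recruitment, not faster
degradation: expressing PAN3 moves ~29 percentage points of steady-state
mRNA into the miRISC-bound state. Finally `04_model_selection.py` confirms
the decay patterns are genuinely biphasic: the two-state model beats a
single exponential by ΔAIC ≈ 223 on the negative control.

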