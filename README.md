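# vamalign

Version alignment for grouped longitudinal survey data.

## The problem

Longitudinal surveys often record a continuous quantity — weekly duration of
leisure-time physical activity, income, exposure time — through a
multiple-choice item whose options are numeric intervals, with an open-ended
top option (`[a, ∞)`).  When the option grid is revised between waves, the
pattern of information loss changes and every downstream estimate shifts: in
the motivating panel the estimated annual mean jumps by ~0.6 h/week across
the revision year while neighbouring years differ by at most ~0.13.  Simply
discarding one version's data biases the analysis; analysing them jointly
without adjustment confounds real change with the instrument change.

`vamalign` is for epidemiologists and survey methodologists who need to
analyse such panels across a revision.  It estimates the revision-related
transition matrix from a *cohort* (respondents observed in both the last
pre-revision and first post-revision wave), separates it from genuine
time-related change, and re-expresses all responses on one questionnaire
version before estimating means.

## Method

Responses on a `d`-option interval scale aggregate to a probability vector
`p`; change between waves is a column-stochastic transition matrix `T`,
countable directly from cohort pairs.  With a revision between `t1` and
`t2`, `T` factors as `T = B·A`: first the revision re-binning `A`
(`d2 × d1`), then time change `B` (`d2 × d2`).  The factors are recovered by
minimizing weighted slack variables

```
min  θ₁γ + θ₂ε + θ₃β + θ₄α
s.t. A, B column-stochastic,  |BA − T|∞ ≤ γ,  |BAu − v′|∞ ≤ ε,
     |B − B_ref|∞ ≤ β,        |A − G|∞ ≤ α,       θ₁ = θ₂ > θ₃ > θ₄ > 0
```

where `u, v′` are the cohort's response distributions at the two waves,
`B_ref` a revision-free time matrix from a later year, and `G` the *ideal
revision matrix* `G[i,j] = Φ(I2ᵢ ∩ I1ⱼ)/Φ(I1ⱼ)` under a latent distribution
(default Gamma) fitted to the cohort's pre-revision responses by grouped
maximum likelihood.  The bilinear product constraint is handled by
alternating linear programs.  The aligned population vector `z = Â·y` then
feeds either estimator of the mean:

* **midpoint method** — interval midpoints (lower bound for the top-coded
  option) weighted by relative frequencies;
* **grouped MLE** — multinomial likelihood with Gamma CDF-difference cell
  probabilities, mean = shape × scale.

See `docs/methods.md` for assumptions, tuning and limitations.

## Worked example

Simulate a revision-spanning panel under the ideal response model (latent
durations Gamma(1, 3), 57 000 respondents, cohort of 20 000, 4-option source
and 5-option target grids) and align it:

```python
import vamalign as va

scenario = va.build_scenario(va.SimConfig(seed=1))
print("true population mean:", round(scenario.population_mean, 5))
print("naive midpoint mean of y1:", round(va.midpoint_mean(scenario.y1).mean, 5))
result = va.vam_pipeline(scenario.y1, scenario.cohort_pairs, scenario.B_ref,
                         beta_reference=scenario.beta_reference)
print(result.summary())
print("alignment error |z - z_true|inf:",
      round(va.linf(result.z, scenario.z1_true), 5))
```

prints

```
true population mean: 2.98858
naive midpoint mean of y1: 1.91446
Version alignment decomposition (T = B @ A)
===========================================
T shape:            5 x 4
alternations:       1
theta escalations:  0
objective:          0.498553
realized slacks:
  gamma |BA-T|inf   2.498e-16
  eps   |BAu-v'|inf 5.551e-17
  beta  |B-Bref|inf 4.986e-02
  alpha |A-G|inf    2.776e-16
slack target met:   True (target 0.0001)
converged:          True

aligned population p.v.: [0.28405, 0.28072, 0.21256, 0.10885, 0.11382]
population mean (midpoint): 2.71576
population mean (grouped MLE): 2.99575
alignment error |z - z_true|inf: 0.00048
```

The naive midpoint estimate on the 4-option grid (1.914) misses the true
mean (2.989) badly because the top-coded option hides the tail; after
alignment, the grouped MLE on the 5-option grid recovers it to 0.2%, and the
aligned distribution differs from the (normally unobservable) true one by
less than 0.001 in any cell.  The decomposition log shows the factorization
and cohort-vector constraints met essentially exactly, the time factor
within 0.05 of its reference, and the revision factor at the ideal matrix.

Published vectors and matrices from the motivating panel ship as fixtures
(`vamalign.datasets`) for the same workflow on real numbers, and a CLI
(`vamalign simulate | fit-mle | midpoint | ideal-matrix |
estimate-transitions | vam-align | bootstrap-ci | trend`) wraps each step
for shell use.

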