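# Methods

## Model structure

The animal is described by a neoblast count *N(t)*, differentiated-cell
counts *D₁(t)…D_I(t)* (I = 3 in the full model), and a resource pool
*Q(t)*, advanced by an explicit one-step map (a forward-Euler form of
the corresponding ODEs). Cell counts are continuous reals — the model
is a deterministic mean field — and are never rounded to integers.

Neoblasts divide in three classes with maximum per-step fractions p₁
(N→N,N), p₂ (N→N,P), p₃ (N→P,P). Progeny cells P are not a persistent
state: the 𝒫(t) produced in a step either complete differentiation
(probability f_Q(Q)) and are allocated across classes by relative need
wᵢ ∝ D̄ᵢ/Dᵢ, or return to the resource pool, within that same step.
Differentiated cells die at per-step rate

    Mᵢ = μ_Q(q) + μᵢ [ σ((dᵢ−D̄ᵢ)/σ_Dᵢ) + σ((ρᵢ−ρ̄ᵢ)/σ_ρᵢ) ],

where σ is the logistic function, so apoptosis responds to both the
absolute and the relative (proportion ρᵢ) deviation from the
homeostatic targets; at homeostasis each bracket term is ½ and
Mᵢ = μᵢ. Resources are spent by priority — maintenance first, then the
three division classes in order — encoded in the cumulative thresholds
q₁…q₄ whose Hill-type gates a₁…a₃ multiply the division rates.

One step is one unit of model time; p₁+p₂+p₃ is the maximum fraction
of neoblasts active per step, which is what ties a step to physical
time (no chronological calibration is assumed; reported "scaled time"
is steps/10,000).

## Parameters

| symbol | default | meaning / rationale |
|---|---|---|
| p₁, p₂, p₃ | 1e-4, 5e-4, 1.5e-4 | per-step division-class maxima; p₁ < p₃ is required for a steady state |
| I | 3 (full), 1 (simplified) | differentiated classes |
| μ₀, s | 1.5e-4, (0.75, 1, 1) | baseline mortality and class multipliers, μᵢ = sᵢμ₀; the sᵢ set the 40/30/30 steady mix |
| μ | 1.5e-4 | simplified-model constant mortality; set equal to μ₀ (only a baseline rate is specified anywhere) |
| m_r, m_d | 1, 4 | resource units per cell-step of maintenance and per division |
| γ | 3.2 (= 0.8 m_d) | resources recycled from a dying cell |
| γ_p | = γ | recycling from a progeny cell returning to the pool; no separate value is specified and the term is inactive whenever f_Q = 1, so the cell value is reused |
| δ | 2/3 | food-acquisition exponent (surface-area scaling); only class 1 gathers food |
| Y_e | 450 | external food in multiples of m_r (the reference growth-protocol level) |
| β_Q | 1e-5 | shape of f_Q = 1−e^(−β_Q q). Chosen so f_Q > 0.999 whenever the pool covers ~7×10⁵ resource units, i.e. any pool at the scale of the maintenance requirement q₁ of a steady-state animal (10⁶–10⁷ cells); configurable |
| μ_Q,max | 0 | ceiling of resource-dependent mortality; 0 disables it, matching the sufficient-resources regime all headline results use |
| c_N, c_D | 0.15 | N_c = σ_N = c_N·N̄(Y_e); σ_Dᵢ, σ_ρᵢ = c_D × steady values |
| hill_exponent | 2 | exponent of the resource gates; exposed because its value is an open empirical question |

`sufficient_resources=True` (default) forces a₁=a₂=a₃=1, f_Q=1,
μ_Q=0 and freezes Q; all reported experiments run in this regime.

The threshold q₃ is implemented as q₂ + p₂ f_D m_d n: the p₂ factor
counts the expected N→N,P divisions, making q₃ consistent with its
siblings q₂ (p₁) and q₄ (p₃) and with the division-cost term of the
resource balance. The variant without the p₂ factor is available via
`q3_includes_p2=False`. μ_Q is implemented exactly in its stated form,
which is non-monotone in q between q_μ and 10 q_μ; with μ_Q,max = 0
this has no effect on any default run.

## Steady state and calibration

With sufficient resources the steady state satisfies f_D(D̄) = φ̄ =
p₁/p₃ (hence p₁ < p₃), wᵢ = D̄ᵢ/N̄ = φ̄(p₂+2p₃)/(I(1−e^(−μᵢ))), and a
resource balance that yields N̄^(1−δ) explicitly. The neoblast
fraction 1/(1+Σwᵢ) ≈ 0.2020 depends only on the p's and μ's — it is
the model's food-independence prediction. The feedback strengths
αᵢ = (1/φ̄−1)/D̄ᵢ therefore fall with food. For each food level the
calibration (D̄ᵢ, ρ̄ᵢ, αᵢ, N_c, σ_N, σ_D, σ_ρ) is recomputed; on a
food change during a run the model is *recalibrated* to the new level,
which is how the food signal reaches the dynamics even when resources
never bind. (Freezing the calibration instead is available via
`recalibrate=False`.)

Body size uses ln S = −3.8373 + 0.46582 ln ΣDᵢ (natural logs;
coefficients taken as fixed constants from published planarian
cell-count/size data; a base-10 variant is provided). Neoblasts do not
contribute to size, which is why irradiation leaves size exactly
continuous.

## Fixed-point structure (important caveat)

The closed form assumes f_N(N̄) = 1, but the calibrated logistic gives
f_N(N̄) = σ(0.85/0.15) ≈ 0.9966. The consequences are larger than the
0.3 % shortfall suggests, because the dynamics are nearly degenerate
along the manifold f_D·f_N = φ̄:

* Each model has an exact fixed point of its step map *adjacent* to
  the closed form (simplified: N −1.4 %, D −1.1 %; full: N −3.8 %,
  D −1.3 %). It is a **saddle**: the leading Jacobian eigenvalue is
  ≈ 1 + 2×10⁻⁵ (simplified) / 1 + 8×10⁻⁶ (full). A trajectory started
  exactly at the closed form lies on the runaway side and grows
  without bound, e-folding every ~10⁵ steps.
* A second, **stable** fixed point sits well below (simplified
  D ≈ 0.42 D̄; full D ≈ 0.80 D̄, i.e. ~90 % of the closed-form size).
  Animals grown from small starts — the 20 %-of-steady growth
  protocol, fission fragments — converge to it, on a slow timescale
  (all eigenvalues within a few 10⁻⁴ of 1, e-folding times of
  3×10⁴–10⁵ steps).

Operationally: homeostasis in *simulated* animals means the stable
fixed point, so the excision and irradiation protocols first grow the
animal to that attractor (2×10⁵-step burn-in from a 20 % start,
Newton-polished to machine precision; `neoblast.fixed_points`) before
perturbing. Quantities derived from the closed form (composition,
neoblast fraction, α calibration, size–food scaling) are unaffected —
the stable attractor shares the closed form's composition and neoblast
fraction to within a few percent — but *absolute* convergence of
simulated sizes to the closed-form size should not be expected, and
the test suite deliberately keeps two red tests recording exactly
that: epoch-wise convergence of the growth protocol to within 2 % of
the recalibrated closed form does not occur (epoch-end sizes reach
84–91 % over 7-scaled-unit epochs), and the fission protocol's
mortality burst peaks near 1.03× the terminal per-capita rate, not
≥ 1.5× (all compartments of a fragment start *below* their absolute
targets, so the level logistic suppresses rather than boosts
mortality; the burst that does occur — an initial per-capita spike
1.35× the post-remodeling trough, driven by the over-represented
class — is asserted by a passing test).

## In-silico protocols and problem sizes

All protocols are deterministic and run to scaled time 21
(2.1×10⁵ steps) by default, recording every 100 steps:

* **growth/degrowth** — start at 20 % of the closed-form cell numbers
  (the "20 % of steady size" initial condition is read as 20 % of
  cell numbers; a size-based convention can be had by passing the
  corresponding fraction), food schedule 450 → 400 @ t=7 → 480 @ t=14
  for the full model, 240 → 200 @ 7 → 160 @ 15 for the simplified
  repeat (the latter schedule's values are package defaults, not
  reported ones).
* **fission remodeling** — full model from 50 % of steady neoblasts
  and (10, 30, 5) % of the three differentiated classes; constant
  food 450.
* **excision / x-ray** — simplified model at its stable attractor for
  food 240 (a package default; the reported runs do not print one);
  at t=7 remove 25 % of D (excision) or of N (x-ray).

Recovery of a metric after a perturbation is reported two ways:
the first return of |x − x_pre| within 1 % of the pre-perturbation
value (undefined when the excursion never leaves that band, as for
f_N after excision, whose excursion is ~0.8 %), and a scale-free
variant — the time for the deviation to decay below 1 % of its peak —
used when comparing metrics whose excursions differ by orders of
magnitude. By the scale-free measure f_D relaxes within ~9 scaled
units after excision while f_N has not finished relaxing by the end of
the run, reproducing the different-time-scales signature.

## Numerical choices

* Relative-need weights are undefined when a class is empty; inside
  the allocation only, counts are floored at 10⁻⁹ cells
  (`allocation_floor`), so an emptied class simply captures ~all
  progeny. Mortality with zero total differentiated cells raises a
  degenerate-state error rather than guessing.
* In resource-tracking mode a transiently negative pool is clamped at
  0 with a logged warning and the clamp amount reported per step; the
  bookkeeping identity Q(t+1) − Q(t) = Σ fluxes + clamp is exact.
* The logistic is evaluated in its numerically stable branch form;
  deaths use expm1. Resource gates return 0 when a division class is
  fully suppressed upstream (n = 0 or f_D = 0 collapse a threshold
  interval); the suppressed class has zero rate regardless.
* Fixed points are polished by damped Newton on the step residual
  with central-difference Jacobians (dimension 2 or 1+I), relative
  tolerance 10⁻¹³.
* Trajectory CSVs are written with 12 significant digits —
  regression-stable yet precise — with a generated JSON schema
  documenting every column; identical configs give byte-identical
  files.

## What the simulations do and do not emulate

Runs are generated entirely by the model: there is no external data
path. The protocols emulate whole-animal cell-count experiments —
growth under feeding regimes, remodeling after fission, wounding, and
irradiation — at the level of compartment totals. They do not emulate
spatial structure (no wound-site localization, no cell migration, and
therefore no second, wound-local proliferative peak), stochastic
cell-fate noise (counts are continuous means), inter-individual
parameter variation, or the developmental origin of the homeostatic
targets D̄ᵢ, which are exogenous constants. Passing tests therefore
demonstrate internal consistency of the feedback architecture and
its qualitative agreement with whole-animal observations, not
quantitative agreement with any measured planarian dataset.

## Known limitations

* The closed-form steady state is not the simulated attractor (see
  the fixed-point section); claims that require it to be one are
  recorded as red tests rather than hidden.
* The full model's neoblast fraction sags to ~0.13–0.15 during
  20 %-start growth — 25–35 % below the closed-form 0.202 — before
  creeping back; the simplified model keeps its fraction within 10 %.
  The "constant fraction" prediction is exact across steady states,
  approximate along trajectories.
* With I = 1 the proportion logistic of the full mortality law is
  identically ½, so the simplified model's constant-μ mortality is not
  the I = 1 reduction of the full law; the models coincide exactly
  (tested to 10⁻¹²) only when the full model is run with its
  constant-mortality option.
* Physical time per step and per-cell resource units are conventions;
  only dimensionless combinations (fractions, ratios, scaled times)
  should be compared across parameterizations.
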