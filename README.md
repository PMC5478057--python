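# msrecap

Age-structured **m**ulti**s**tate mark–**recap**ture analysis for two-colony
bat populations.

`msrecap` implements the four-state capture–recapture model used in
long-term demographic studies of sympatric mouse-eared bats
(*Myotis blythii* and *M. myotis*) breeding at two nursery roosts
(Naters and Raron): females are observed annually in one of four states —
not-yet-breeding at colony N (1) or R (2), experienced breeder at N (3) or
R (4) — and the model estimates apparent survival, age-specific first
reproduction, natal and breeding dispersal, and recapture probabilities
from the resulting capture histories. It is written for population
ecologists who want a scriptable, testable alternative to GUI
capture–recapture software for this model class, including a matching
simulator for design and power work.

## The model

For a female marked as a juvenile, the transition from age 0 to 1 couples
first-year survival φ^juv, natal dispersal *n* and the first-year breeding
probability α₁; e.g. the probability of surviving in colony N, staying,
and starting to breed is φ^juv_N (1−n_NR) α₁^N. From age *j* to *j*+1
(1 ≤ *j* ≤ 4) adult survival φ^ad and breeding dispersal *b* apply, with
α_j acting only on females that have not yet bred; α₄ = 1, so every
survivor breeds by age 4 (a structural constraint required for
identifiability). From age 5 onward — and for all females marked as adults
— only the breeder states remain. Death is carried as an explicit fifth
absorbing state, so every transition matrix is exactly row-stochastic.

Each capture history contributes a multinomial likelihood term computed by
the hidden-Markov forward recursion, conditional on first release.
Parameters are free on the logit scale under user-declared effect
structures written in the compact field notation, e.g.

```
phi(juv: year; ad: spec) psi(juv: .; ad: spec) p(Col*year+rep+spec) alpha(a3+spec)
```

Candidate models are ranked by AIC (ΔAIC, Akaike weights) and parameters
can be model-averaged with Burnham–Anderson unconditional standard
errors. Derived life-history quantities follow the standard arithmetic:
mean age at first reproduction AFR = α₁ + Σₙ₌₂⁴ n αₙ Πᵢ₌₁ⁿ⁻¹ (1−αᵢ), life
expectancy at age 1 = −1/ln(φ^ad), and expected reproductive years =
life expectancy − (AFR − 1).

## Worked example

```python
import msrecap as m
from msrecap.recovery import generating_model_spec

config = m.mouse_eared_study_config(seed=7, species=(m.BLYTHII,))
dataset = m.simulate(config)          # 430 females, 13 occasions, none in 1994
model = m.fit(generating_model_spec(), dataset, starts=3, seed=0)
print(model.estimate("phi_ad"))       # (estimate, SE)
```

Running `python examples/fit_generating_model.py` (this exact analysis)
prints:

```
n = 430 females, deviance = 2706.80, k = 9, converged = True

adult survival       0.844  (SE 0.012)
first-year survival  0.546  (SE 0.037)
alpha_2              0.213  (SE 0.052)
alpha_3              0.709  (SE 0.072)
recapture            0.712  (SE 0.017)
breeding disp. N->R  0.067  (SE 0.011)
breeding disp. R->N  0.141  (SE 0.021)
```

The simulation truth was φ^ad = 0.84, φ^juv = 0.52, α = (0, 0.33, 0.63, 1),
p = 0.7 and dispersal (0.063, 0.142): each estimate sits within sampling
error of its generating value at this sample size (α₂/α₃ rest on the ~120
known-age females surviving their first year, hence the wider spread).
Other entry points are shown one per script under `examples/`, and the
same pipeline is available from the shell via `msrecap simulate | fit |
select | derive`.

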