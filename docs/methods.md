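# Methods

## Model and assumptions

`msrecap` implements an age-structured multistate (Arnason–Schwarz-type)
capture–recapture model for females of two bat species sharing two nursery
colonies. The state space is {1: not-yet-breeding at colony N, 2:
not-yet-breeding at R, 3: experienced breeder at N, 4: breeder at R} plus
an explicit absorbing dead state. Assumptions: annual sampling occasions;
states assessed without error when captured; first breeding is absorbing
(a breeder never returns to states 1–2); all survivors breed by attained
age 4 (α₄ ≡ 1, a structural constraint without which the late-age
first-breeding probabilities are inestimable); individuals are independent
and homogeneous given their covariates (species, colony, age class, year,
pulse-resource status); apparent survival confounds death and permanent
emigration. Females marked as adults enter in the breeder states
regardless of their current reproductive status and inform only adult
survival, breeding dispersal and breeder recapture.

Transition matrices follow the standard three-regime schedule. The age
0→1 block uses first-year survival φ^juv, natal dispersal *n* and α₁;
attained ages 2–4 use adult survival φ^ad, breeding dispersal *b* and α at
the attained age (the subscript convention adopted here indexes α by the
age reached at the end of the interval, which makes the forced age-4
transition a special case of the generic block rather than a separate
matrix); from attained age 5 onward only breeder rows remain. The dead
state makes every block row-stochastic to machine precision, which the
test suite asserts directly.

## Likelihood and fitting

Each history contributes −log of the probability of its observation
sequence after first release, conditional on release in the observed
state, computed by the forward recursion with per-step renormalisation
(underflow-safe). The recursion is verified against exhaustive latent-path
enumeration on all histories of ≤ 5 occasions. Recapture uses the latent
state's status: states 1–2 take the not-yet-bred probability, 3–4 the
breeder probability; recapture is structurally 0 at occasions with no
capture (the 1994 gap in the study design), making any observation there
impossible. Histories with probability 0 under a model's structural zeros
abort the fit with a list of offending individuals rather than being
dropped.

For speed, identical histories within a (species, age-at-marking, release
occasion, birth-cohort flag) group are pooled with multiplicities and the
recursion is vectorised across a group; equality with the per-history sum
is tested to 1e-8.

Optimisation is L-BFGS-B on the logit scale from 5 dispersed starts by
default (first start at logit 0; others N(0,1)), ftol 1e-10, gtol 1e-7. A
fit is flagged converged when the optimiser succeeded and the two best
starts agree within 1e-4 in deviance — finite-difference gradients cannot
certify a 1e-8 gradient norm, so start-agreement stands in for it.
Standard errors come from the pseudo-inverse of a central-difference
Hessian of the negative log-likelihood, mapped to the probability scale by
the delta method; cells whose linear predictor exceeds |logit| > 10 are
treated as boundary estimates and their SE suppressed (NaN). The Hessian's
numerical rank is reported so that confounded parameters (e.g. year-specific
first-year survival into the uncaptured year) are flagged post hoc rather
than removed a priori; the printed parameter counts of legacy analyses
depend on such conventions and are deliberately not an output this package
tries to match.

Deviance is plain −2·log-likelihood without a saturated-model constant;
constants cancel in ΔAIC and Akaike weights (tested by offset invariance).

## Effect coding

Effect structures are linear models on the logit scale: additive terms use
corner-point (treatment) coding with a shared intercept, interactions
expand patsy-style (`A*B` = A + B + A:B), so a full interaction spends one
free parameter per factor-level combination. Factor levels absent from the
free cells (e.g. a fixed α₁, or the skipped occasion's recapture) are
dropped before coding, keeping the design matrix full-rank. Movement is
always direction-specific (N→R vs R→N are separate baseline cells; `.`
gives 2 parameters per age class, `spec` gives direction × species cell
means), because the field estimates show strong directional asymmetry.
The pulse-resource (cockchafer mass-flight) covariate enters survival as a
temporal effect of the interval's *ending* year (spring flights precede
the capture season) and enters first breeding either as the same temporal
effect or as a cohort effect keyed to the birth year; the study-wide
indicator is the union of the two colony calendars.

## Model selection and averaging

AIC = deviance + 2k; ΔAIC to the best model; weights exp(−ΔAIC/2),
normalised over the full candidate set, ties broken by fewer parameters.
Model averaging retains models with weight > 0.02 (configurable),
renormalises, averages on the probability scale and reports the
Burnham–Anderson unconditional SE Σ wᵢ √(varᵢ + (θᵢ − θ̄)²). The
averaging scale and the unconditional-SE form are design choices; both
identities (single model → conditional values, equal estimates →
conditional SE) are tested.

## Synthetic data

The simulator draws each female's latent path through the same transition
blocks the likelihood uses and thins it with the recapture probabilities —
generator and likelihood share one engine, so parameter recovery is a
meaningful end-to-end check rather than a tautology about two copies of
the same closed form. Each individual consumes an independent
`numpy` stream seeded by (global seed, individual index), so a subset of
individuals can be regenerated bit-for-bit.

The bundled study-like configuration mirrors the 13-year field design: 13
annual occasions 1989–2001 with no capture in 1994; colonies Naters and
Raron; per-colony cockchafer calendars (N: 1990/1994/1998, R:
1989/1992/1995/1998/2001); 430 lesser and 849 greater mouse-eared females
marked, of which 227 and 461 known-age. Colony splits (blythii 256/174,
myotis 193/656 for N/R) are back-calculated from the published colony
composition percentages, and releases are spread uniformly over the 11
marking years. Truth rates are the published species-level estimates:
φ^ad 0.84/0.80, φ^juv 0.52 (its published year-to-year variability is
summarised by a geometric mean, so the generator's default holds it
constant at that mean), α = (≈0, 0.33, 0.63, 1) and (≈0, 0.93, 0.98, 1),
and the four dispersal probabilities per species. The first-year breeding
probability is set to exactly 0 (reported only as "very low"), and fits of
the generating model fix it there. Recapture is not reported in the source
analysis; the default 0.7 reflects the high capture effort (≥ 4 netting
sessions per season) at closed nursery roosts.

What the simulator does **not** emulate: individual heterogeneity, tag
loss, transience or trap response, within-year structure, overdispersion,
or year effects in the generating truth. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness of the field estimates to their violation.

## Problem sizes and numerical choices

The recovery studies fit the 9-parameter constant-rate generating model to
20 replicates per species at the full study scale (430 / 849 females, 2
optimiser starts per fit, no Hessian), a few minutes on one CPU; these
sizes keep the Monte-Carlo SE of the replicate mean near 0.003 (adult
survival) and 0.006 (α₂), small enough to detect estimator bias of a
percentage point. Tolerances: forward-vs-enumeration agreement 1e-9;
pooled-vs-direct likelihood 1e-8; closed-form binomial MLE agreement 1e-6
(limited by optimiser termination); link round-trip 1e-12. Ties in AIC
ranking favour the more parsimonious model. Degenerate inputs (empty
datasets, histories with nothing after release, all-fixed families with
zero free parameters) are exercised in the unit tests.

## Known limitations

* No goodness-of-fit machinery or overdispersion (ĉ) adjustment.
* No random effects or individual covariates beyond
  species/colony/age/status; no senescence classes.
* Recapture estimates at the final occasion of a year-specific model are
  confounded with survival in the usual CJS way; the package reports them
  without special flagging beyond Hessian rank.
* Published absolute deviances from legacy software include a
  saturated-model constant and are not comparable to this package's
  deviance scale; only ΔAIC arithmetic is.
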