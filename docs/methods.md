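# Methods

## The model

The package implements an annual-cycle, deterministic state-transition
cohort model of false-positive accumulation in repeated non-invasive
colorectal-cancer screening. Five states are tracked as real-valued
occupancies of a closed cohort (default 100 000 persons at age 50):

* alive, neoplasia-free, never false-positive (`free_no_fp`) — the only
  state that can generate a *first* false positive;
* alive, neoplasia-free, with a prior false positive (`free_fp`);
* alive with colorectal neoplasia, without / with a prior false positive
  (`neo_no_fp`, `neo_fp`);
* dead.

A separate non-decreasing counter `cum_fp` records everyone who ever
tested false positive; it is never decremented when those people later
develop neoplasia or die, matching the "cumulative number of persons"
semantics of the headline outcome. A false positive is a positive stool
test in a person free of both CRC and adenomas at test time; neoplasia
onset is absorbing for FP eligibility (no detection/regression modelling
is needed for this outcome, and none is attempted).

Within each cycle at integer age `a` the order of events is: screening
(if `a` is a round age), then neoplasia onset with probability `i(a)`
(preserving the FP flag), then death with probability `q(a)` applied
uniformly to all alive states. Screening first makes the free-pool
occupancy at a round exactly equal to the survivorship value `F(a_r)`
used by the closed form below, so the engine/oracle agreement is exact
rather than approximate; the tolerance in the equivalence tests (1e-9
relative) covers only floating-point accumulation. No half-cycle
correction is applied — occupancies are evaluated at integer ages.

## Closed form

Anyone free at round `r` was free at every earlier round, so their prior
test history is a sequence of independent Bernoulli trials with the
per-round FP probabilities, giving first-FP round weights
`w_r = p_r · Π_{j<r}(1 − p_j)` and

```
cumFP(a) = 100000 · Σ_{r: a_r ≤ a} F(a_r) · w_r ,
```

with `F(a)` the fraction of the age-50 cohort alive and neoplasia-free at
`a`. Two consequences shape the whole package:

1. `F` is a sufficient statistic — the split of attrition between
   incidence and mortality is unidentifiable from cumFP (verified as a
   property test: any two schedule pairs with equal per-age product
   `(1 − i)(1 − q)` give identical output);
2. at fixed shape, cumFP is proportional to `F(50)`, so scale calibration
   is a single division.

The closed form also inverts: the increments of a cumFP column across
rounds identify `F` at exactly the screening ages,
`F(a_r) = [cumFP(a_r) − cumFP(a_{r−1})]/(100000·w_r)`. Inversion is
deliberately restricted to round ages; no interpolation is offered.

## Screening strategies

A strategy is `(start_age, stop_age = 74, interval, specificity s,
dependence reduction δ)`. Round ages run `start, start+interval, …` with
both endpoints eligible; the last round is the largest grid age ≤ 74.
The base case assumes conditional independence of sequential testing:
`p_r = 1 − s` at every round. The sensitivity variant lowers the FP
probability by one *percentage point* (absolute) from the second round
onward, `p_r = 1 − s − 0.01`, reflecting evidence that people with prior
true-negative results are less prone to false positives. Under perfect
adherence — assumed throughout — anyone facing round `r ≥ 2` while still
free and never false-positive has exactly `r − 1` prior true negatives,
so the rule needs no per-person history. The reduction is additive rather
than relative because a relative 1% change would be a negligible
perturbation, inconsistent with the ~40% effect the variant is meant to
explore. `δ` may not exceed `1 − s`.

The standard catalogue holds eleven strategies: intervals {1, 2, 3} years
× specificity {98, 95, 92}% starting at age 50, plus biennial 98%
starting at 54 and at 58 — the grid over which published results for this
model family are reported.

## Calibration (the synthetic-data stage)

The cohort's empirical inputs — age-specific neoplasia incidence from a
screening-colonoscopy trial arm and Dutch national life-table mortality —
are not redistributable, and by the sufficiency argument above they
matter only through `F`. The package therefore treats `F` itself as the
calibration target:

* **shape**: `F(a)` linear in age on [50, 74] with
  `F(74)/F(50) = ratio_74 = 0.54`, the published fraction of the
  neoplasia-free at 50 who are still alive and lesion-free at 74;
* **scale**: `f50 = F(50)` fitted so the biennial / 98%-specificity /
  start-50 strategy reproduces the published age-74 cumFP of 15 102 per
  100 000, giving `f50 ≈ 0.8374`.

Linearity is a modelling choice, not a published fact; it is justified
post hoc by reproduction quality — every published base-case age-74 value
is matched within 0.7% and the dependence-variant values within 1.7%
(both inside the 1.5% / 3% acceptance bands the tests assert). Because
the shape has a single free parameter, quantities that are ratios of
cumFP values (cross-strategy percent differences, the per-lesion-free
percentage) are independent of `f50` entirely.

Calibrated engine runs start at age 50 with initial neoplasia prevalence
`1 − f50` and place all subsequent attrition in the incidence schedule
(zero mortality): `i(a) = 1 − F(a+1)/F(a)`. This choice is
observationally neutral (sufficiency) and round-trips exactly — the
engine's free-pool occupancy reproduces `F` to better than 1e-10
relative. When a mortality schedule is supplied, the derivation divides
it out, `i(a) = 1 − [F(a+1)/F(a)]/(1 − q(a))`, clipping negative values
within 1e-9 (floating-point noise at curve endpoints) and raising beyond
that, naming the failing age: a curve whose annual drop is smaller than
mortality alone is inconsistent with that life table. Ages below 50 are
not simulated; they affect the model only through `f50`.

The synthetic Gompertz mortality generator (`q(a) = min(1, a·e^{b·age})`,
defaults of order `a ≈ 1e-5`, `b ≈ 0.1/yr` matching Western-European
adult life tables) exists so that engine runs with a realistic,
non-degenerate mortality component can be constructed and tested without
external data. What the synthetic stage does **not** emulate: cohort
heterogeneity in FP proneness beyond the single-δ dependence rule,
imperfect adherence, sex differences, and any non-linear curvature of the
true survivorship — so passing tests demonstrate internal consistency and
reproduction of the published aggregate figures, not validity of the
linear shape for other populations.

## Numerical choices

* Real-valued cohort proportions throughout; no Monte Carlo noise.
  Rounding to integers per 100 000 (half-up) happens only at CSV
  serialization.
* Engine ≡ closed-form equivalence is asserted at 1e-9 relative,
  inversion and schedule round-trips at 1e-10; these are float-noise
  budgets, not model tolerances — any genuine disagreement is a bug.
* Schedule CSVs require consecutive integer ages; gaps are an error, not
  an interpolation opportunity.
* The calibration rejects fitted `f50` outside (0, 1] (beyond a 1e-9
  noise allowance at the no-attrition limit), anchors outside their
  domains, and anchor strategies with δ > 0 (the anchor is a base-case
  figure).
* Strategies whose first round lies after the run start age simply age
  the cohort untested until that round; a run may not start after the
  first round.

## External consistency check

`zorzi_check` mirrors the one long-running empirical benchmark available:
a biennial FIT programme whose 12-year follow-up implies 91–98 of every
1000 neoplasia-free regular participants aged 50–54 received a positive
result over five rounds. The check runs the closed form for five biennial
rounds at specificity 97.5% starting at age 52 (the midpoint of the
recruitment ages — the published comparison does not state how the range
was collapsed) on the calibrated curve, yielding ≈ 88.3 per 1000.

## Problem sizes and limitations

All computations are desk-scale: 25 annual cycles × 11 strategies × 3
tables run in well under a second, and the randomized property suites use
tens of draws of 25-element schedules. Known limitations: the linear
survivorship shape is an approximation whose error grows with the
dependence reduction δ (hence the wider 3% band on the sensitivity
variant); results are not sex-stratified; test sensitivity, colonoscopy
follow-up, and screening benefit are out of scope — the model prices the
false-positive burden only.
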